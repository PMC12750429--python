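"""Assembly of the 26-predictor feature table from patient records.

The candidate predictors are: sex, age, BMI, total length of stay, days
from injury to measurement, UEMS, LEMS, the combined-acceleration means
at the three IMU sites, and the normalized RMS (%) and wavelet median
frequency (Hz) of the eight recorded muscles.  One row per patient,
missing values as NaN, group label kept alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import emg, kinematics
from .io import IMU_SITES, MUSCLES, PatientRecord

FEATURE_COLUMNS: tuple[str, ...] = (
    "sex", "age", "bmi", "total_length_of_stay", "days_injury_to_measurement",
    "uems", "lems",
    *(f"acc_{site}" for site in IMU_SITES),
    *(f"rms_{m}" for m in MUSCLES),
    *(f"mdf_{m}" for m in MUSCLES),
)

LABEL_COLUMN = "group"
POSITIVE_CLASS = "WD"  # walking dependent is the positive class throughout


def extract_features(
    record: PatientRecord,
    onset_threshold_deg: float = 2.0,
    onset_min_hold_s: float = 0.2,
    window_s: float = 10.0,
    acc_summary: str = "mean",
    scale_frequencies: np.ndarray | None = None,
) -> dict:
    """Compute one patient's feature row from their recorded trials.

    SLR onsets are detected from the lower-leg pitch; trials without a
    detectable onset (or too short for the 10-s window) are skipped, and
    features average over the usable trials.  Missing covariates and
    features unavailable through missing normalization trials propagate
    as NaN.
    """
    onsets: list[int | None] = []
    windows: list[kinematics.AnalysisWindow | None] = []
    for trial in record.slr_trials:
        try:
            pitch = kinematics.estimate_pitch(
                trial.imu_acc["lower_leg"], trial.imu_gyr["lower_leg"], trial.fs
            )
            onset = kinematics.detect_slr_onset(pitch, onset_threshold_deg, onset_min_hold_s)
        except (kinematics.OnsetNotDetected, ValueError):
            onsets.append(None)
            windows.append(None)
            continue
        window = kinematics.AnalysisWindow.from_onset(onset, trial.fs, window_s)
        if window.end_index > trial.n_samples:
            onsets.append(None)
            windows.append(None)
        else:
            onsets.append(onset)
            windows.append(window)

    row: dict = {
        "patient_id": record.patient_id,
        LABEL_COLUMN: record.group,
        "sex": 1.0 if record.sex == "M" else 0.0,
        "age": record.age,
        "bmi": record.bmi,
        "total_length_of_stay": record.total_length_of_stay,
        "days_injury_to_measurement": record.days_injury_to_measurement,
        "uems": np.nan if record.uems is None else record.uems,
        "lems": np.nan if record.lems is None else record.lems,
    }

    acc = kinematics.acceleration_feature(record.slr_trials, onsets, window_s, acc_summary)
    for site in IMU_SITES:
        row[f"acc_{site}"] = acc[site].trial_average

    try:
        reference = emg.reference_rms(record.normalization_trials)
        activation = emg.normalized_rms(record.slr_trials, windows, reference)
        for m in MUSCLES:
            row[f"rms_{m}"] = activation.average[m]
    except emg.DegenerateReferenceError:
        for m in MUSCLES:
            row[f"rms_{m}"] = np.nan

    spectral = emg.spectral_feature(record.slr_trials, windows, scale_frequencies)
    for m in MUSCLES:
        row[f"mdf_{m}"] = spectral.mdf[m]
    return row


def feature_table(records: list[PatientRecord], **kwargs) -> pd.DataFrame:
    """Feature rows for a whole cohort, in record order."""
    rows = [extract_features(r, **kwargs) for r in records]
    return pd.DataFrame(rows, columns=["patient_id", LABEL_COLUMN, *FEATURE_COLUMNS])
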