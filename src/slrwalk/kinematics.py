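"""Pitch estimation, SLR onset detection and combined-acceleration features.

The straight-leg-raise start point is identified from the lower-leg pitch
angle; the analysis window runs from that start point to 10 s after it.
Gravity is removed from each accelerometer axis with a 1-Hz high-pass
zero-lag 4th-order Butterworth filter, and the combined acceleration is
the per-sample Euclidean magnitude of the filtered triaxial signal,
summarized by its time-mean over the analysis window and averaged over
the three trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import IMU_SITES, MultichannelTrial


class OnsetNotDetected(RuntimeError):
    """No sustained pitch threshold crossing was found in the trial."""


@dataclass
class PitchTrace:
    """Estimated pitch in degrees, one value per sample of the source trial."""

    pitch: np.ndarray
    fs: float


@dataclass
class AnalysisWindow:
    """Sample window from the SLR start point to exactly 10 s after it."""

    start_index: int
    end_index: int

    @classmethod
    def from_onset(cls, onset_index: int, fs: float, length_s: float = 10.0) -> "AnalysisWindow":
        return cls(onset_index, onset_index + int(round(length_s * fs)))

    def slice(self) -> slice:
        return slice(self.start_index, self.end_index)


@dataclass
class CombinedAccelerationFeature:
    site: str
    per_trial: list[float]  # mean magnitude per usable trial, g
    trial_average: float    # arithmetic mean of per-trial values, g


def estimate_pitch(
    acc: np.ndarray,
    gyr: np.ndarray | None,
    fs: float,
    crossover_hz: float = 0.5,
) -> PitchTrace:
    """Estimate the pitch angle from a triaxial accelerometer (+ gyroscope).

    Accelerometer inclination (atan2 of the along-limb axis over the
    perpendicular axis) gives a drift-free but noisy and motion-corrupted
    estimate; the y-axis gyroscope gives a clean short-term derivative.
    They are fused with a first-order complementary filter whose crossover
    is ``crossover_hz``: below it the accelerometer dominates, above it
    the integrated gyroscope does.  Returns degrees, 0 at the rest
    posture.  Without a gyroscope the inclination is low-pass filtered at
    the crossover instead.
    """
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError("accelerometer input must have shape (n, 3)")
    if not np.any(np.linalg.norm(acc, axis=1) > 1e-12):
        raise ValueError("all-zero accelerometer: no gravity reference for inclination")
    theta_acc = np.degrees(np.arctan2(acc[:, 0], acc[:, 2]))
    dt = 1.0 / fs
    if gyr is None:
        b, a = sps.butter(2, crossover_hz, btype="lowpass", fs=fs)
        pitch = sps.filtfilt(b, a, theta_acc)
        return PitchTrace(pitch=pitch, fs=fs)
    gyr = np.asarray(gyr, dtype=float)
    tau = 1.0 / (2.0 * np.pi * crossover_hz)
    alpha = tau / (tau + dt)
    # y[i] = alpha*(y[i-1] + gyr_y[i]*dt) + (1-alpha)*theta_acc[i], vectorized
    # as a first-order IIR recursion with initial state theta_acc[0]
    u = alpha * gyr[:, 1] * dt + (1.0 - alpha) * theta_acc
    # seed the recursion from the early-rest mean inclination, not a single
    # noisy sample, so the filter's settling transient does not pollute the
    # short pre-movement baseline
    n_init = max(int(round(0.25 * fs)), 1)
    zi = np.array([alpha * float(np.mean(theta_acc[:n_init]))])
    pitch, _ = sps.lfilter([1.0], [1.0, -alpha], u, zi=zi)
    return PitchTrace(pitch=pitch, fs=fs)


def detect_slr_onset(
    pitch: PitchTrace,
    threshold_deg: float = 2.0,
    min_hold_s: float = 0.2,
    baseline_s: float = 0.5,
    backtrack_margin_deg: float = 0.25,
) -> int:
    """Movement-start sample from a sustained pitch threshold crossing.

    The baseline is the median pitch over the first ``baseline_s`` seconds
    of pre-movement rest.  The detector finds the first sample where pitch
    exceeds baseline + ``threshold_deg`` and stays above for
    ``min_hold_s`` — the threshold is set well above rest noise so this
    crossing is unambiguous — then walks backwards to the last sample
    within ``backtrack_margin_deg`` of baseline, so the returned index
    marks the start of the raise rather than the (rate-dependent) point
    where the threshold itself was reached.  Raises
    :class:`OnsetNotDetected` when no sustained crossing exists (such
    trials are excluded upstream).
    """
    x = np.asarray(pitch.pitch, dtype=float)
    fs = pitch.fs
    n_base = int(round(baseline_s * fs))
    if n_base < 1 or n_base > len(x):
        raise ValueError("trial too short for the pre-movement baseline")
    baseline = float(np.median(x[:n_base]))
    above = x > baseline + threshold_deg
    hold_n = max(int(round(min_hold_s * fs)), 1)
    if len(x) < hold_n:
        raise OnsetNotDetected("trial shorter than the sustain requirement")
    # windowed count of 'above' samples via cumulative sum
    c = np.concatenate([[0], np.cumsum(above)])
    sums = c[hold_n:] - c[:-hold_n]
    hits = np.nonzero(sums == hold_n)[0]
    if len(hits) == 0:
        raise OnsetNotDetected(
            f"pitch never exceeded baseline {baseline:.2f} + {threshold_deg} deg for {min_hold_s} s"
        )
    i = int(hits[0])
    while i > 0 and x[i - 1] > baseline + backtrack_margin_deg:
        i -= 1
    return i


def remove_gravity(acc: np.ndarray, fs: float, cutoff_hz: float = 1.0) -> np.ndarray:
    """High-pass each axis at 1 Hz with a zero-lag 4th-order Butterworth.

    The forward-backward application cancels phase, so the gravitational
    (quasi-DC) component is removed without shifting motion transients.
    """
    acc = np.asarray(acc, dtype=float)
    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    # second-order sections: the cutoff sits at ~0.1% of Nyquist, where the
    # polynomial (b, a) form of an order-4 filter is numerically unstable
    sos = sps.butter(4, cutoff_hz, btype="highpass", fs=fs, output="sos")
    n = acc.shape[0] if acc.ndim > 1 else len(acc)
    if n <= 81:  # 3x the forward-backward padding span
        raise ValueError(f"series of {n} samples too short for filter settling")
    return sps.sosfiltfilt(sos, acc, axis=0)


def combined_acceleration(acc: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean magnitude of a triaxial series."""
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError("expected shape (n, 3)")
    return np.linalg.norm(acc, axis=1)


def acceleration_feature(
    trials: list[MultichannelTrial],
    onsets: list[int | None],
    window_s: float = 10.0,
    summary: str = "mean",
) -> dict[str, CombinedAccelerationFeature]:
    """Combined-acceleration feature per IMU site, averaged over trials.

    For each trial with a detected onset: gravity-filter the site's
    accelerometer, take the magnitude, and summarize it (time-mean by
    default, peak optionally) over the 10-s analysis window; the feature
    is the mean of the per-trial summaries.  Trials whose onset is None or
    whose window exceeds the trial are skipped; a site with zero usable
    trials yields a NaN trial average (missing-feature flag).
    """
    if summary not in ("mean", "peak"):
        raise ValueError("summary must be 'mean' or 'peak'")
    out: dict[str, CombinedAccelerationFeature] = {}
    for site in IMU_SITES:
        per_trial: list[float] = []
        for trial, onset in zip(trials, onsets):
            if onset is None:
                continue
            window = AnalysisWindow.from_onset(onset, trial.fs, window_s)
            if window.end_index > trial.n_samples:
                continue
            filtered = remove_gravity(trial.imu_acc[site], trial.fs)
            mag = combined_acceleration(filtered)[window.slice()]
            per_trial.append(float(mag.max() if summary == "peak" else mag.mean()))
        avg = float(np.mean(per_trial)) if per_trial else float("nan")
        out[site] = CombinedAccelerationFeature(site=site, per_trial=per_trial, trial_average=avg)
    return out
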