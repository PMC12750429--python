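"""Trial and cohort containers plus the plain-text recording dialect.

A recording session for one patient consists of three straight-leg-raising
(SLR) trials and three bilateral-SLR normalization trials, each a
synchronized 1000-Hz multichannel recording: 8 surface-EMG channels and
3 inertial sensor sites (triaxial accelerometer in g, triaxial gyroscope
in deg/s).

Channel montage
---------------
EMG channels are named by muscle and side relative to the raised
(nondominant) leg: ``rf_ips`` (ipsilateral rectus femoris), ``bf_con``
(contralateral biceps femoris), and bilateral rectus abdominis, internal
oblique and external oblique (``ra_ips``/``ra_con``, ``io_ips``/``io_con``,
``eo_ips``/``eo_con``).  IMU sites are ``asis`` (anterior superior iliac
spine), ``thigh`` and ``lower_leg``, each contributing ``*_acc_{x,y,z}``
and ``*_gyr_{x,y,z}`` columns.

File dialect
------------
One CSV per trial: ``#``-prefixed header lines carry the trial role,
sampling rate and channel order; the first data column is time in
seconds, followed by the 8 EMG and 18 IMU columns in canonical order.
``covariates.csv`` holds one row per patient with empty cells for missing
values.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

MUSCLES: tuple[str, ...] = (
    "rf_ips", "bf_con", "ra_ips", "ra_con", "io_ips", "io_con", "eo_ips", "eo_con",
)
IMU_SITES: tuple[str, ...] = ("asis", "thigh", "lower_leg")
AXES: tuple[str, ...] = ("x", "y", "z")

#: canonical data-column order of the trial CSV dialect (after the time column)
TRIAL_COLUMNS: tuple[str, ...] = MUSCLES + tuple(
    f"{site}_{kind}_{ax}" for site in IMU_SITES for kind in ("acc", "gyr") for ax in AXES
)

TRIAL_ROLES = ("slr", "normalization")

DEFAULT_FS = 1000.0


class TrialParseError(ValueError):
    """Raised when a trial file violates the documented dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass
class MultichannelTrial:
    """One synchronized multichannel recording (EMG in volts, IMU in g / deg/s)."""

    role: str
    fs: float
    emg: dict[str, np.ndarray]
    imu_acc: dict[str, np.ndarray]  # site -> (n, 3) in g
    imu_gyr: dict[str, np.ndarray]  # site -> (n, 3) in deg/s

    def __post_init__(self):
        if self.role not in TRIAL_ROLES:
            raise ValueError(f"unknown trial role {self.role!r}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        missing = set(MUSCLES) - set(self.emg)
        if missing:
            raise ValueError(f"missing EMG channel(s): {sorted(missing)}")
        extra = set(self.emg) - set(MUSCLES)
        if extra:
            raise ValueError(f"unknown EMG channel(s): {sorted(extra)}")
        for site in IMU_SITES:
            if site not in self.imu_acc or site not in self.imu_gyr:
                raise ValueError(f"missing IMU site {site!r}")
        n = self.n_samples
        for name, series in self.emg.items():
            if len(series) != n:
                raise ValueError(f"channel {name} length {len(series)} != {n}")
        for site in IMU_SITES:
            for kind, d in (("acc", self.imu_acc), ("gyr", self.imu_gyr)):
                arr = np.asarray(d[site])
                if arr.shape != (n, 3):
                    raise ValueError(f"{site} {kind} shape {arr.shape} != ({n}, 3)")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.emg.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def to_frame(self) -> pd.DataFrame:
        """Trial as a DataFrame in canonical column order, with a time column."""
        n = self.n_samples
        data: dict[str, np.ndarray] = {"time": np.arange(n) / self.fs}
        for m in MUSCLES:
            data[m] = np.asarray(self.emg[m], dtype=float)
        for site in IMU_SITES:
            for kind, d in (("acc", self.imu_acc), ("gyr", self.imu_gyr)):
                arr = np.asarray(d[site], dtype=float)
                for j, ax in enumerate(AXES):
                    data[f"{site}_{kind}_{ax}"] = arr[:, j]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, role: str, fs: float) -> "MultichannelTrial":
        emg = {m: frame[m].to_numpy(dtype=float) for m in MUSCLES}
        acc = {
            site: np.column_stack([frame[f"{site}_acc_{ax}"].to_numpy(dtype=float) for ax in AXES])
            for site in IMU_SITES
        }
        gyr = {
            site: np.column_stack([frame[f"{site}_gyr_{ax}"].to_numpy(dtype=float) for ax in AXES])
            for site in IMU_SITES
        }
        return cls(role=role, fs=fs, emg=emg, imu_acc=acc, imu_gyr=gyr)


@dataclass
class PatientRecord:
    """Clinical covariates plus the 3+3 recorded trials for one patient.

    ``uems``/``lems`` are the upper/lower extremity motor scores (0-50 points
    each, ``None`` when missing); ``scim_mobility_indoors`` is item 12 of the
    Spinal Cord Independence Measure (0-8 points) whose value defines the
    walking-dependent (WD, <=3) vs walking-independent (WI, >=4) label.
    """

    patient_id: str
    sex: str  # "M" | "F"
    age: float
    height_cm: float
    weight_kg: float
    total_length_of_stay: float
    days_injury_to_measurement: float
    uems: float | None
    lems: float | None
    scim_mobility_indoors: int
    group: str  # "WD" | "WI"
    slr_trials: list[MultichannelTrial] = field(default_factory=list)
    normalization_trials: list[MultichannelTrial] = field(default_factory=list)
    degraded: bool = False  # explicit flag when fewer than 3 trials of a role exist

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2


@dataclass
class Finding:
    """One validation finding with a severity of ``error`` or ``warning``."""

    severity: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.message}"


def validate_record(record: PatientRecord) -> list[Finding]:
    """Check a patient record against the structural invariants.

    Returns an empty list when the record is well formed.  A missing
    normalization trial is a warning (the cohort this emulates had one
    patient per group without usable bilateral-SLR EMG), while label/score
    inconsistencies are errors.
    """
    findings: list[Finding] = []
    scim = record.scim_mobility_indoors
    if not 0 <= scim <= 8:
        findings.append(Finding("error", f"SCIM Mobility-Indoors score {scim} outside 0-8"))
    expected = "WD" if scim <= 3 else "WI"
    if record.group not in ("WD", "WI"):
        findings.append(Finding("error", f"unknown group label {record.group!r}"))
    elif record.group != expected:
        findings.append(Finding(
            "error",
            f"label/score mismatch: SCIM indoors {scim} implies {expected}, record says {record.group}",
        ))
    for val, name, hi in ((record.uems, "UEMS", 50), (record.lems, "LEMS", 50)):
        if val is not None and not 0 <= val <= hi:
            findings.append(Finding("error", f"{name} {val} outside 0-{hi}"))
    for role, trials in (("slr", record.slr_trials), ("normalization", record.normalization_trials)):
        n = len(trials)
        if n < 3:
            sev = "warning" if record.degraded else "error"
            findings.append(Finding(sev, f"{n} {role} trial(s), expected 3"))
        for i, t in enumerate(trials):
            if t.role != role:
                findings.append(Finding("error", f"{role} trial {i} has role {t.role!r}"))
            if t.duration < 1.0:
                findings.append(Finding("error", f"{role} trial {i} shorter than 1 s"))
    return findings


# ---------------------------------------------------------------------------
# trial CSV dialect


def write_trial(trial: MultichannelTrial, path: str | Path) -> Path:
    """Write a trial in the documented CSV dialect (UTF-8, '.' decimal)."""
    path = Path(path)
    frame = trial.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# slrwalk-trial v1\n")
        fh.write(f"# role: {trial.role}\n")
        fh.write(f"# fs_hz: {trial.fs:g}\n")
        fh.write(",".join(frame.columns) + "\n")
        # 17 significant digits round-trip IEEE doubles exactly
        np.savetxt(fh, frame.to_numpy(), delimiter=",", fmt="%.17g")
    return path


def read_trial(path: str | Path) -> MultichannelTrial:
    """Read a trial CSV, validating header and channel set.

    Raises :class:`TrialParseError` (with a line number) on a missing or
    malformed header, absent channels, or ragged columns.
    """
    path = Path(path)
    header: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lineno = 0
        pos = 0
        for line in fh:
            lineno += 1
            if not line.startswith("#"):
                break
            pos = fh.tell() if not fh.seekable() else pos
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                header[key.strip()] = value.strip()
        else:
            raise TrialParseError("no data rows found", lineno)
    if "role" not in header or "fs_hz" not in header:
        raise TrialParseError("missing '# role:' or '# fs_hz:' header", 1)
    role = header["role"]
    if role not in TRIAL_ROLES:
        raise TrialParseError(f"unknown trial role {role!r}", 2)
    try:
        fs = float(header["fs_hz"])
    except ValueError as exc:
        raise TrialParseError(f"bad fs_hz value {header['fs_hz']!r}", 3) from exc

    n_header = len(header) + 1  # header lines precede the column row
    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise TrialParseError(f"ragged or malformed CSV body: {exc}", n_header + 1) from exc
    expected = ("time",) + TRIAL_COLUMNS
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise TrialParseError(f"absent channel column(s): {missing}", n_header)
    if frame[list(expected)].isna().to_numpy().any():
        bad = int(np.argwhere(frame[list(expected)].isna().to_numpy().any(axis=1))[0][0])
        raise TrialParseError("ragged row (missing values)", n_header + 1 + bad)
    return MultichannelTrial.from_frame(frame, role=role, fs=fs)


# ---------------------------------------------------------------------------
# cohort covariate table

COVARIATE_COLUMNS = (
    "patient_id", "group", "sex", "age", "height_cm", "weight_kg",
    "total_length_of_stay", "days_injury_to_measurement",
    "uems", "lems", "scim_mobility_indoors",
)


def covariates_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id, "group": r.group, "sex": r.sex,
            "age": r.age, "height_cm": r.height_cm, "weight_kg": r.weight_kg,
            "total_length_of_stay": r.total_length_of_stay,
            "days_injury_to_measurement": r.days_injury_to_measurement,
            "uems": r.uems, "lems": r.lems,
            "scim_mobility_indoors": r.scim_mobility_indoors,
        })
    return pd.DataFrame(rows, columns=list(COVARIATE_COLUMNS))


def write_cohort(records: list[PatientRecord], out_dir: str | Path) -> Path:
    """Write one directory per patient (trial CSVs) plus ``covariates.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for r in records:
        pdir = out_dir / r.patient_id
        pdir.mkdir(exist_ok=True)
        for i, t in enumerate(r.slr_trials, 1):
            write_trial(t, pdir / f"slr_{i}.csv")
        for i, t in enumerate(r.normalization_trials, 1):
            write_trial(t, pdir / f"normalization_{i}.csv")
    covariates_frame(records).to_csv(out_dir / "covariates.csv", index=False)
    return out_dir


def read_cohort(in_dir: str | Path) -> list[PatientRecord]:
    """Read a cohort directory written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "covariates.csv")
    records: list[PatientRecord] = []
    for _, row in table.iterrows():
        pdir = in_dir / str(row["patient_id"])
        slr = [read_trial(p) for p in sorted(pdir.glob("slr_*.csv"))]
        norm = [read_trial(p) for p in sorted(pdir.glob("normalization_*.csv"))]
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            sex=str(row["sex"]),
            age=float(row["age"]),
            height_cm=float(row["height_cm"]),
            weight_kg=float(row["weight_kg"]),
            total_length_of_stay=float(row["total_length_of_stay"]),
            days_injury_to_measurement=float(row["days_injury_to_measurement"]),
            uems=None if pd.isna(row["uems"]) else float(row["uems"]),
            lems=None if pd.isna(row["lems"]) else float(row["lems"]),
            scim_mobility_indoors=int(row["scim_mobility_indoors"]),
            group=str(row["group"]),
            slr_trials=slr,
            normalization_trials=norm,
            degraded=len(slr) < 3 or len(norm) < 3,
        ))
    return records
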