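"""EMG conditioning and the two per-muscle features: RMS% and wavelet MDF.

Raw EMG is band-pass filtered to 5-450 Hz with a zero-lag 4th-order
Butterworth.  Amplitude is summarized as the root mean square over
non-overlapping 50-ms windows; activation is normalized to a submaximal
reference — the RMS over the central 3 s of three 5-s bilateral-SLR
trials — and expressed as a percentage (RMS%), 100% meaning activation
equal to the submaximal reference.  The spectral feature is the median
frequency (MDF) of a 20-scale complex-Morlet continuous wavelet
transform (bandwidth and center-frequency parameters 1): squared
coefficient magnitudes are accumulated over the analysis window per
scale and the MDF is the frequency splitting that power in half, with
linear interpolation between adjacent scale frequencies.  Lower MDF is
conventionally read as preferential type-I fiber recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .io import MUSCLES, MultichannelTrial
from .kinematics import AnalysisWindow

EMG_BAND = (5.0, 450.0)
DEFAULT_N_SCALES = 20
#: scale pseudo-frequency range in Hz for the default CWT scale set
DEFAULT_SCALE_RANGE = (10.0, 450.0)
CMOR_WAVELET = "cmor1.0-1.0"  # complex Morlet, bandwidth 1, center frequency 1


class DegenerateReferenceError(ValueError):
    """A muscle's normalization reference RMS is zero (or no trials exist)."""


@dataclass
class ReferenceActivation:
    """Per-muscle submaximal reference RMS in volts."""

    reference: dict[str, float]
    n_trials_used: int


@dataclass
class NormalizedActivation:
    """Per-muscle RMS% (percent of the submaximal reference)."""

    per_trial: dict[str, list[float]]
    average: dict[str, float]


@dataclass
class SpectralFeature:
    """Per-muscle MDF in Hz plus the scale spectrum it came from."""

    mdf: dict[str, float]
    scale_frequencies: np.ndarray
    per_scale_power: dict[str, np.ndarray] = field(default_factory=dict)


def bandpass_emg(series: np.ndarray, fs: float, band: tuple[float, float] = EMG_BAND) -> np.ndarray:
    """Zero-lag 4th-order Butterworth band-pass (default 5-450 Hz)."""
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for the {band[1]} Hz band edge")
    series = np.asarray(series, dtype=float)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, series)


def windowed_rms(series: np.ndarray, fs: float, window_ms: float = 50.0) -> np.ndarray:
    """RMS over consecutive non-overlapping windows (default 50 ms).

    The trailing partial window is discarded so every value summarizes a
    full window.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    w = int(round(window_ms / 1000.0 * fs))
    if w < 1 or len(series) < w:
        raise ValueError(f"series shorter than one {window_ms} ms window")
    n_win = len(series) // w
    chunks = series[: n_win * w].reshape(n_win, w)
    return np.sqrt(np.mean(chunks**2, axis=1))


def reference_rms(
    normalization_trials: list[MultichannelTrial],
    central_s: float = 3.0,
    window_ms: float = 50.0,
    band: tuple[float, float] = EMG_BAND,
) -> ReferenceActivation:
    """Submaximal reference RMS per muscle from the bilateral-SLR trials.

    Per trial: band-pass, windowed RMS over the central ``central_s``
    seconds, mean over windows; the reference is the mean across trials.
    """
    if not normalization_trials:
        raise DegenerateReferenceError("no normalization trials available")
    per_muscle: dict[str, list[float]] = {m: [] for m in MUSCLES}
    for trial in normalization_trials:
        n = trial.n_samples
        n_central = int(round(central_s * trial.fs))
        if n < n_central:
            raise ValueError(f"normalization trial shorter than the central {central_s} s")
        start = (n - n_central) // 2
        for m in MUSCLES:
            conditioned = bandpass_emg(trial.emg[m], trial.fs, band)
            vals = windowed_rms(conditioned[start : start + n_central], trial.fs, window_ms)
            per_muscle[m].append(float(np.mean(vals)))
    reference = {m: float(np.mean(v)) for m, v in per_muscle.items()}
    for m, ref in reference.items():
        if ref <= 0:
            raise DegenerateReferenceError(f"reference RMS for {m} is not positive")
    return ReferenceActivation(reference=reference, n_trials_used=len(normalization_trials))


def normalized_rms(
    slr_trials: list[MultichannelTrial],
    windows: list[AnalysisWindow | None],
    reference: ReferenceActivation,
    window_ms: float = 50.0,
    band: tuple[float, float] = EMG_BAND,
) -> NormalizedActivation:
    """RMS% per muscle: windowed RMS over the analysis window / reference x 100.

    Per trial the value is the mean windowed RMS over the 10-s window
    divided by the muscle's reference; the feature is the mean over
    trials.  Trials whose window is None (no onset) are skipped.
    """
    per_trial: dict[str, list[float]] = {m: [] for m in MUSCLES}
    for trial, window in zip(slr_trials, windows):
        if window is None or window.end_index > trial.n_samples:
            continue
        for m in MUSCLES:
            ref = reference.reference.get(m, 0.0)
            if ref <= 0:
                raise DegenerateReferenceError(f"missing or zero reference for {m}")
            conditioned = bandpass_emg(trial.emg[m], trial.fs, band)
            vals = windowed_rms(conditioned[window.slice()], trial.fs, window_ms)
            per_trial[m].append(float(np.mean(vals) / ref * 100.0))
    average = {m: (float(np.mean(v)) if v else float("nan")) for m, v in per_trial.items()}
    return NormalizedActivation(per_trial=per_trial, average=average)


# ---------------------------------------------------------------------------
# wavelet spectral analysis


def default_scale_frequencies(
    n_scales: int = DEFAULT_N_SCALES,
    freq_range: tuple[float, float] = DEFAULT_SCALE_RANGE,
) -> np.ndarray:
    """Pseudo-frequencies (Hz, ascending) log-spaced over the analysis band."""
    return np.geomspace(freq_range[0], freq_range[1], n_scales)


def frequencies_to_scales(frequencies: np.ndarray, fs: float, wavelet: str = CMOR_WAVELET) -> np.ndarray:
    """Map pseudo-frequencies to CWT scales for the given wavelet."""
    fc = pywt.central_frequency(wavelet)
    return fc * fs / np.asarray(frequencies, dtype=float)


def cwt_power(
    series: np.ndarray,
    fs: float,
    frequencies: np.ndarray | None = None,
    wavelet: str = CMOR_WAVELET,
) -> tuple[np.ndarray, np.ndarray]:
    """Squared CWT coefficient magnitudes per scale and time point.

    Returns ``(power, frequencies)`` with ``power`` of shape
    (n_scales, n_samples) and frequencies ascending in Hz.  The default
    scale set is 20 log-spaced pseudo-frequencies spanning the EMG band.
    """
    series = np.asarray(series, dtype=float)
    if frequencies is None:
        frequencies = default_scale_frequencies()
    frequencies = np.sort(np.asarray(frequencies, dtype=float))
    if frequencies[0] < EMG_BAND[0] or frequencies[-1] > EMG_BAND[1]:
        raise ValueError(
            f"scale frequencies {frequencies[0]:.1f}-{frequencies[-1]:.1f} Hz outside the "
            f"{EMG_BAND[0]:.0f}-{EMG_BAND[1]:.0f} Hz band"
        )
    scales = frequencies_to_scales(frequencies, fs, wavelet)
    coef, _ = pywt.cwt(series, scales, wavelet, sampling_period=1.0 / fs, method="fft")
    # rows follow the given scale order; scales from ascending frequencies are
    # descending, so rows are already in ascending-frequency order
    power = np.abs(coef) ** 2
    return power, frequencies


def median_frequency(per_scale_power: np.ndarray, scale_frequencies: np.ndarray) -> float:
    """Median frequency of a discrete scale spectrum, interpolated.

    ``per_scale_power`` may be (n_scales,) totals or (n_scales, n_time)
    squared amplitudes, which are summed over time first.  Each scale's
    power is treated as mass centred at its pseudo-frequency; the
    cumulative mass curve (midpoint convention) is linearly interpolated
    to find the frequency at which half the total power is reached, so a
    single active scale returns exactly that scale's frequency and two
    equal scales return their midpoint.
    """
    p = np.asarray(per_scale_power, dtype=float)
    if p.ndim == 2:
        p = p.sum(axis=1)
    f = np.asarray(scale_frequencies, dtype=float)
    if len(p) != len(f) or len(p) < 1:
        raise ValueError("power and frequency arrays must have equal nonzero length")
    if np.any(p < 0):
        raise ValueError("negative scale power")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero power: median frequency undefined")
    if len(p) == 1:
        return float(f[0])
    cum_mid = np.cumsum(p) - 0.5 * p
    return float(np.interp(0.5 * total, cum_mid, f))


def spectral_feature(
    slr_trials: list[MultichannelTrial],
    windows: list[AnalysisWindow | None],
    frequencies: np.ndarray | None = None,
    band: tuple[float, float] = EMG_BAND,
) -> SpectralFeature:
    """Per-muscle MDF averaged over trials.

    Per trial and muscle: band-pass the channel, restrict to the analysis
    window, accumulate squared CWT amplitudes over the window per scale,
    and take the median frequency; the feature is the mean over trials.
    """
    if frequencies is None:
        frequencies = default_scale_frequencies()
    per_muscle: dict[str, list[float]] = {m: [] for m in MUSCLES}
    total_power: dict[str, np.ndarray] = {}
    for trial, window in zip(slr_trials, windows):
        if window is None or window.end_index > trial.n_samples:
            continue
        for m in MUSCLES:
            conditioned = bandpass_emg(trial.emg[m], trial.fs, band)
            power, freqs = cwt_power(conditioned[window.slice()], trial.fs, frequencies)
            scale_power = power.sum(axis=1)
            per_muscle[m].append(median_frequency(scale_power, freqs))
            total_power[m] = total_power.get(m, 0.0) + scale_power
    mdf = {m: (float(np.mean(v)) if v else float("nan")) for m, v in per_muscle.items()}
    return SpectralFeature(mdf=mdf, scale_frequencies=np.asarray(frequencies), per_scale_power=total_power)
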