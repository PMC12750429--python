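import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram

from slrwalk.emg import (
    DegenerateReferenceError,
    bandpass_emg,
    cwt_power,
    default_scale_frequencies,
    median_frequency,
    normalized_rms,
    reference_rms,
    spectral_feature,
    windowed_rms,
)
from slrwalk.io import MUSCLES
from slrwalk.kinematics import AnalysisWindow
from slrwalk.synthetic import CohortConfig, generate_feature_table, synthesize_emg_channel


class TestBandpass:
    def test_dc_offset_rejected(self):
        out = bandpass_emg(np.ones(3000), 1000.0)
        assert np.abs(out[500:-500]).max() < 1e-6

    def test_passband_sinusoid_amplitude_within_one_percent(self):
        t = np.arange(0, 5, 1e-3)
        y = bandpass_emg(np.sin(2 * np.pi * 100 * t), 1000.0)
        amp = np.sqrt(2 * np.mean(y[1000:4000] ** 2))
        assert amp == pytest.approx(1.0, abs=0.01)

    def test_stopband_edge_attenuated(self):
        t = np.arange(0, 5, 1e-3)
        y = bandpass_emg(np.sin(2 * np.pi * 480 * t), 1000.0)
        amp = np.sqrt(2 * np.mean(y[1000:4000] ** 2))
        assert amp < 0.1

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            bandpass_emg(np.zeros(1000), 900.0)


class TestWindowedRMS:
    def test_constant_signal_gives_constant_rms(self):
        vals = windowed_rms(np.full(500, -3.0), 1000.0)
        np.testing.assert_allclose(vals, 3.0)
        assert len(vals) == 10

    def test_unit_sinusoid_integer_cycles_gives_inverse_sqrt_two(self):
        # 5 cycles of 100 Hz fit exactly in one 50-ms window
        t = np.arange(0, 0.5, 1e-3)
        vals = windowed_rms(np.sin(2 * np.pi * 100 * t), 1000.0)
        np.testing.assert_allclose(vals, 1 / np.sqrt(2), rtol=1e-6)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_single_window_matches_brute_force(self, seed):
        x = np.random.default_rng(seed).standard_normal(50)
        val = windowed_rms(x, 1000.0)
        assert len(val) == 1
        assert val[0] == pytest.approx(np.sqrt(np.sum(x**2) / 50), rel=1e-12)

    def test_trailing_partial_window_discarded(self):
        assert len(windowed_rms(np.ones(125), 1000.0)) == 2

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            windowed_rms(np.array([]), 1000.0)


def _emg_trial(amplitudes: dict, duration=5.0, fs=1000.0, role="normalization", seed=0):
    """Trial whose channels are synthetic EMG at the given RMS amplitudes."""
    from slrwalk.io import MultichannelTrial

    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    emg = {m: synthesize_emg_channel(duration, fs, amplitudes.get(m, 1.0), 100.0, rng)
           for m in MUSCLES}
    zeros = {s: np.zeros((n, 3)) for s in ("asis", "thigh", "lower_leg")}
    return MultichannelTrial(role=role, fs=fs, emg=emg, imu_acc=zeros,
                             imu_gyr={s: np.zeros((n, 3)) for s in zeros})


class TestReferenceRMS:
    def test_three_equal_trials_give_their_rms(self):
        trials = [_emg_trial({m: 2.0 for m in MUSCLES}, seed=s) for s in range(3)]
        ref = reference_rms(trials)
        for m in MUSCLES:
            # short-window RMS of narrowband noise carries a small downward
            # bias (few degrees of freedom per 50-ms window); it cancels in
            # the normalized percentage downstream
            assert ref.reference[m] == pytest.approx(2.0, rel=0.10)
        assert ref.n_trials_used == 3

    def test_reference_is_mean_across_trials(self):
        trials = [_emg_trial({m: a for m in MUSCLES}, seed=1) for a in (1.0, 2.0, 3.0)]
        ref = reference_rms(trials)
        for m in MUSCLES:
            assert ref.reference[m] == pytest.approx(2.0, rel=0.10)

    def test_silent_channel_raises_degenerate_reference(self):
        trials = [_emg_trial({"eo_con": 0.0}, seed=2)]
        with pytest.raises(DegenerateReferenceError, match="eo_con"):
            reference_rms(trials)

    def test_no_trials_raises(self):
        with pytest.raises(DegenerateReferenceError):
            reference_rms([])


class TestNormalizedRMS:
    def _window(self):
        return AnalysisWindow(0, 3000)

    def test_activation_equal_to_reference_reads_100_percent(self):
        norm = [_emg_trial({m: 1.0 for m in MUSCLES}, seed=s) for s in range(3)]
        ref = reference_rms(norm)
        slr = [_emg_trial({m: 1.0 for m in MUSCLES}, duration=3.0, role="slr", seed=9)]
        act = normalized_rms(slr, [self._window()], ref)
        for m in MUSCLES:
            assert act.average[m] == pytest.approx(100.0, rel=0.05)

    def test_double_amplitude_reads_200_percent(self):
        norm = [_emg_trial({m: 1.0 for m in MUSCLES}, seed=s) for s in range(3)]
        ref = reference_rms(norm)
        slr = [_emg_trial({m: 2.0 for m in MUSCLES}, duration=3.0, role="slr", seed=9)]
        act = normalized_rms(slr, [self._window()], ref)
        for m in MUSCLES:
            assert act.average[m] == pytest.approx(200.0, rel=0.02 + 0.05)

    def test_zero_signal_trial_reads_zero_percent(self):
        norm = [_emg_trial({m: 1.0 for m in MUSCLES}, seed=s) for s in range(3)]
        ref = reference_rms(norm)
        slr = [_emg_trial({m: 0.0 for m in MUSCLES}, duration=3.0, role="slr", seed=9)]
        act = normalized_rms(slr, [self._window()], ref)
        for m in MUSCLES:
            assert act.average[m] == pytest.approx(0.0, abs=1e-9)

    def test_common_rescaling_leaves_percentage_unchanged(self):
        # scale equivariance: scaling task and reference signals together
        norm = [_emg_trial({m: 1.0 for m in MUSCLES}, seed=s) for s in range(3)]
        slr = [_emg_trial({m: 1.7 for m in MUSCLES}, duration=3.0, role="slr", seed=9)]
        act1 = normalized_rms(slr, [self._window()], reference_rms(norm))
        k = 3.3

        def scaled(trial):
            return dataclasses.replace(
                trial, emg={m: k * v for m, v in trial.emg.items()})

        act2 = normalized_rms([scaled(t) for t in slr], [self._window()],
                              reference_rms([scaled(t) for t in norm]))
        for m in MUSCLES:
            assert act2.average[m] == pytest.approx(act1.average[m], rel=1e-9)


class TestCWT:
    def test_zero_series_gives_zero_power(self):
        power, _ = cwt_power(np.zeros(2000), 1000.0)
        assert not np.any(power)

    def test_tone_at_scale_frequency_peaks_at_that_scale(self):
        freqs = default_scale_frequencies()
        t = np.arange(0, 2, 1e-3)
        for k in (8, 12, 15):
            power, f = cwt_power(np.sin(2 * np.pi * freqs[k] * t), 1000.0)
            assert np.argmax(power.sum(axis=1)) == k

    def test_total_power_is_quadratic_in_amplitude(self, rng):
        x = rng.standard_normal(1500)
        p1, _ = cwt_power(x, 1000.0)
        p2, _ = cwt_power(2.0 * x, 1000.0)
        np.testing.assert_allclose(p2, 4.0 * p1, rtol=1e-9)

    def test_scales_outside_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            cwt_power(np.zeros(100), 1000.0, frequencies=np.array([2.0, 100.0]))


class TestMedianFrequency:
    def test_single_active_scale_returns_its_frequency(self):
        p = np.zeros(20)
        p[7] = 5.0
        freqs = default_scale_frequencies()
        assert median_frequency(p, freqs) == pytest.approx(freqs[7])

    def test_two_equal_scales_interpolate_to_midpoint(self):
        assert median_frequency(np.array([1.0, 1.0]), np.array([50.0, 150.0])) == \
            pytest.approx(100.0)

    def test_all_zero_power_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            median_frequency(np.zeros(20), default_scale_frequencies())

    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_amplitude_invariance_is_exact(self, seed, k):
        x = np.random.default_rng(seed).standard_normal(1024)
        p1, f = cwt_power(x, 1000.0)
        p2, _ = cwt_power(k * x, 1000.0)
        assert median_frequency(p2, f) == pytest.approx(median_frequency(p1, f), rel=1e-12)

    def test_cwt_mdf_tracks_fourier_oracle_on_synthetic_emg(self):
        for centroid, seed in ((80.0, 1), (120.0, 2), (200.0, 3)):
            x = synthesize_emg_channel(10.0, 1000.0, 1.0, centroid, seed)
            f, pxx = periodogram(x, fs=1000.0)
            cum = np.cumsum(pxx)
            mdf_fourier = f[np.searchsorted(cum, cum[-1] / 2)]
            power, freqs = cwt_power(x, 1000.0)
            mdf_cwt = median_frequency(power, freqs)
            assert abs(mdf_cwt - mdf_fourier) / mdf_fourier < 0.15


def test_increasing_eo_gain_increases_cohort_mean_activation():
    base = CohortConfig(n_per_group=30, seed=6)
    boosted = CohortConfig(n_per_group=30, seed=6)
    boosted.emg.gains = {g: dict(v) for g, v in base.emg.gains.items()}
    boosted.emg.gains["WD"]["eo_con"] *= 1.5
    t0 = generate_feature_table(base)
    t1 = generate_feature_table(boosted)
    wd0 = t0[t0.group == "WD"].rms_eo_con.mean()
    wd1 = t1[t1.group == "WD"].rms_eo_con.mean()
    assert wd1 > wd0


def test_spectral_feature_averages_over_trials(small_cohort):
    records, truth, _ = small_cohort
    rec = records[0]
    windows = [AnalysisWindow(1500, 11500)] * 3
    feat = spectral_feature(rec.slr_trials, windows)
    gt = truth.patients[rec.patient_id].emg_centroid
    for m in MUSCLES:
        assert abs(feat.mdf[m] - gt[m]) / gt[m] < 0.20
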