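"""Modulation strength (SNR), frequency (matching pursuit), polarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taumod import (
    CouplingSpec,
    LagGrid,
    Recording,
    TMCSeries,
    extract_band_pair,
    generate_channel_signal,
    matching_pursuit,
    modulation_frequency,
    modulation_polarity,
    normalize_strength,
    strength_series,
    strength_snr,
)
from taumod.features import default_dictionary
from taumod.tmc import tmc_series

GRID = LagGrid()
TAU = GRID.lags_s
FREQ_RES = 1.0 / (2.56 * 4)  # dictionary frequency step


def series_from_R(R):
    R = np.asarray(R, dtype=float)
    times = np.arange(R.shape[0]) * 0.2
    return TMCSeries(R=R, window_times_s=times)


def null_strength(waveform, seed, duration_s=120.0):
    comp = generate_channel_signal(
        CouplingSpec(depth=0.0, mod_freq_hz=1.0, waveform=waveform),
        duration_s,
        1000.0,
        seed=seed,
        return_components=True,
    )
    pair = extract_band_pair(Recording(samples=comp.signal[np.newaxis, :], fs_hz=1000.0))
    _, raw = strength_series(tmc_series(pair))
    return float(np.nanmean(raw))


class TestStrengthSnr:
    def test_hand_computed_two_by_two_stack(self):
        # pooled population variance of {0,1,1,0} = 0.25; per-lag variances
        # 0.25 and 0.25 -> SNR exactly 1
        assert strength_snr(np.array([[0.0, 1.0], [1.0, 0.0]])) == pytest.approx(
            1.0, abs=1e-15
        )

    def test_iid_noise_calibrates_to_one(self):
        rng = np.random.default_rng(0)
        vals = [strength_snr(rng.standard_normal((25, 64))) for _ in range(100)]
        assert 0.9 <= np.mean(vals) <= 1.1

    def test_identical_tmcs_degenerate(self):
        tmc = np.random.default_rng(0).standard_normal(64)
        assert np.isnan(strength_snr(np.tile(tmc, (25, 1))))

    def test_excessive_nans_yield_nan(self):
        stack = np.random.default_rng(0).standard_normal((25, 64))
        stack[:8] = np.nan  # 32% NaN
        assert np.isnan(strength_snr(stack))

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(a=st.floats(0.01, 50.0), b=st.floats(-10.0, 10.0))
    def test_affine_invariance(self, a, b):
        stack = np.random.default_rng(1).standard_normal((25, 64))
        assert strength_snr(a * stack + b) == pytest.approx(strength_snr(stack))

    def test_monotone_in_coupling_depth(self):
        means = []
        for depth in (0.0, 0.25, 0.5, 0.75, 1.0):
            comp = generate_channel_signal(
                CouplingSpec(depth=depth, mod_freq_hz=1.0),
                90.0,
                1000.0,
                seed=21,
                return_components=True,
            )
            pair = extract_band_pair(
                Recording(samples=comp.signal[np.newaxis, :], fs_hz=1000.0)
            )
            _, raw = strength_series(tmc_series(pair))
            means.append(np.nanmean(raw))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_nonsinusoidal_null_matches_sinusoidal_null(self):
        """A sharp sawtooth slow wave with independent gamma must not inflate
        the strength statistic beyond its sinusoidal-null level."""
        saw = null_strength("sawtooth", seed=4)
        sin = null_strength("sinusoid", seed=4)
        assert abs(saw - sin) / sin < 0.25


class TestNormalizeStrength:
    def test_series_equal_to_baseline_standardized(self):
        rng = np.random.default_rng(0)
        t = np.arange(100) * 0.2
        raw = rng.standard_normal(100) + 5.0
        z = normalize_strength(t, raw, (0.0, 100.0))
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z) == pytest.approx(1.0, abs=1e-12)

    def test_constant_baseline_rejected(self):
        t = np.arange(100) * 0.2
        with pytest.raises(ValueError, match="constant"):
            normalize_strength(t, np.ones(100), (0.0, 100.0))

    def test_short_baseline_rejected(self):
        t = np.arange(100) * 0.2
        raw = np.random.default_rng(0).standard_normal(100)
        with pytest.raises(ValueError, match="baseline"):
            normalize_strength(t, raw, (0.0, 2.0))


class TestMatchingPursuit:
    def test_dictionary_atom_recovered_exactly(self):
        d = default_dictionary(GRID)
        i = 20000
        x = 0.7 * (np.cos(0.4) * d.Qc[i] + np.sin(0.4) * d.Qs[i])
        atoms = matching_pursuit(x, dictionary=d)
        a = atoms[0]
        assert a.center_time_s == d.t0[i]
        assert a.center_freq_hz == d.freq[i]
        assert a.spread_s == d.spread[i]
        # residual below 1% of input energy
        recon = a.amplitude * (
            np.cos(a.phase_rad) * d.Qc[i] + np.sin(a.phase_rad) * d.Qs[i]
        )
        assert np.sum((x - recon) ** 2) < 0.01 * np.sum(x**2)

    def test_cosine_frequency_within_dictionary_resolution(self):
        atoms = matching_pursuit(np.cos(2 * np.pi * 1.0 * TAU))
        osc = [a for a in atoms if a.center_freq_hz >= 0.2]
        assert abs(osc[0].center_freq_hz - 1.0) <= FREQ_RES + 1e-12

    def test_constant_offset_has_no_oscillatory_atom(self):
        atoms = matching_pursuit(np.full(64, 2.5))
        assert all(a.center_freq_hz < 0.2 for a in atoms)

    def test_all_zero_input_empty(self):
        assert matching_pursuit(np.zeros(64)) == []

    def test_residual_energy_non_increasing(self):
        d = default_dictionary(GRID)
        rng = np.random.default_rng(3)
        x = rng.standard_normal(64)
        atoms = matching_pursuit(x, dictionary=d, max_atoms=8, residual_tol=0.0)
        r = x.copy()
        energies = [float(r @ r)]
        for a in atoms:
            env = (
                np.exp(-((TAU - a.center_time_s) ** 2) / (2 * a.spread_s**2))
                if np.isfinite(a.spread_s)
                else np.ones(64)
            )
            arg = 2 * np.pi * a.center_freq_hz * (TAU - a.center_time_s)
            r = r - a.amplitude * (
                np.cos(a.phase_rad) * env * np.cos(arg)
                + np.sin(a.phase_rad) * env * np.sin(arg)
            )
            energies.append(float(r @ r))
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))


class TestModulationFrequency:
    def test_cosine_stack_recovers_one_hertz(self):
        R = np.tile(np.cos(2 * np.pi * 1.0 * TAU) * 0.5, (30, 1))
        R += np.random.default_rng(0).normal(0, 0.01, R.shape)
        _, f = modulation_frequency(series_from_R(R))
        assert np.nanmedian(f) == pytest.approx(1.0, abs=FREQ_RES + 1e-12)

    def test_linear_ramp_yields_nan(self):
        R = np.tile(np.linspace(-0.5, 0.5, 64), (30, 1))
        _, f = modulation_frequency(series_from_R(R))
        assert np.isnan(f).all()

    def test_invalid_tmcs_yield_nan(self):
        R = np.tile(np.cos(2 * np.pi * TAU), (30, 1))
        R[10] = np.nan
        _, f = modulation_frequency(series_from_R(R))
        assert np.isnan(f[: 10 + 1]).all()  # windows containing row 10


class TestModulationPolarity:
    def test_positive_cosine_is_peak_max(self):
        R = np.tile(0.4 * np.cos(2 * np.pi * 1.0 * TAU), (30, 1))
        _, p = modulation_polarity(series_from_R(R))
        assert (p == 1.0).all()

    def test_negative_cosine_is_trough_max(self):
        R = np.tile(-0.4 * np.cos(2 * np.pi * 1.0 * TAU), (30, 1))
        _, p = modulation_polarity(series_from_R(R))
        assert (p == -1.0).all()

    def test_linear_trend_removed_before_sign(self):
        R = np.tile(0.4 * np.cos(2 * np.pi * 1.0 * TAU) + 0.3 * TAU, (30, 1))
        _, p = modulation_polarity(series_from_R(R))
        assert (p == 1.0).all()

    def test_all_nan_window_yields_nan(self):
        R = np.full((30, 64), np.nan)
        _, p = modulation_polarity(series_from_R(R))
        assert np.isnan(p).all()
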