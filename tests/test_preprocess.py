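"""Referencing, FIR filtering, Hilbert envelopes, decimation, band extraction."""

import numpy as np
import pytest
from scipy import signal as sps

from taumod import (
    Recording,
    analytic_envelope,
    common_average_reference,
    extract_band_pair,
    fir_filter,
    resample_to,
)

FS = 1000.0


def interior(x, frac=0.2):
    n = len(x)
    return x[int(n * frac) : int(n * (1 - frac))]


def tone(freq, dur=30.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestCommonAverageReference:
    def test_identical_channels_become_zero(self):
        x = np.random.default_rng(0).standard_normal(1000)
        rec = Recording(samples=np.tile(x, (4, 1)), fs_hz=FS)
        assert np.allclose(common_average_reference(rec).samples, 0.0)

    def test_antisymmetric_pair_unchanged(self):
        x = np.random.default_rng(0).standard_normal(1000)
        rec = Recording(samples=np.vstack([x, -x]), fs_hz=FS)
        assert np.allclose(common_average_reference(rec).samples, rec.samples)

    def test_output_channel_mean_is_zero(self):
        rng = np.random.default_rng(1)
        rec = Recording(samples=rng.standard_normal((5, 2000)), fs_hz=FS)
        out = common_average_reference(rec)
        assert np.allclose(out.samples.mean(axis=0), 0.0, atol=1e-12)

    def test_single_channel_rejected(self):
        rec = Recording(samples=np.zeros((1, 1000)), fs_hz=FS)
        with pytest.raises(ValueError):
            common_average_reference(rec)


class TestFirFilter:
    def test_passband_tone_amplitude_preserved(self):
        y = fir_filter(tone(1.0), FS, "bandpass", 0.2, 4.0)
        env = np.abs(sps.hilbert(y))
        assert np.allclose(interior(env, 0.3), 1.0, atol=0.05)

    def test_bandstop_attenuates_line_frequency(self):
        y = fir_filter(tone(50.0), FS, "bandstop", 48.0, 52.0)
        rms_out = interior(y).std()
        assert 20 * np.log10(rms_out / tone(50.0).std()) < -20

    def test_zero_input_zero_output(self):
        assert np.allclose(fir_filter(np.zeros(20000), FS, "bandpass", 0.2, 4.0), 0.0)

    def test_output_length_equals_input_length(self):
        x = np.random.default_rng(0).standard_normal(12345)
        assert fir_filter(x, FS, "bandpass", 1.0, 10.0).shape == x.shape

    def test_band_edges_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            fir_filter(np.zeros(10000), FS, "bandpass", 100.0, 600.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            fir_filter(np.zeros(50), FS, "bandpass", 0.2, 4.0)

    def test_nan_input_rejected(self):
        x = np.zeros(10000)
        x[5] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fir_filter(x, FS, "bandpass", 0.2, 4.0)

    def test_shift_covariance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(20000)
        d = 250
        y = fir_filter(x, FS, "bandpass", 1.0, 10.0)
        y_shifted_input = fir_filter(np.roll(x, d), FS, "bandpass", 1.0, 10.0)
        core = slice(5000, 15000)
        assert np.allclose(y_shifted_input[core], np.roll(y, d)[core], atol=1e-8)


class TestAnalyticEnvelope:
    def test_constant_tone_envelope(self):
        env = analytic_envelope(tone(100.0, dur=10.0))
        assert np.allclose(interior(env, 0.1), 1.0, atol=0.01)

    def test_am_tone_envelope_tracks_modulator(self):
        t = np.arange(int(10.0 * FS)) / FS
        mod = 1.0 + 0.5 * np.cos(2 * np.pi * 1.0 * t)
        env = analytic_envelope(mod * np.sin(2 * np.pi * 100.0 * t))
        err = np.abs(interior(env, 0.1) - interior(mod, 0.1))
        assert err.max() < 0.05

    def test_zero_signal_zero_envelope(self):
        assert np.allclose(analytic_envelope(np.zeros(1000)), 0.0)

    def test_nan_rejected(self):
        x = np.zeros(100)
        x[0] = np.nan
        with pytest.raises(ValueError):
            analytic_envelope(x)


class TestResample:
    def test_length_ratio(self):
        y, _ = resample_to(np.zeros(40000), 1000.0, 25.0)
        assert y.shape == (1000,)

    def test_slow_tone_amplitude_preserved(self):
        y, n_edge = resample_to(tone(1.0, dur=40.0), 1000.0, 25.0)
        env = np.abs(sps.hilbert(y[n_edge:-n_edge]))
        assert np.allclose(interior(env, 0.2), 1.0, atol=0.02)

    def test_aliasing_suppressed(self):
        # 20 Hz would alias to 5 Hz at 25 Hz output; it must be filtered out
        y, n_edge = resample_to(tone(20.0, dur=40.0), 1000.0, 25.0)
        rms = y[n_edge:-n_edge].std()
        assert 20 * np.log10(rms / tone(20.0).std()) < -40

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample_to(np.zeros(1000), 1000.0, 1000.0)
        with pytest.raises(ValueError):
            resample_to(np.zeros(1000), 25.0, 1000.0)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            resample_to(np.zeros(1000), 1000.0, 30.0)


class TestExtractBandPair:
    def test_default_output_rate_is_25(self, coupled_band_pair):
        assert coupled_band_pair.rate_hz == 25.0
        n_in = 90 * 1000
        assert coupled_band_pair.n_times == n_in // 40

    def test_gamma_envelope_non_negative(self, coupled_band_pair):
        assert (coupled_band_pair.gamma_env >= 0).all()

    def test_coupled_channel_zero_shift_correlation(self, coupled_band_pair):
        ok = ~coupled_band_pair.edge_mask
        r = np.corrcoef(
            coupled_band_pair.slow[0][ok], coupled_band_pair.gamma_env[0][ok]
        )[0, 1]
        assert r > 0.3

    def test_band_separation_crosstalk(self):
        # one component per band: each output should recover only its own band
        t = np.arange(int(60.0 * FS)) / FS
        slow_true = 50.0 * np.sin(2 * np.pi * 1.0 * t)
        fast = 20.0 * np.sin(2 * np.pi * 100.0 * t)
        rec = Recording(samples=(slow_true + fast)[np.newaxis, :], fs_hz=FS)
        pair = extract_band_pair(rec)
        ok = ~pair.edge_mask
        slow_ref = slow_true[::40][ok]
        resid = pair.slow[0][ok] - slow_ref
        assert resid.std() / slow_ref.std() < 0.01
        # gamma envelope ~ constant 20 uV (the tone's amplitude)
        assert np.allclose(pair.gamma_env[0][ok], 20.0, rtol=0.05)

    def test_too_short_recording_rejected(self):
        rec = Recording(samples=np.zeros((1, 5000)), fs_hz=FS)
        with pytest.raises(ValueError):
            extract_band_pair(rec)
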