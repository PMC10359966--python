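"""Synthetic-data generator: determinism, coupling structure, waveforms."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import signal as sps

from taumod import (
    CouplingSpec,
    SessionSpec,
    StageSpec,
    generate_channel_signal,
    generate_session,
)


def lagged_pearson(slow, env, max_lag, step):
    """Direct Pearson between slow and envelope at lags -max_lag..max_lag."""
    out = {}
    for lag in range(-max_lag, max_lag + 1, step):
        if lag >= 0:
            a, b = slow[: len(slow) - lag], env[lag:]
        else:
            a, b = slow[-lag:], env[: len(env) + lag]
        out[lag] = np.corrcoef(a, b)[0, 1]
    return out


def realized_envelope(comp):
    return np.abs(sps.hilbert(comp.gamma))


class TestChannelSignal:
    def test_deterministic_for_fixed_seed(self):
        spec = CouplingSpec(depth=0.5)
        a = generate_channel_signal(spec, 20.0, 1000.0, seed=3)
        b = generate_channel_signal(spec, 20.0, 1000.0, seed=3)
        assert np.array_equal(a, b)
        c = generate_channel_signal(spec, 20.0, 1000.0, seed=4)
        assert not np.array_equal(a, c)

    def test_depth_zero_gamma_envelope_independent_of_slow(self):
        comp = generate_channel_signal(
            CouplingSpec(depth=0.0), 60.0, 1000.0, seed=0, return_components=True
        )
        r = lagged_pearson(comp.slow, realized_envelope(comp), 1280, 40)
        assert max(abs(v) for v in r.values()) < 0.1

    @pytest.mark.parametrize("waveform", ["sinusoid", "asymmetric", "sawtooth"])
    def test_slow_component_fundamental_at_mod_freq(self, waveform):
        comp = generate_channel_signal(
            CouplingSpec(depth=0.0, mod_freq_hz=1.0, waveform=waveform),
            60.0,
            1000.0,
            seed=3,
            return_components=True,
        )
        f, p = sps.periodogram(comp.slow, fs=1000.0)
        assert abs(f[np.argmax(p)] - 1.0) <= f[1] - f[0] + 1e-12

    def test_sawtooth_carries_harmonics_sinusoid_does_not(self):
        power = {}
        for waveform in ("sawtooth", "sinusoid"):
            comp = generate_channel_signal(
                CouplingSpec(depth=0.0, mod_freq_hz=1.0, waveform=waveform),
                60.0,
                1000.0,
                seed=3,
                return_components=True,
            )
            f, p = sps.periodogram(comp.slow, fs=1000.0)
            power[waveform] = [
                p[(f > k - 0.2) & (f < k + 0.2)].max() for k in (1, 2, 3)
            ]
        p1, p2, p3 = power["sawtooth"]
        assert p2 > 0.05 * p1 and p3 > 0.02 * p1
        q1, q2, q3 = power["sinusoid"]
        assert q2 < 1e-3 * q1 and q3 < 1e-3 * q1

    def test_coupling_monotone_in_depth(self):
        r0 = []
        for depth in (0.0, 0.25, 0.5, 0.75, 1.0):
            comp = generate_channel_signal(
                CouplingSpec(depth=depth), 60.0, 1000.0, seed=9, return_components=True
            )
            r0.append(
                abs(np.corrcoef(comp.slow, realized_envelope(comp))[0, 1])
            )
        assert all(b > a for a, b in zip(r0, r0[1:]))

    def test_polarity_flip_negates_coupling_correlation(self):
        r = {}
        for pol in (1, -1):
            comp = generate_channel_signal(
                CouplingSpec(depth=0.8, polarity=pol),
                60.0,
                1000.0,
                seed=9,
                return_components=True,
            )
            r[pol] = np.corrcoef(comp.slow, realized_envelope(comp))[0, 1]
        assert r[1] > 0.3 and r[-1] < -0.3
        assert abs(r[1] + r[-1]) < 0.1

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            CouplingSpec(depth=1.5)
        with pytest.raises(ValueError):
            CouplingSpec(polarity=0)
        with pytest.raises(ValueError):
            CouplingSpec(lag_s=2.0)
        with pytest.raises(ValueError):
            CouplingSpec(mod_freq_hz=-1.0)
        with pytest.raises(ValueError):
            generate_channel_signal(CouplingSpec(), 5.0, 1000.0)
        with pytest.raises(ValueError):
            generate_channel_signal(CouplingSpec(), 20.0, 100.0)


def two_stage_spec(seed=0, **anesthetized_kwargs):
    base = CouplingSpec(depth=0.0, slow_amp_uv=25.0)
    anesthetized = replace(
        CouplingSpec(slow_amp_uv=100.0), **anesthetized_kwargs
    )
    return SessionSpec(
        stages=[
            StageSpec("awake_eyes_covered", 30.0, base),
            StageSpec("anesthetized", 60.0, anesthetized),
        ],
        seed=seed,
    )


class TestSession:
    def test_same_seed_identical_recording(self):
        spec = two_stage_spec(seed=5, depth=0.7)
        rec1, gt1 = generate_session(spec)
        rec2, gt2 = generate_session(spec)
        assert np.array_equal(rec1.samples, rec2.samples)
        assert gt1.equals(gt2)

    def test_markers_and_intervals_at_stage_boundaries(self):
        rec, _ = generate_session(two_stage_spec(depth=0.5))
        assert ("awake_eyes_covered", 0.0) in rec.markers
        assert ("anesthetized", 30.0) in rec.markers
        assert rec.condition_intervals["anesthetized"] == (30.0, 90.0)

    def test_anesthetized_interval_coupling_positive(self):
        spec = two_stage_spec(seed=2, depth=0.8, polarity=1, lag_s=0.0)
        rec, gt, comps = generate_session(spec, return_components=True)
        lo, hi = rec.condition_intervals["anesthetized"]
        sl = slice(int((lo + 10) * 1000), int((hi - 5) * 1000))
        c = comps[0]
        r = np.corrcoef(c.slow[sl], c.gamma_env[sl])[0, 1]
        assert r > 0.3

    def test_onset_delays_echoed_in_ground_truth(self):
        base = CouplingSpec(depth=0.5)
        spec = SessionSpec(
            stages=[StageSpec("anesthetized", 30.0, base)],
            n_channels=4,
            onset_delays_s=(0.0, 60.0, 120.0, 180.0),
            seed=1,
        )
        _, gt = generate_session(spec)
        assert list(gt.groupby("channel")["onset_s"].first()) == [0.0, 60.0, 120.0, 180.0]

    def test_overlapping_stages_rejected(self):
        base = CouplingSpec()
        with pytest.raises(ValueError, match="overlap"):
            SessionSpec(
                stages=[
                    StageSpec("a", 30.0, base, start_s=0.0),
                    StageSpec("b", 30.0, base, start_s=10.0),
                ]
            )

    def test_grid_coordinates_shape(self):
        spec = two_stage_spec()
        spec.n_channels = 4
        xy = spec.grid_xy_mm()
        assert xy.shape == (4, 2)
        assert np.ptp(xy[:, 0]) == 5.0
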