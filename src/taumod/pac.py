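"""Conventional phase-amplitude coupling baseline (Canolty modulation index).

The classic three-step recipe: narrowband-filter the slow wave, extract its
phase by Hilbert transform, and quantify coupling to a fast amplitude series
as the magnitude of the time-averaged composite ``A(t) * exp(i * phi(t))``.
Included as the comparison method: unlike the tau-modulation statistic it
relies on a narrowband phase estimate, which is the step that makes it
susceptible to spurious coupling for non-sinusoidal slow waves.

Significance is assessed against a circular time-shift surrogate null, which
preserves the amplitude autocorrelation while destroying the phase-amplitude
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import fir_filter

__all__ = ["PACResult", "canolty_mi", "slow_wave_phase"]


@dataclass(frozen=True)
class PACResult:
    """Modulation index with its surrogate statistics."""

    mi: float
    preferred_phase_rad: float
    surrogate_z: float
    surrogate_mean: float
    surrogate_sd: float
    n_surrogates: int


def slow_wave_phase(
    x: np.ndarray,
    fs_hz: float,
    band_hz: tuple[float, float] = (0.2, 4.0),
) -> np.ndarray:
    """Instantaneous slow-wave phase (radians) via narrowband Hilbert."""
    slow = fir_filter(x, fs_hz, "bandpass", *band_hz)
    return np.angle(sps.hilbert(slow))


def canolty_mi(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_surrogates: int = 200,
    seed: int | np.random.Generator = 0,
    min_shift: int = 1,
) -> PACResult:
    """Canolty-style modulation index with a time-shift surrogate z-score.

    Parameters
    ----------
    phase : phase series in radians.
    amplitude : non-negative amplitude series, same length.
    n_surrogates : number of circular time-shifts for the null.
    min_shift : smallest allowed circular shift in samples (keep >= one
        slow-wave cycle to avoid residual alignment).
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape or phase.ndim != 1:
        raise ValueError("phase and amplitude must be equal-length 1-D series")
    if not (np.isfinite(phase).all() and np.isfinite(amplitude).all()):
        raise ValueError("phase and amplitude must be finite")
    if (amplitude < 0).any():
        raise ValueError("amplitude must be non-negative")

    z = amplitude * np.exp(1j * phase)
    mean_z = z.mean()
    mi = float(np.abs(mean_z))
    pref = float(np.angle(mean_z))

    if amplitude.max() == 0.0:
        return PACResult(0.0, 0.0, float("nan"), float("nan"), float("nan"), 0)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = phase.size
    if n_surrogates > 0 and n > 2 * min_shift:
        shifts = rng.integers(min_shift, n - min_shift, size=n_surrogates)
        e = np.exp(1j * phase)
        sur = np.empty(n_surrogates)
        for i, s in enumerate(shifts):
            sur[i] = np.abs(np.roll(amplitude, int(s)) @ e) / n
        mu, sd = float(sur.mean()), float(sur.std())
        zscore = (mi - mu) / sd if sd > 0 else float("nan")
    else:
        mu = sd = zscore = float("nan")
        n_surrogates = 0
    return PACResult(mi, pref, float(zscore), mu, sd, int(n_surrogates))
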