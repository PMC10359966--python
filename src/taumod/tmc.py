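"""Tau-modulation curves: lagged Pearson correlation of band envelopes.

A tau-modulation curve (TMC) is the vector of Pearson correlation
coefficients R(tau) between a 2.56 s Hamming-windowed slow-wave segment and
the broadband-gamma envelope shifted by each lag tau on a 64-point grid
covering -1.28 s ... +1.24 s at the 25 Hz feature rate. The sign convention:
a POSITIVE lag means the gamma envelope is taken LATER in time than the
slow-wave window (gamma lags the slow wave).

TMCs are recomputed every 0.2 s, producing a (windows x 64) matrix per
channel from which the three modulation features are extracted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BandPair

__all__ = ["LagGrid", "TMCSeries", "tmc_window", "tmc_series"]

_EPS_VAR = 1e-24  # variance below this counts as degenerate (constant segment)


@dataclass(frozen=True)
class LagGrid:
    """The 64-point lag grid: tau_k = (k - 32) / rate for k = 0..63.

    The printed lag count (64 = 25 samples/s x 2.56 s) is the binding
    constraint; an inclusive -1.28..+1.28 s grid would hold 65 points, so the
    grid runs -1.28 ... +1.24 s.
    """

    rate_hz: float = 25.0
    n_lags: int = 64

    @property
    def lag_samples(self) -> np.ndarray:
        return np.arange(self.n_lags) - self.n_lags // 2

    @property
    def lags_s(self) -> np.ndarray:
        return self.lag_samples / self.rate_hz

    @property
    def max_lag_samples(self) -> int:
        return self.n_lags // 2

    @property
    def step_s(self) -> float:
        return 1.0 / self.rate_hz


@dataclass
class TMCSeries:
    """A series of tau-modulation curves for one channel.

    ``R[w, k]`` is the Pearson coefficient of window ``w`` at lag ``k``;
    invalid windows (insufficient lag context or filter-edge contamination)
    are all-NaN with ``valid[w] = False``.
    """

    R: np.ndarray
    window_times_s: np.ndarray
    lag_grid: LagGrid = field(default_factory=LagGrid)
    valid: np.ndarray | None = None
    step_s: float = 0.2

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.window_times_s = np.asarray(self.window_times_s, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.R).all(axis=1)
        finite = self.R[np.isfinite(self.R)]
        if finite.size and (np.abs(finite) > 1.0 + 1e-9).any():
            raise ValueError("Pearson coefficients must lie in [-1, 1]")

    @property
    def n_windows(self) -> int:
        return self.R.shape[0]


def tmc_window(
    slow_segment: np.ndarray,
    gamma_env_context: np.ndarray,
    lag_grid: LagGrid | None = None,
) -> np.ndarray:
    """One tau-modulation curve, computed by the direct per-lag Pearson loop.

    Parameters
    ----------
    slow_segment : ndarray, shape (64,)
        Slow-wave samples of one 2.56 s window at 25 Hz. The 64-point Hamming
        window multiplies this segment (and only this segment).
    gamma_env_context : ndarray, shape (>= 128,)
        Gamma envelope covering the window plus the +-1.28 s lag span,
        centered on the window (window samples sit in the middle).
    lag_grid : LagGrid, optional

    Returns
    -------
    ndarray, shape (64,)
        R at each lag; all-NaN if the windowed slow segment is constant, NaN
        at individual lags where the gamma segment is constant.

    This implementation is the reference oracle; :func:`tmc_series` must match
    it to ~1e-10.
    """
    grid = lag_grid or LagGrid()
    n = grid.n_lags
    slow_segment = np.asarray(slow_segment, dtype=float)
    gamma_env_context = np.asarray(gamma_env_context, dtype=float)
    if slow_segment.shape != (n,):
        raise ValueError(f"slow_segment must have exactly {n} samples")
    need = n + 2 * grid.max_lag_samples
    if gamma_env_context.shape[0] < need:
        raise ValueError(
            f"gamma context of {gamma_env_context.shape[0]} samples is shorter "
            f"than the required {need} (window + lag span)"
        )
    offset = (gamma_env_context.shape[0] - n) // 2  # center the window

    w = np.hamming(n)
    sw = w * slow_segment
    sw = sw - sw.mean()
    s_ss = float(sw @ sw)
    raw = slow_segment - slow_segment.mean()
    out = np.full(n, np.nan)
    # a constant slow segment is degenerate even though windowing gives it shape
    if s_ss < _EPS_VAR or float(raw @ raw) < _EPS_VAR:
        return out
    for k, lag in enumerate(grid.lag_samples):
        g = gamma_env_context[offset + lag : offset + lag + n]
        g = g - g.mean()
        g_ss = float(g @ g)
        if g_ss < _EPS_VAR:
            continue
        out[k] = float(sw @ g) / np.sqrt(s_ss * g_ss)
    return np.clip(out, -1.0, 1.0, out=out)


def tmc_series(
    band_pair: BandPair,
    channel: int = 0,
    window_s: float = 2.56,
    step_s: float = 0.2,
    lag_grid: LagGrid | None = None,
) -> TMCSeries:
    """Tau-modulation curves every ``step_s`` seconds for one channel.

    Windows are placed so that the full +-1.28 s lag context lies inside the
    recording; windows touching edge-flagged samples are kept in the series
    but marked invalid (all-NaN). Timestamps are window centers.
    """
    grid = lag_grid or LagGrid(rate_hz=band_pair.rate_hz)
    rate = band_pair.rate_hz
    n_win = int(round(window_s * rate))
    if n_win != grid.n_lags:
        raise ValueError("window length in samples must equal the lag count")
    step = int(round(step_s * rate))
    ctx = grid.max_lag_samples
    slow = band_pair.slow[channel]
    gamma = band_pair.gamma_env[channel]
    n = slow.shape[0]

    last_start = n - n_win - ctx
    starts = np.arange(ctx, last_start + 1, step)
    if starts.size == 0:
        import warnings

        warnings.warn("recording too short for any tau-modulation window")
        return TMCSeries(
            R=np.empty((0, grid.n_lags)),
            window_times_s=np.empty(0),
            lag_grid=grid,
            valid=np.empty(0, dtype=bool),
            step_s=step_s,
        )

    # validity: full lagged context must avoid edge-contaminated samples
    mask = band_pair.edge_mask
    bad_cum = np.concatenate([[0], np.cumsum(mask.astype(int))])
    ctx_lo = starts - ctx
    ctx_hi = starts + n_win + ctx  # exclusive
    valid = (bad_cum[ctx_hi] - bad_cum[ctx_lo]) == 0

    w = np.hamming(n_win)
    win_view = np.lib.stride_tricks.sliding_window_view(slow, n_win)
    raw = win_view[starts] - win_view[starts].mean(axis=1, keepdims=True)
    raw_ss = np.einsum("ij,ij->i", raw, raw)
    sw = win_view[starts] * w
    sw = sw - sw.mean(axis=1, keepdims=True)
    s_ss = np.einsum("ij,ij->i", sw, sw)

    g_view = np.lib.stride_tricks.sliding_window_view(gamma, n_win)
    R = np.full((starts.size, grid.n_lags), np.nan)
    ok_s = (s_ss >= _EPS_VAR) & (raw_ss >= _EPS_VAR)
    for k, lag in enumerate(grid.lag_samples):
        g = g_view[starts + lag]
        g = g - g.mean(axis=1, keepdims=True)
        g_ss = np.einsum("ij,ij->i", g, g)
        ok = ok_s & (g_ss >= _EPS_VAR)
        num = np.einsum("ij,ij->i", sw, g)
        with np.errstate(invalid="ignore", divide="ignore"):
            col = num / np.sqrt(s_ss * g_ss)
        R[ok, k] = col[ok]
    R[~valid] = np.nan
    np.clip(R, -1.0, 1.0, out=R)

    times = band_pair.start_time_s + (starts + (n_win - 1) / 2.0) / rate
    return TMCSeries(
        R=R, window_times_s=times, lag_grid=grid, valid=valid, step_s=step_s
    )
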