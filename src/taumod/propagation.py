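"""Spatiotemporal propagation of modulation strength across channels.

For each channel the normalized modulation-strength series over an analysis
interval after the anesthetic injection (5-20 min by default) is smoothed by
a 20th-order least-squares polynomial, and the channel's *peak modulation
time* is the first local maximum of the fitted curve that exceeds the mean
normalized strength of the anesthetized period. Ordering channels by peak
time (and attaching electrode coordinates when available) yields the
propagation map.

The fit uses time affinely mapped to [-1, 1]; a degree-20 Vandermonde fit on
raw seconds would be catastrophically ill-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureSeries

__all__ = ["PropagationMap", "peak_modulation_time", "propagation_map"]

POLY_ORDER = 20
DEFAULT_ANALYSIS_S = (300.0, 1200.0)  # 5-20 min after injection
_GRID_STEP_S = 1.0  # dense evaluation grid for peak finding


@dataclass
class PeakResult:
    peak_time_s: float
    peak_strength_z: float
    valid: bool
    reason: str
    coefficients: np.ndarray | None = None  # Polynomial (mapped-domain) coefs


def _fit_polynomial(times_s: np.ndarray, values: np.ndarray, order: int):
    poly = np.polynomial.Polynomial.fit(times_s, values, deg=order)
    return poly


def peak_modulation_time(
    times_s: np.ndarray,
    strength_z: np.ndarray,
    analysis_interval_s: tuple[float, float] = DEFAULT_ANALYSIS_S,
    threshold_interval_s: tuple[float, float] | None = None,
    threshold: float | None = None,
    order: int = POLY_ORDER,
    min_points: int = 200,
) -> PeakResult:
    """First fitted-curve peak of a normalized strength series.

    Parameters
    ----------
    times_s, strength_z : the strength series (times relative to injection).
    analysis_interval_s : interval to fit, in the same time base.
    threshold_interval_s : interval whose mean strength defines the peak
        threshold (typically the anesthetized period). Alternatively pass
        ``threshold`` directly.
    min_points : minimum finite samples required inside the analysis interval.

    Returns a :class:`PeakResult`; invalid results carry a reason code
    (``too_few_points``, ``no_peak``, ``degenerate``).
    """
    times_s = np.asarray(times_s, dtype=float)
    strength_z = np.asarray(strength_z, dtype=float)
    if threshold is None:
        if threshold_interval_s is None:
            raise ValueError("provide either threshold or threshold_interval_s")
        lo, hi = threshold_interval_s
        sel = (times_s >= lo) & (times_s <= hi) & np.isfinite(strength_z)
        if not sel.any():
            raise ValueError("threshold interval contains no finite strength values")
        threshold = float(strength_z[sel].mean())

    lo, hi = analysis_interval_s
    sel = (times_s >= lo) & (times_s <= hi) & np.isfinite(strength_z)
    if sel.sum() < min_points:
        return PeakResult(np.nan, np.nan, False, "too_few_points")
    t = times_s[sel]
    v = strength_z[sel]
    if np.ptp(t) <= 0 or np.allclose(v, v[0]):
        return PeakResult(np.nan, np.nan, False, "degenerate")
    poly = _fit_polynomial(t, v, order)

    grid = np.arange(t[0], t[-1] + _GRID_STEP_S / 2, _GRID_STEP_S)
    y = poly(grid)
    # interior local maxima: strict rise before, fall after (endpoints excluded)
    is_max = np.zeros(grid.size, dtype=bool)
    is_max[1:-1] = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
    candidates = np.flatnonzero(is_max & (y > threshold))
    if candidates.size == 0:
        return PeakResult(np.nan, np.nan, False, "no_peak", poly.coef)
    i = candidates[0]
    # refine the peak within the bracketing grid cell
    fine = np.linspace(grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)], 201)
    yf = poly(fine)
    j = int(np.argmax(yf))
    return PeakResult(float(fine[j]), float(yf[j]), True, "", poly.coef)


@dataclass
class PropagationMap:
    """Per-channel peak modulation times, ordered earliest-first."""

    table: pd.DataFrame  # channel, peak_time_s, peak_strength_z, valid, reason, x_mm, y_mm

    @property
    def order(self) -> list[str]:
        valid = self.table[self.table["valid"]]
        return list(valid.sort_values("peak_time_s")["channel"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="")


def propagation_map(
    feature_series: list[FeatureSeries],
    injection_time_s: float,
    channel_xy_mm: np.ndarray | None = None,
    analysis_interval_s: tuple[float, float] = DEFAULT_ANALYSIS_S,
    threshold_interval_s: tuple[float, float] | None = None,
    order: int = POLY_ORDER,
    min_points: int = 200,
) -> PropagationMap:
    """Apply :func:`peak_modulation_time` channel-wise and assemble the map.

    Intervals are interpreted relative to ``injection_time_s`` (the
    ``injection`` marker of the recording). ``threshold_interval_s`` defaults
    to the analysis interval itself when no anesthetized-period interval is
    supplied. Channels whose fit fails are flagged invalid, never dropped.
    """
    if not feature_series:
        raise ValueError("at least one channel of features is required")
    thr_int = threshold_interval_s or analysis_interval_s
    rows = []
    for ch_idx, fs in enumerate(feature_series):
        z = fs.strength_z if fs.strength_z is not None else fs.strength_raw
        rel_t = np.asarray(fs.times_s) - injection_time_s
        finite_thr = np.isfinite(z) & (rel_t >= thr_int[0]) & (rel_t <= thr_int[1])
        if not finite_thr.any():
            res = PeakResult(np.nan, np.nan, False, "no_threshold_data")
        else:
            res = peak_modulation_time(
                rel_t,
                z,
                analysis_interval_s=analysis_interval_s,
                threshold_interval_s=thr_int,
                order=order,
                min_points=min_points,
            )
        row = dict(
            channel=fs.channel,
            peak_time_s=res.peak_time_s,
            peak_strength_z=res.peak_strength_z,
            valid=res.valid,
            reason=res.reason,
        )
        if channel_xy_mm is not None:
            row["x_mm"] = float(channel_xy_mm[ch_idx, 0])
            row["y_mm"] = float(channel_xy_mm[ch_idx, 1])
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        "peak_time_s", na_position="last", kind="stable"
    )
    return PropagationMap(table=table.reset_index(drop=True))
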