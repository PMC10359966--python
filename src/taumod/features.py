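"""The three tau-modulation features: strength, frequency, polarity.

All three are computed from 5 s observation windows containing 25 consecutive
tau-modulation curves (TMCs), advanced every 0.2 s (5 Hz feature rate):

* **strength** -- the signal-to-noise ratio of the observation stack,
  SNR = sigma^2 / ((1/n) * sum_i sigma_i^2), where sigma^2 is the pooled
  (population) variance of all 25 x 64 R values and sigma_i^2 the population
  variance of R at lag i across the 25 TMCs. If the R samples were
  uncorrelated this ratio is calibrated to ~1 under no coupling and grows
  with coupling, because consistent TMC structure inflates the pooled
  variance while leaving the per-lag variances at the noise level.
* **frequency** -- the center frequency of the first oscillatory Gabor atom
  of a greedy matching-pursuit decomposition of the averaged TMC.
* **polarity** -- the sign of the linearly detrended averaged TMC around lag
  zero: +1 gamma-high-at-slow-wave-peaks (peak-max), -1 trough-max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tmc import LagGrid, TMCSeries

__all__ = [
    "GaborAtom",
    "FeatureSeries",
    "strength_snr",
    "strength_series",
    "normalize_strength",
    "GaborDictionary",
    "matching_pursuit",
    "modulation_frequency",
    "modulation_polarity",
    "compute_features",
]

OBS_N_TMCS = 25  # 5 s observation window at the 0.2 s TMC step
_MAX_NAN_FRACTION = 0.2


# --------------------------------------------------------------------------
# strength
# --------------------------------------------------------------------------

def strength_snr(stack: np.ndarray) -> float:
    """SNR of one observation stack of TMCs (rows = TMCs, columns = lags).

    Population-variance convention throughout. Returns NaN when more than
    20% of the entries are NaN, or when the per-lag (noise) variances are all
    zero (identical TMCs repeated -- degenerate).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 2 or stack.shape[0] < 2:
        raise ValueError("stack must be a (n_tmcs >= 2, n_lags) matrix")
    finite = np.isfinite(stack)
    if 1.0 - finite.mean() > _MAX_NAN_FRACTION:
        return float("nan")
    with np.errstate(invalid="ignore"):
        pooled = np.nanvar(stack)
        per_lag = np.nanvar(stack, axis=0)
    denom = np.nanmean(per_lag)
    # identical TMCs give per-lag variances at float-noise level: degenerate
    if not np.isfinite(denom) or denom <= 1e-12 * max(pooled, 1e-300):
        return float("nan")
    return float(pooled / denom)


def _obs_starts(tmc: TMCSeries, n_obs: int) -> np.ndarray:
    n = tmc.n_windows
    if n < n_obs:
        return np.empty(0, dtype=int)
    return np.arange(0, n - n_obs + 1)


def _obs_times(tmc: TMCSeries, starts: np.ndarray, n_obs: int) -> np.ndarray:
    # feature timestamp = center of the 5 s observation window
    return tmc.window_times_s[starts + n_obs // 2]


def strength_series(
    tmc: TMCSeries, n_obs: int = OBS_N_TMCS
) -> tuple[np.ndarray, np.ndarray]:
    """Raw SNR per observation window, advanced one TMC step (0.2 s) at a time.

    Returns ``(times_s, strength_raw)``.
    """
    starts = _obs_starts(tmc, n_obs)
    out = np.full(starts.size, np.nan)
    for j, s in enumerate(starts):
        out[j] = strength_snr(tmc.R[s : s + n_obs])
    return _obs_times(tmc, starts, n_obs), out


def normalize_strength(
    times_s: np.ndarray,
    strength_raw: np.ndarray,
    baseline_interval_s: tuple[float, float],
    min_baseline: int = 25,
) -> np.ndarray:
    """Z-score a strength series against a baseline interval.

    Subtracts the baseline mean and divides by the baseline standard
    deviation, so the baseline itself has mean ~0 and sd ~1.
    """
    times_s = np.asarray(times_s, dtype=float)
    strength_raw = np.asarray(strength_raw, dtype=float)
    lo, hi = baseline_interval_s
    in_base = (times_s >= lo) & (times_s <= hi)
    base = strength_raw[in_base]
    base = base[np.isfinite(base)]
    if base.size < min_baseline:
        raise ValueError(
            f"baseline interval holds only {base.size} finite strength values "
            f"(need >= {min_baseline})"
        )
    sd = float(np.std(base))
    if sd == 0.0:
        raise ValueError("baseline strength is constant; cannot normalize")
    return (strength_raw - float(np.mean(base))) / sd


# --------------------------------------------------------------------------
# frequency (matching pursuit)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GaborAtom:
    """One Gabor atom: a Gaussian-windowed cosine on the lag axis."""

    center_time_s: float
    center_freq_hz: float
    spread_s: float
    amplitude: float
    phase_rad: float


class GaborDictionary:
    """Discrete Gabor dictionary on the 64-point lag grid.

    Atoms ``exp(-(tau - t0)^2 / (2 s^2)) * cos(2 pi f (tau - t0) - phi)`` with
    center times at every lag sample, center frequencies 0 ... rate/2 in
    steps of ``1 / (4 * span)`` (4x zero-padding refinement of the natural
    1/2.56 Hz resolution), five logarithmically spaced spreads, plus one
    constant atom. The optimal phase is solved analytically per atom from the
    two quadrature projections.
    """

    def __init__(
        self,
        lag_grid: LagGrid | None = None,
        n_spreads: int = 5,
        spread_range_s: tuple[float, float] = (0.08, 1.28),
        freq_refinement: int = 4,
    ) -> None:
        grid = lag_grid or LagGrid()
        tau = grid.lags_s
        span = grid.n_lags / grid.rate_hz
        df = 1.0 / (span * freq_refinement)
        freqs = np.arange(0.0, grid.rate_hz / 2.0 + df / 2, df)
        spreads = np.geomspace(*spread_range_s, n_spreads)

        t0s, fs, ss, qc, qs = [], [], [], [], []
        for s in spreads:
            for t0 in tau:
                env = np.exp(-((tau - t0) ** 2) / (2.0 * s**2))
                for f in freqs:
                    arg = 2.0 * np.pi * f * (tau - t0)
                    qc.append(env * np.cos(arg))
                    qs.append(env * np.sin(arg))
                    t0s.append(t0)
                    fs.append(f)
                    ss.append(s)
        # constant atom (captures offsets; never oscillatory)
        qc.append(np.ones_like(tau))
        qs.append(np.zeros_like(tau))
        t0s.append(0.0)
        fs.append(0.0)
        ss.append(np.inf)

        self.lag_grid = grid
        self.t0 = np.array(t0s)
        self.freq = np.array(fs)
        self.spread = np.array(ss)
        self.Qc = np.array(qc)
        self.Qs = np.array(qs)
        # per-atom Gram matrix of the two quadratures
        self._ccc = np.einsum("ij,ij->i", self.Qc, self.Qc)
        self._css = np.einsum("ij,ij->i", self.Qs, self.Qs)
        self._ccs = np.einsum("ij,ij->i", self.Qc, self.Qs)
        self._det = self._ccc * self._css - self._ccs**2
        self._degenerate = self._det < 1e-12 * np.maximum(self._ccc, 1e-30) ** 2

    def __len__(self) -> int:
        return self.t0.size

    def project(self, r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Energy captured by each atom at its optimal phase, plus quadrature
        coefficients (a, b) such that the best fit is a*qc + b*qs."""
        rc = self.Qc @ r
        rs = self.Qs @ r
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (self._css * rc - self._ccs * rs) / self._det
            b = (self._ccc * rs - self._ccs * rc) / self._det
        a_d = rc / self._ccc
        a = np.where(self._degenerate, a_d, a)
        b = np.where(self._degenerate, 0.0, b)
        gain = a * rc + b * rs
        return gain, a, b


_DICT_CACHE: dict[tuple, GaborDictionary] = {}


def default_dictionary(lag_grid: LagGrid | None = None) -> GaborDictionary:
    grid = lag_grid or LagGrid()
    key = (grid.rate_hz, grid.n_lags)
    if key not in _DICT_CACHE:
        _DICT_CACHE[key] = GaborDictionary(grid)
    return _DICT_CACHE[key]


def matching_pursuit(
    x: np.ndarray,
    lag_grid: LagGrid | None = None,
    max_atoms: int = 10,
    residual_tol: float = 0.05,
    dictionary: GaborDictionary | None = None,
    stop_at_freq_hz: float | None = None,
) -> list[GaborAtom]:
    """Greedy Gabor decomposition of a 64-sample curve.

    At each step the dictionary atom capturing the most residual energy (at
    its analytically optimal phase) is subtracted. Stops when ``max_atoms``
    are extracted, the residual energy drops below ``residual_tol`` of the
    input energy, or -- if ``stop_at_freq_hz`` is given -- right after the
    first atom at or above that center frequency (extraction order is greedy,
    so the truncated run agrees with a full run up to that atom).
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("matching pursuit requires a finite input")
    d = dictionary or default_dictionary(lag_grid)
    if x.shape != (d.lag_grid.n_lags,):
        raise ValueError(f"input must have {d.lag_grid.n_lags} samples")
    e0 = float(x @ x)
    atoms: list[GaborAtom] = []
    if e0 == 0.0:
        return atoms
    r = x.copy()
    for _ in range(max_atoms):
        gain, a, b = d.project(r)
        i = int(np.nanargmax(gain))
        if not np.isfinite(gain[i]) or gain[i] <= 1e-15 * e0:
            break
        r = r - (a[i] * d.Qc[i] + b[i] * d.Qs[i])
        atoms.append(
            GaborAtom(
                center_time_s=float(d.t0[i]),
                center_freq_hz=float(d.freq[i]),
                spread_s=float(d.spread[i]),
                amplitude=float(np.hypot(a[i], b[i])),
                phase_rad=float(np.arctan2(b[i], a[i])),
            )
        )
        if stop_at_freq_hz is not None and d.freq[i] >= stop_at_freq_hz:
            break
        if float(r @ r) < residual_tol * e0:
            break
    return atoms


def modulation_frequency(
    tmc: TMCSeries,
    oscillatory_threshold_hz: float = 0.2,
    n_obs: int = OBS_N_TMCS,
    max_atoms: int = 10,
    residual_tol: float = 0.05,
    dictionary: GaborDictionary | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Modulation frequency per observation window.

    The 25 TMCs of each window are averaged and decomposed by matching
    pursuit; the frequency is the center frequency of the first atom (in
    extraction order) at or above the oscillatory threshold. Windows with any
    invalid TMC, or with no oscillatory atom, yield NaN.

    Returns ``(times_s, freq_hz)``.
    """
    d = dictionary or default_dictionary(tmc.lag_grid)
    starts = _obs_starts(tmc, n_obs)
    out = np.full(starts.size, np.nan)
    for j, s in enumerate(starts):
        if not tmc.valid[s : s + n_obs].all():
            continue
        mean_tmc = tmc.R[s : s + n_obs].mean(axis=0)
        if not np.isfinite(mean_tmc).all():
            continue
        atoms = matching_pursuit(
            mean_tmc,
            max_atoms=max_atoms,
            residual_tol=residual_tol,
            dictionary=d,
            stop_at_freq_hz=oscillatory_threshold_hz,
        )
        for atom in atoms:
            if atom.center_freq_hz >= oscillatory_threshold_hz:
                out[j] = atom.center_freq_hz
                break
    return _obs_times(tmc, starts, n_obs), out


# --------------------------------------------------------------------------
# polarity
# --------------------------------------------------------------------------

def _detrend_linear(tau_s: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef = np.polynomial.polynomial.polyfit(tau_s, y, 1)
    return y - np.polynomial.polynomial.polyval(tau_s, coef)


def modulation_polarity(
    tmc: TMCSeries,
    half_width_s: float = 0.12,
    n_obs: int = OBS_N_TMCS,
    min_valid_fraction: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Modulation polarity per observation window.

    The valid TMCs of each window are averaged, the least-squares linear
    trend in tau is removed, and the sign of the mean detrended value over
    ``|tau| <= half_width_s`` is returned: +1 peak-max, -1 trough-max, NaN
    when fewer than ``min_valid_fraction`` of the TMCs are valid or the mean
    is exactly zero.

    Returns ``(times_s, polarity)``.
    """
    tau = tmc.lag_grid.lags_s
    near0 = np.abs(tau) <= half_width_s + 1e-12
    starts = _obs_starts(tmc, n_obs)
    out = np.full(starts.size, np.nan)
    for j, s in enumerate(starts):
        sub = tmc.R[s : s + n_obs]
        rows = np.isfinite(sub).all(axis=1)
        if rows.mean() < min_valid_fraction:
            continue
        mean_tmc = sub[rows].mean(axis=0)
        det = _detrend_linear(tau, mean_tmc)
        m = det[near0].mean()
        if m != 0.0:
            out[j] = np.sign(m)
    return _obs_times(tmc, starts, n_obs), out


# --------------------------------------------------------------------------
# combined feature series
# --------------------------------------------------------------------------

@dataclass
class FeatureSeries:
    """The three modulation features for one channel at the 5 Hz feature rate."""

    times_s: np.ndarray
    strength_raw: np.ndarray
    freq_hz: np.ndarray
    polarity: np.ndarray
    strength_z: np.ndarray | None = None
    channel: str = "ch000"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times_s)
        for name in ("strength_raw", "freq_hz", "polarity"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must match times_s")
        pol = self.polarity[np.isfinite(self.polarity)]
        if pol.size and not np.isin(pol, (-1.0, 1.0)).all():
            raise ValueError("polarity must be +1, -1 or NaN")


def compute_features(
    tmc: TMCSeries,
    baseline_interval_s: tuple[float, float] | None = None,
    channel: str = "ch000",
    polarity_half_width_s: float = 0.12,
    oscillatory_threshold_hz: float = 0.2,
    n_obs: int = OBS_N_TMCS,
    dictionary: GaborDictionary | None = None,
    with_frequency: bool = True,
) -> FeatureSeries:
    """Extract all three features from one channel's TMC series."""
    times, raw = strength_series(tmc, n_obs=n_obs)
    if with_frequency:
        _, freq = modulation_frequency(
            tmc,
            oscillatory_threshold_hz=oscillatory_threshold_hz,
            n_obs=n_obs,
            dictionary=dictionary,
        )
    else:
        freq = np.full(times.size, np.nan)
    _, pol = modulation_polarity(tmc, half_width_s=polarity_half_width_s, n_obs=n_obs)
    z = None
    if baseline_interval_s is not None:
        z = normalize_strength(times, raw, baseline_interval_s)
    return FeatureSeries(
        times_s=times,
        strength_raw=raw,
        freq_hz=freq,
        polarity=pol,
        strength_z=z,
        channel=channel,
    )
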