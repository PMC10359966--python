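"""Synthetic electrophysiology with known ground-truth slow-wave coupling.

Generates ECoG/EEG-like multichannel recordings in which a broadband-gamma
carrier's amplitude envelope is coupled -- with configurable depth, polarity,
time lag, and slow-waveform shape -- to a slow-wave component, on top of a
1/f background and line noise. A session is a timeline of labeled anesthesia
stages (awake -> injection transient -> suppression -> anesthetized ->
recovery), each carrying its own coupling parameters, with per-channel onset
delays for propagation experiments. Everything is bit-reproducible for a
fixed seed.

The generative model per channel::

    x(t) = A_s(t) * m(t)                               slow wave
         + A_g(t) * max(0, 1 + d(t) * p * m(t - lag)) * c(t)   coupled gamma
         + 1/f background + line noise

where ``m`` is the unit-normalized slow waveform (sinusoid, skewed sinusoid
or sawtooth evaluated on an integrated, possibly non-stationary phase),
``c`` a unit-RMS 55-145 Hz Gaussian noise carrier (broadband gamma is
non-rhythmic, so the carrier is band-limited noise rather than a tone),
``d`` the coupling depth in [0, 1] and ``p`` the polarity (+1 peak-max,
-1 trough-max).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import Recording
from .preprocess import design_fir, _convolve_zero_phase

__all__ = [
    "CouplingSpec",
    "StageSpec",
    "SessionSpec",
    "ChannelComponents",
    "generate_channel_signal",
    "generate_session",
    "default_anesthesia_session",
]

_WAVEFORMS = ("sinusoid", "asymmetric", "sawtooth")


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth coupling parameters for one channel/stage.

    ``mod_freq_hz`` is either a constant or a piecewise-linear trajectory
    given as ``[(t_s, f_hz), ...]`` relative to the start of the segment.
    ``lag_s`` shifts the gamma envelope relative to the slow wave (positive:
    gamma peaks after slow-wave peaks).
    """

    mod_freq_hz: float | tuple[tuple[float, float], ...] = 1.0
    depth: float = 0.0
    polarity: int = 1
    lag_s: float = 0.0
    waveform: str = "sinusoid"
    slow_amp_uv: float = 100.0
    gamma_amp_uv: float = 10.0
    noise_exponent: float = 1.0
    noise_amp_uv: float = 20.0
    line_noise_uv: tuple[float, float, float] = (5.0, 2.0, 1.0)
    line_freq_hz: float = 50.0
    asymmetry: float = 0.5
    sawtooth_width: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.depth <= 1.0):
            raise ValueError("depth must lie in [0, 1]")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")
        if abs(self.lag_s) >= 1.28:
            raise ValueError("|lag_s| must be below 1.28 s")
        if self.waveform not in _WAVEFORMS:
            raise ValueError(f"waveform must be one of {_WAVEFORMS}")
        for _, f in self._freq_points(1.0):
            if f <= 0:
                raise ValueError("mod_freq_hz must be positive")

    def _freq_points(self, duration_s: float) -> tuple[tuple[float, float], ...]:
        if np.isscalar(self.mod_freq_hz):
            return ((0.0, float(self.mod_freq_hz)), (duration_s, float(self.mod_freq_hz)))
        return tuple((float(t), float(f)) for t, f in self.mod_freq_hz)

    def freq_profile(self, t_s: np.ndarray) -> np.ndarray:
        """Instantaneous slow-wave frequency at each time (piecewise linear)."""
        pts = self._freq_points(float(t_s[-1]) if len(t_s) else 0.0)
        tp = np.array([p[0] for p in pts])
        fp = np.array([p[1] for p in pts])
        return np.interp(t_s, tp, fp)


def _waveform_from_phase(phase: np.ndarray, spec: CouplingSpec) -> np.ndarray:
    """Unit-normalized slow waveform m(phase); peaks at phase = 0 mod 2 pi."""
    if spec.waveform == "sinusoid":
        m = np.cos(phase)
    elif spec.waveform == "asymmetric":
        # phase-skewed sinusoid: rise/fall ratio set by the asymmetry term
        m = np.cos(phase + spec.asymmetry * np.sin(phase))
    else:  # sawtooth with sharp transients; shift so the maximum sits at 0
        m = sps.sawtooth(phase + np.pi * spec.sawtooth_width, width=spec.sawtooth_width)
    m = m - m.mean()
    peak = np.abs(m).max()
    return m / peak if peak > 0 else m


def _one_over_f_noise(
    n: int, fs_hz: float, exponent: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Spectrally shaped Gaussian noise with PSD ~ 1/f**exponent.

    The shaping is flattened below 0.1 Hz so the variance stays finite.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs_hz)
    f_floor = max(0.1, f[1] if n > 1 else 0.1)
    shape = np.zeros_like(f)
    shape[1:] = np.maximum(f[1:], f_floor) ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _gamma_carrier(
    n: int, fs_hz: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (the non-rhythmic gamma carrier)."""
    taps = design_fir(fs_hz, "bandpass", *band, transition_hz=10.0, max_taps=(n - 1) // 3)
    c = _convolve_zero_phase(rng.standard_normal(n), taps)
    return c / c.std()


@dataclass
class ChannelComponents:
    """Ground-truth constituents of one generated channel."""

    signal: np.ndarray
    slow: np.ndarray
    gamma: np.ndarray
    gamma_env: np.ndarray  # the true amplitude profile applied to the carrier
    waveform: np.ndarray  # unit-normalized m(t)
    noise: np.ndarray
    line: np.ndarray


def generate_channel_signal(
    coupling: CouplingSpec,
    duration_s: float,
    fs_hz: float,
    seed: int | np.random.Generator = 0,
    gamma_band_hz: tuple[float, float] = (55.0, 145.0),
    return_components: bool = False,
) -> np.ndarray | ChannelComponents:
    """Generate one channel with stationary coupling parameters."""
    if duration_s < 10.0:
        raise ValueError("duration_s must be at least 10 s")
    if fs_hz < 500.0:
        raise ValueError("fs_hz must be at least 500 Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz

    freq = coupling.freq_profile(t)
    phase = 2.0 * np.pi * np.cumsum(freq) / fs_hz
    m = _waveform_from_phase(phase, coupling)
    slow = coupling.slow_amp_uv * m

    # gamma envelope follows the slow waveform evaluated at t - lag
    phase_lag = np.interp(t - coupling.lag_s, t, phase)
    m_lag = _waveform_from_phase(phase_lag, coupling)
    env = coupling.gamma_amp_uv * np.clip(
        1.0 + coupling.depth * coupling.polarity * m_lag, 0.0, None
    )
    carrier = _gamma_carrier(n, fs_hz, gamma_band_hz, rng)
    gamma = env * carrier

    noise = _one_over_f_noise(
        n, fs_hz, coupling.noise_exponent, coupling.noise_amp_uv, rng
    )
    line = np.zeros(n)
    for k, amp in enumerate(coupling.line_noise_uv, start=1):
        line += amp * np.sin(
            2.0 * np.pi * k * coupling.line_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )

    signal = slow + gamma + noise + line
    if return_components:
        return ChannelComponents(
            signal=signal,
            slow=slow,
            gamma=gamma,
            gamma_env=env,
            waveform=m,
            noise=noise,
            line=line,
        )
    return signal


# --------------------------------------------------------------------------
# sessions
# --------------------------------------------------------------------------

STAGE_LABELS = (
    "awake_eyes_open",
    "awake_eyes_covered",
    "injection_transient",
    "suppression",
    "anesthetized",
    "recovery",
)


@dataclass(frozen=True)
class StageSpec:
    """One labeled interval of the session timeline."""

    label: str
    duration_s: float
    coupling: CouplingSpec
    start_s: float | None = None  # validated against the running timeline


@dataclass
class SessionSpec:
    """Full multichannel session: timeline, geometry, and seed."""

    stages: list[StageSpec]
    n_channels: int = 1
    fs_hz: float = 1000.0
    onset_delays_s: tuple[float, ...] | None = None
    grid_spacing_mm: float = 5.0
    transition_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("session needs at least one stage")
        t = 0.0
        for st in self.stages:
            if st.duration_s <= 0:
                raise ValueError("stage durations must be positive")
            if st.start_s is not None:
                if st.start_s < t - 1e-9:
                    raise ValueError(
                        f"stage {st.label!r} starts at {st.start_s} s, overlapping "
                        f"the previous stage ending at {t} s"
                    )
                if abs(st.start_s - t) > 1e-9:
                    raise ValueError("stages must tile the timeline without gaps")
            t += st.duration_s
        if self.onset_delays_s is not None and len(self.onset_delays_s) != self.n_channels:
            raise ValueError("one onset delay per channel required")

    @property
    def duration_s(self) -> float:
        return sum(st.duration_s for st in self.stages)

    @property
    def boundaries_s(self) -> list[tuple[str, float, float]]:
        out, t = [], 0.0
        for st in self.stages:
            out.append((st.label, t, t + st.duration_s))
            t += st.duration_s
        return out

    def grid_xy_mm(self) -> np.ndarray:
        side = int(np.ceil(np.sqrt(self.n_channels)))
        ix = np.arange(self.n_channels)
        return np.column_stack([ix % side, ix // side]) * self.grid_spacing_mm


def _smooth_profile(x: np.ndarray, fs_hz: float, transition_s: float) -> np.ndarray:
    if transition_s <= 0:
        return x
    w = int(round(transition_s * fs_hz))
    if w < 2:
        return x
    kern = np.hanning(w + 2)[1:-1]
    kern /= kern.sum()
    pad = len(kern) // 2
    xp = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    return sps.fftconvolve(xp, kern, mode="valid")[: len(x)]


def _stage_index(spec: SessionSpec, ts: np.ndarray) -> np.ndarray:
    """Stage index for each (possibly onset-shifted) session time."""
    edges = np.cumsum([st.duration_s for st in spec.stages])
    idx = np.searchsorted(edges, ts, side="right")
    return np.clip(idx, 0, len(spec.stages) - 1)


def _session_channel(
    spec: SessionSpec,
    delay_s: float,
    rng: np.random.Generator,
    gamma_band_hz: tuple[float, float],
) -> ChannelComponents:
    fs = spec.fs_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    ts = np.clip(t - delay_s, 0.0, spec.duration_s - 1.0 / fs)
    idx = _stage_index(spec, ts)
    starts = np.concatenate([[0.0], np.cumsum([st.duration_s for st in spec.stages])])

    def per_stage(fn) -> np.ndarray:
        out = np.empty(n)
        for i, st in enumerate(spec.stages):
            sel = idx == i
            if sel.any():
                out[sel] = fn(st, ts[sel] - starts[i])
        return out

    freq = per_stage(lambda st, rel: st.coupling.freq_profile(rel))
    depth = per_stage(lambda st, rel: np.full(rel.shape, st.coupling.depth))
    pol = per_stage(lambda st, rel: np.full(rel.shape, float(st.coupling.polarity)))
    lag = per_stage(lambda st, rel: np.full(rel.shape, st.coupling.lag_s))
    slow_amp = per_stage(lambda st, rel: np.full(rel.shape, st.coupling.slow_amp_uv))
    gamma_amp = per_stage(lambda st, rel: np.full(rel.shape, st.coupling.gamma_amp_uv))
    noise_amp = per_stage(lambda st, rel: np.full(rel.shape, st.coupling.noise_amp_uv))

    # continuous quantities crossfade over stage boundaries; the discrete ones
    # (polarity, lag, waveform) switch sharply
    freq = _smooth_profile(freq, fs, spec.transition_s)
    depth = _smooth_profile(depth, fs, spec.transition_s)
    slow_amp = _smooth_profile(slow_amp, fs, spec.transition_s)
    gamma_amp = _smooth_profile(gamma_amp, fs, spec.transition_s)
    noise_amp = _smooth_profile(noise_amp, fs, spec.transition_s)

    # channels are not phase-locked to each other: a per-channel random
    # initial phase keeps the slow wave from cancelling under CAR
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    phase = phi0 + 2.0 * np.pi * np.cumsum(freq) / fs
    phase_lag = np.interp(t - lag, t, phase)

    m = np.empty(n)
    m_lag = np.empty(n)
    for i, st in enumerate(spec.stages):
        sel = idx == i
        if sel.any():
            m[sel] = _waveform_from_phase(phase[sel], st.coupling)
            m_lag[sel] = _waveform_from_phase(phase_lag[sel], st.coupling)

    slow = slow_amp * m
    env = gamma_amp * np.clip(1.0 + depth * pol * m_lag, 0.0, None)
    carrier = _gamma_carrier(n, fs, gamma_band_hz, rng)
    gamma = env * carrier

    c0 = spec.stages[0].coupling
    noise = _one_over_f_noise(n, fs, c0.noise_exponent, 1.0, rng) * noise_amp
    line = np.zeros(n)
    for k, amp in enumerate(c0.line_noise_uv, start=1):
        line += amp * np.sin(2 * np.pi * k * c0.line_freq_hz * t + rng.uniform(0, 2 * np.pi))

    return ChannelComponents(
        signal=slow + gamma + noise + line,
        slow=slow,
        gamma=gamma,
        gamma_env=env,
        waveform=m,
        noise=noise,
        line=line,
    )


def generate_session(
    spec: SessionSpec,
    gamma_band_hz: tuple[float, float] = (55.0, 145.0),
    return_components: bool = False,
):
    """Generate a full session.

    Returns ``(recording, ground_truth)`` -- or
    ``(recording, ground_truth, components)`` with the per-channel
    ground-truth constituents when ``return_components`` is set. The
    recording carries a marker at every stage boundary (plus an
    ``injection`` alias at the start of the injection transient) and one
    labeled condition interval per stage. Identical specs and seeds produce
    identical bytes.
    """
    delays = spec.onset_delays_s or tuple(0.0 for _ in range(spec.n_channels))
    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_channels)
    comps = [
        _session_channel(spec, d, np.random.default_rng(s), gamma_band_hz)
        for d, s in zip(delays, child_seeds)
    ]
    samples = np.vstack([c.signal for c in comps])

    markers = []
    intervals: dict[str, tuple[float, float]] = {}
    for label, lo, hi in spec.boundaries_s:
        markers.append((label, lo))
        intervals[label] = (lo, hi)
        if label == "injection_transient":
            markers.append(("injection", lo))
    recording = Recording(
        samples=samples,
        fs_hz=spec.fs_hz,
        markers=markers,
        condition_intervals=intervals,
        channel_xy_mm=spec.grid_xy_mm(),
    )

    rows = []
    for ch in range(spec.n_channels):
        for st, (label, lo, hi) in zip(spec.stages, spec.boundaries_s):
            f = st.coupling._freq_points(st.duration_s)
            rows.append(
                dict(
                    channel=recording.channel_labels[ch],
                    interval=label,
                    start_s=lo,
                    end_s=hi,
                    depth=st.coupling.depth,
                    polarity=st.coupling.polarity,
                    lag_s=st.coupling.lag_s,
                    freq_hz=float(np.mean([p[1] for p in f])),
                    onset_s=float(delays[ch]),
                )
            )
    ground_truth = pd.DataFrame(rows)
    if return_components:
        return recording, ground_truth, comps
    return recording, ground_truth


def default_anesthesia_session(
    n_channels: int = 1,
    seed: int = 0,
    depth: float = 0.8,
    polarity: int = 1,
    lag_s: float = 0.0,
    mod_freq_hz: float = 1.0,
    waveform: str = "sinusoid",
    onset_delays_s: tuple[float, ...] | None = None,
    durations_s: dict[str, float] | None = None,
    fs_hz: float = 1000.0,
) -> SessionSpec:
    """A typical propofol-anesthesia timeline with sensible stage parameters.

    Awake stages are uncoupled with weak slow-wave power; the injection
    transient carries a brief burst of strong coupling; suppression damps
    everything; the anesthetized stage holds the requested coupling; recovery
    tapers it off.
    """
    dur = {
        "awake_eyes_open": 60.0,
        "awake_eyes_covered": 120.0,
        "injection_transient": 60.0,
        "suppression": 60.0,
        "anesthetized": 180.0,
        "recovery": 120.0,
    }
    if durations_s:
        dur.update(durations_s)
    base = CouplingSpec(
        mod_freq_hz=mod_freq_hz,
        depth=depth,
        polarity=polarity,
        lag_s=lag_s,
        waveform=waveform,
    )
    stages = [
        StageSpec("awake_eyes_open", dur["awake_eyes_open"],
                  replace(base, depth=0.0, slow_amp_uv=20.0)),
        StageSpec("awake_eyes_covered", dur["awake_eyes_covered"],
                  replace(base, depth=0.0, slow_amp_uv=25.0)),
        StageSpec("injection_transient", dur["injection_transient"],
                  replace(base, depth=min(1.0, depth + 0.1), slow_amp_uv=120.0,
                          mod_freq_hz=1.2)),
        StageSpec("suppression", dur["suppression"],
                  replace(base, depth=0.1, slow_amp_uv=30.0, gamma_amp_uv=5.0)),
        StageSpec("anesthetized", dur["anesthetized"],
                  replace(base, slow_amp_uv=100.0)),
        StageSpec("recovery", dur["recovery"],
                  replace(base, depth=0.2, slow_amp_uv=40.0)),
    ]
    return SessionSpec(
        stages=stages,
        n_channels=n_channels,
        fs_hz=fs_hz,
        onset_delays_s=onset_delays_s,
        seed=seed,
    )
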