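"""In-memory containers shared across the pipeline.

A :class:`Recording` holds a continuous multichannel signal in microvolts
together with its event markers and (optionally) 2-D electrode coordinates.
A :class:`BandPair` holds the two band-decomposed series the tau-modulation
method correlates: the slow-wave signal (0.2-4 Hz by default) and the
amplitude envelope of broadband gamma (55-145 Hz by default), both at the
reduced feature rate (25 Hz by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Recording", "BandPair"]


@dataclass
class Recording:
    """Continuous multichannel electrophysiological recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    fs_hz : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per channel.
    markers : list of (str, float)
        Event markers as ``(label, time_s)`` pairs.
    condition_intervals : dict
        Labeled experimental conditions, ``label -> (start_s, end_s)``.
    channel_xy_mm : ndarray of shape (n_channels, 2), optional
        Electrode grid coordinates in millimetres.
    """

    samples: np.ndarray
    fs_hz: float
    channel_labels: list[str] = field(default_factory=list)
    markers: list[tuple[str, float]] = field(default_factory=list)
    condition_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    channel_xy_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_times) matrix")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match the channel count")
        dur = self.duration_s
        for label, t in self.markers:
            if not (0.0 <= t <= dur):
                raise ValueError(f"marker {label!r} at {t} s outside [0, {dur}] s")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs_hz

    def marker_time(self, label: str) -> float:
        """Time of the first marker with the given label."""
        for lab, t in self.markers:
            if lab == label:
                return t
        raise KeyError(f"no marker labeled {label!r}")

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)


@dataclass
class BandPair:
    """Aligned slow-wave series and broadband-gamma envelope at the feature rate.

    ``edge_mask`` is True at samples contaminated by FIR filter edges; windows
    touching masked samples are excluded from downstream statistics.
    """

    slow: np.ndarray
    gamma_env: np.ndarray
    rate_hz: float = 25.0
    start_time_s: float = 0.0
    slow_band_hz: tuple[float, float] = (0.2, 4.0)
    gamma_band_hz: tuple[float, float] = (55.0, 145.0)
    edge_mask: np.ndarray | None = None
    markers: list[tuple[str, float]] = field(default_factory=list)
    condition_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    channel_xy_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.slow = np.atleast_2d(np.asarray(self.slow, dtype=float))
        self.gamma_env = np.atleast_2d(np.asarray(self.gamma_env, dtype=float))
        if self.slow.shape != self.gamma_env.shape:
            raise ValueError("slow and gamma_env must have the same shape")
        if np.nanmin(self.gamma_env) < 0:
            raise ValueError("gamma_env must be non-negative")
        if self.edge_mask is None:
            self.edge_mask = np.zeros(self.slow.shape[1], dtype=bool)
        else:
            self.edge_mask = np.asarray(self.edge_mask, dtype=bool)
            if self.edge_mask.shape != (self.slow.shape[1],):
                raise ValueError("edge_mask must be one flag per time sample")

    @property
    def n_channels(self) -> int:
        return self.slow.shape[0]

    @property
    def n_times(self) -> int:
        return self.slow.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_times) / self.rate_hz
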