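"""Preprocessing: referencing, FIR filtering, envelopes, decimation.

The decomposition mirrors standard ECoG practice: common average reference,
FIR notch filters at the line frequency and its first harmonic, linear-phase
FIR bandpass into the slow-wave band and the broadband-gamma band, Hilbert
envelope of the gamma band, and anti-aliased decimation of both series to the
feature rate (25 Hz).

All FIR filters are Hamming-window designs applied in a single pass with the
group delay compensated, which is exactly zero-phase for a linear-phase
(symmetric) kernel. Samples within half a kernel length of either end are
edge-contaminated and flagged; the flags ride along in
:class:`~taumod.containers.BandPair.edge_mask`.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .containers import BandPair, Recording

__all__ = [
    "common_average_reference",
    "design_fir",
    "fir_filter",
    "notch_line_noise",
    "analytic_envelope",
    "resample_to",
    "extract_band_pair",
]

# Hamming-window FIR: transition width ~ 3.3 / numtaps (in cycles/sample).
_HAMMING_TBW = 3.3


def common_average_reference(recording: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean from every channel.

    Removes noise common to all electrodes (reference drift, some line noise).
    Markers and metadata pass through unchanged.
    """
    if recording.n_channels < 2:
        raise ValueError("common average reference requires at least 2 channels")
    car = recording.samples - recording.samples.mean(axis=0, keepdims=True)
    return recording.copy_with(samples=car)


def _default_transition_hz(mode: str, lo_hz: float) -> float:
    if mode == "bandstop":
        # the rule below would smear a 4 Hz-wide notch over tens of Hz
        return 2.0
    return max(0.25 * lo_hz, 0.1)


def design_fir(
    fs_hz: float,
    mode: str,
    lo_hz: float,
    hi_hz: float,
    transition_hz: float | None = None,
    max_taps: int | None = None,
) -> np.ndarray:
    """Design a linear-phase Hamming-window FIR kernel (odd length).

    ``transition_hz`` defaults to max(25% of the lower cutoff, 0.1 Hz) for
    bandpass and 2 Hz for bandstop. ``max_taps`` caps the kernel length (the
    transition widens accordingly) so that short signals remain filterable.
    """
    if mode not in ("bandpass", "bandstop"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if not (0.0 < lo_hz < hi_hz < fs_hz / 2.0):
        raise ValueError(
            f"band edges must satisfy 0 < lo < hi < Nyquist; got "
            f"({lo_hz}, {hi_hz}) at fs={fs_hz}"
        )
    if transition_hz is None:
        transition_hz = _default_transition_hz(mode, lo_hz)
    numtaps = int(np.ceil(_HAMMING_TBW * fs_hz / transition_hz))
    if max_taps is not None:
        numtaps = min(numtaps, max_taps)
    numtaps = max(numtaps, 33)
    if numtaps % 2 == 0:
        numtaps += 1
    taps = sps.firwin(
        numtaps,
        [lo_hz, hi_hz],
        fs=fs_hz,
        pass_zero=(mode == "bandstop"),
        window="hamming",
    )
    return taps


def fir_filter(
    x: np.ndarray,
    fs_hz: float,
    mode: str,
    lo_hz: float,
    hi_hz: float,
    transition_hz: float | None = None,
) -> np.ndarray:
    """Zero-phase linear-phase FIR bandpass/bandstop along the last axis.

    Output length equals input length. Raises if the signal is too short to
    support even a minimal kernel (length < 3x the filter order).
    """
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("input contains NaN; preprocessing requires continuous data")
    n = x.shape[-1]
    # cap the kernel so the 3x-order length requirement stays satisfiable
    taps = design_fir(fs_hz, mode, lo_hz, hi_hz, transition_hz, max_taps=(n - 1) // 3)
    if n < 3 * (len(taps) - 1):
        raise ValueError(
            f"signal of {n} samples is shorter than 3x the filter order "
            f"({len(taps) - 1})"
        )
    return _convolve_zero_phase(x, taps)


def _convolve_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Single-pass FIR with compensated delay; kernel length must be odd."""
    if x.ndim == 1:
        return sps.fftconvolve(x, taps, mode="same")
    return sps.fftconvolve(x, taps[np.newaxis, :], mode="same", axes=-1)


def edge_samples(taps_or_len: np.ndarray | int) -> int:
    """Number of edge-contaminated samples per side for a symmetric kernel."""
    n = taps_or_len if isinstance(taps_or_len, int) else len(taps_or_len)
    return (n - 1) // 2


def notch_line_noise(
    recording: Recording,
    bands_hz: tuple[tuple[float, float], ...] = ((48.0, 52.0), (98.0, 102.0)),
    transition_hz: float = 2.0,
) -> Recording:
    """Apply FIR bandstop filters at the line frequency and harmonics."""
    out = recording.samples
    for lo, hi in bands_hz:
        out = fir_filter(out, recording.fs_hz, "bandstop", lo, hi, transition_hz)
    return recording.copy_with(samples=out)


def analytic_envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic (Hilbert) signal along the last axis."""
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("input contains NaN")
    return np.abs(sps.hilbert(x, axis=-1))


def resample_to(
    x: np.ndarray, fs_in_hz: float, fs_out_hz: float
) -> tuple[np.ndarray, int]:
    """Anti-aliased decimation along the last axis.

    The decimation factor must be an integer. An FIR low-pass with cutoff
    ``0.4 * fs_out_hz`` is applied before taking every k-th sample, so content
    above the output Nyquist is suppressed by well over 40 dB. Output length
    is ``ceil(n / k)``.

    Returns
    -------
    (y, n_edge) : the decimated signal and the number of edge-contaminated
        samples per side *at the output rate*.
    """
    if fs_out_hz >= fs_in_hz:
        raise ValueError("resample_to only decimates; fs_out must be < fs_in")
    factor = fs_in_hz / fs_out_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"fs_in/fs_out must be an integer ratio; got {fs_in_hz}/{fs_out_hz}"
        )
    factor = int(round(factor))
    x = np.asarray(x, dtype=float)
    cutoff = 0.4 * fs_out_hz
    transition = 0.2 * fs_out_hz
    numtaps = int(np.ceil(_HAMMING_TBW * fs_in_hz / transition))
    if numtaps % 2 == 0:
        numtaps += 1
    taps = sps.firwin(numtaps, cutoff, fs=fs_in_hz, window="hamming")
    y = _convolve_zero_phase(x, taps)[..., ::factor]
    n_edge_out = int(np.ceil(edge_samples(taps) / factor))
    return y, n_edge_out


def extract_band_pair(
    recording: Recording,
    slow_band_hz: tuple[float, float] = (0.2, 4.0),
    gamma_band_hz: tuple[float, float] = (55.0, 145.0),
    rate_hz: float = 25.0,
    slow_transition_hz: float | None = None,
    gamma_transition_hz: float | None = None,
) -> BandPair:
    """Decompose a recording into the slow-wave / gamma-envelope pair at 25 Hz.

    Order of operations: bandpass each band at the native rate, take the
    Hilbert envelope of the gamma band (envelope-then-decimate), then decimate
    both series to ``rate_hz``. Filter-edge contamination from every stage is
    accumulated into the output ``edge_mask``.
    """
    if recording.duration_s < 10.0:
        raise ValueError("recording must be at least 10 s long")
    if gamma_band_hz[1] >= recording.fs_hz / 2:
        raise ValueError("gamma band upper edge must be below Nyquist")
    fs = recording.fs_hz
    x = recording.samples
    n = x.shape[-1]

    slow_taps = design_fir(
        fs, "bandpass", *slow_band_hz, slow_transition_hz, max_taps=(n - 1) // 3
    )
    gamma_taps = design_fir(
        fs, "bandpass", *gamma_band_hz, gamma_transition_hz, max_taps=(n - 1) // 3
    )
    slow = _convolve_zero_phase(x, slow_taps)
    gamma = _convolve_zero_phase(x, gamma_taps)
    gamma_env = np.abs(sps.hilbert(gamma, axis=-1))

    slow_25, aa_edge = resample_to(slow, fs, rate_hz)
    gamma_env_25, _ = resample_to(gamma_env, fs, rate_hz)

    factor = int(round(fs / rate_hz))
    slow_edge = int(np.ceil(edge_samples(slow_taps) / factor)) + aa_edge
    gamma_edge = int(np.ceil(edge_samples(gamma_taps) / factor)) + aa_edge
    n_edge = max(slow_edge, gamma_edge)

    n_out = slow_25.shape[-1]
    mask = np.zeros(n_out, dtype=bool)
    if n_edge > 0:
        mask[: min(n_edge, n_out)] = True
        mask[-min(n_edge, n_out):] = True

    return BandPair(
        slow=slow_25,
        gamma_env=gamma_env_25,
        rate_hz=rate_hz,
        start_time_s=0.0,
        slow_band_hz=slow_band_hz,
        gamma_band_hz=gamma_band_hz,
        edge_mask=mask,
        markers=list(recording.markers),
        condition_intervals=dict(recording.condition_intervals),
        channel_xy_mm=recording.channel_xy_mm,
    )
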