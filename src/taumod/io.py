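"""Readers and writers: EDF, the columnar text format, and result tables.

Two recording formats are supported:

* **EDF** -- the standard 16-bit European Data Format. Reading goes through
  :mod:`mne`; writing uses a minimal built-in EDF writer (one 1 s data
  record per second, per-channel physical scaling). Plain EDF has no
  annotation stream, so markers and condition intervals live in a sidecar
  ``<name>.markers.tsv`` written and read alongside the EDF file.
* **columnar** -- a self-describing UTF-8 tab-separated table: commented
  header lines carry the sampling rate, channel labels, markers, condition
  intervals and sample count, followed by one row per sample
  (``time_s`` plus one column per channel, microvolts).

Feature series, ground-truth tables and propagation maps are written as
tab-separated UTF-8 tables with NaN encoded as an empty field.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Recording
from .features import FeatureSeries

__all__ = [
    "read_recording",
    "write_recording",
    "write_columnar",
    "read_columnar",
    "write_edf",
    "read_edf",
    "write_feature_table",
    "read_feature_table",
    "write_ground_truth",
    "read_ground_truth",
]

_COLUMNAR_MAGIC = "# taumod-recording v1"


# --------------------------------------------------------------------------
# columnar text format
# --------------------------------------------------------------------------

def write_columnar(recording: Recording, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_COLUMNAR_MAGIC + "\n")
        fh.write(f"# fs_hz\t{float(recording.fs_hz)!r}\n")
        fh.write(f"# n_samples\t{recording.n_times}\n")
        fh.write("# channels\t" + "\t".join(recording.channel_labels) + "\n")
        for label, t in recording.markers:
            fh.write(f"# marker\t{label}\t{float(t)!r}\n")
        for label, (lo, hi) in recording.condition_intervals.items():
            fh.write(f"# interval\t{label}\t{float(lo)!r}\t{float(hi)!r}\n")
        if recording.channel_xy_mm is not None:
            for lab, (x, y) in zip(recording.channel_labels, recording.channel_xy_mm):
                fh.write(f"# channel_xy\t{lab}\t{float(x)!r}\t{float(y)!r}\n")
        fh.write("time_s\t" + "\t".join(recording.channel_labels) + "\n")
        times = recording.times_s
        body = np.column_stack([times, recording.samples.T])
        np.savetxt(fh, body, fmt="%.6f", delimiter="\t")


def read_columnar(path) -> Recording:
    path = Path(path)
    fs_hz = None
    n_samples = None
    labels: list[str] = []
    markers: list[tuple[str, float]] = []
    intervals: dict[str, tuple[float, float]] = {}
    xy: dict[str, tuple[float, float]] = {}
    header_rows = 0
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != _COLUMNAR_MAGIC:
            raise ValueError(f"{path} is not a taumod columnar recording")
        header_rows += 1
        for line in fh:
            header_rows += 1
            if not line.startswith("#"):
                break
            parts = line[1:].strip().split("\t")
            key = parts[0]
            if key == "fs_hz":
                fs_hz = float(parts[1])
            elif key == "n_samples":
                n_samples = int(parts[1])
            elif key == "channels":
                labels = parts[1:]
            elif key == "marker":
                markers.append((parts[1], float(parts[2])))
            elif key == "interval":
                intervals[parts[1]] = (float(parts[2]), float(parts[3]))
            elif key == "channel_xy":
                xy[parts[1]] = (float(parts[2]), float(parts[3]))
    if fs_hz is None or not labels or n_samples is None:
        raise ValueError(f"{path}: incomplete columnar header")
    data = pd.read_csv(
        path, sep="\t", skiprows=header_rows - 1, header=0, dtype=float
    )
    expected = ["time_s", *labels]
    if list(data.columns) != expected:
        raise ValueError(f"{path}: column header does not match channel list")
    if len(data) != n_samples or data.isna().any().any():
        raise ValueError(
            f"{path}: truncated or corrupt data section "
            f"({len(data)} rows read, {n_samples} declared)"
        )
    samples = data[labels].to_numpy().T
    channel_xy = None
    if xy:
        channel_xy = np.array([xy[lab] for lab in labels])
    return Recording(
        samples=samples,
        fs_hz=fs_hz,
        channel_labels=labels,
        markers=markers,
        condition_intervals=intervals,
        channel_xy_mm=channel_xy,
    )


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", errors="replace")[:n]
    return b + b" " * (n - len(b))


def write_edf(recording: Recording, path) -> None:
    """Write a minimal 16-bit EDF file (1 s data records).

    The sampling rate must be a whole number; the signal is truncated to
    whole seconds. Markers and condition intervals go to a
    ``<name>.markers.tsv`` sidecar because plain EDF cannot carry them.
    """
    path = Path(path)
    fs = recording.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writing requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_rec = recording.n_times // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    x = recording.samples[:, : n_rec * fs]

    pmin = x.min(axis=1)
    pmax = x.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate X X X X", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (n_ch + 1)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_ch), 4))
        for lab in recording.channel_labels:
            fh.write(_pad(lab, 16))
        for _ in range(n_ch):
            fh.write(_pad("", 80))
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        for v in pmin:
            fh.write(_pad(f"{v:.8g}"[:8], 8))
        for v in pmax:
            fh.write(_pad(f"{v:.8g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dmin), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dmax), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 80))
        for _ in range(n_ch):
            fh.write(_pad(str(fs), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 32))
        scale = (dmax - dmin) / (pmax - pmin)
        for r in range(n_rec):
            seg = x[:, r * fs : (r + 1) * fs]
            dig = np.rint((seg - pmin[:, None]) * scale[:, None] + dmin)
            fh.write(dig.astype("<i2").tobytes())

    _write_marker_sidecar(recording, _sidecar_path(path))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".markers.tsv")


def _write_marker_sidecar(recording: Recording, path: Path) -> None:
    rows = [
        dict(kind="marker", label=lab, start_s=t, end_s=np.nan)
        for lab, t in recording.markers
    ]
    rows += [
        dict(kind="interval", label=lab, start_s=lo, end_s=hi)
        for lab, (lo, hi) in recording.condition_intervals.items()
    ]
    pd.DataFrame(rows, columns=["kind", "label", "start_s", "end_s"]).to_csv(
        path, sep="\t", index=False, na_rep=""
    )


def _read_marker_sidecar(path: Path):
    markers: list[tuple[str, float]] = []
    intervals: dict[str, tuple[float, float]] = {}
    if not path.exists():
        return markers, intervals
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        if row["kind"] == "marker":
            markers.append((str(row["label"]), float(row["start_s"])))
        else:
            intervals[str(row["label"])] = (float(row["start_s"]), float(row["end_s"]))
    return markers, intervals


def read_edf(path) -> Recording:
    """Read an EDF recording via mne; microvolt units, sidecar markers."""
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # mne returns volts
    markers, intervals = _read_marker_sidecar(_sidecar_path(path))
    return Recording(
        samples=samples,
        fs_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        markers=markers,
        condition_intervals=intervals,
    )


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------

def read_recording(path, fmt: str | None = None) -> Recording:
    """Read a recording, sniffing the format from the extension if needed."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "columnar"
    if fmt == "edf":
        return read_edf(path)
    if fmt == "columnar":
        return read_columnar(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_recording(recording: Recording, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "columnar"
    if fmt == "edf":
        write_edf(recording, path)
    elif fmt == "columnar":
        write_columnar(recording, path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


# --------------------------------------------------------------------------
# feature / ground-truth tables
# --------------------------------------------------------------------------

_FEATURE_COLS = ["time_s", "channel", "strength_raw", "strength_z", "freq_hz", "polarity"]


def write_feature_table(series: list[FeatureSeries], path) -> None:
    """Write per-channel feature series as one long tab-separated table."""
    frames = []
    for fs in series:
        z = fs.strength_z if fs.strength_z is not None else np.full(len(fs.times_s), np.nan)
        frames.append(
            pd.DataFrame(
                dict(
                    time_s=fs.times_s,
                    channel=fs.channel,
                    strength_raw=fs.strength_raw,
                    strength_z=z,
                    freq_hz=fs.freq_hz,
                    polarity=fs.polarity,
                )
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_FEATURE_COLS)
    )
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _FEATURE_COLS:
        raise ValueError(f"{path}: unexpected feature table header")
    return df


def write_ground_truth(ground_truth: pd.DataFrame, path) -> None:
    ground_truth.to_csv(path, sep="\t", index=False, na_rep="")


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
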