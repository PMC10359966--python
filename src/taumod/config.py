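"""Pipeline configuration with the method's published defaults."""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the tau-modulation pipeline.

    Defaults reproduce the published analysis: slow band 0.2-4 Hz, broadband
    gamma 55-145 Hz, 25 Hz feature rate, 2.56 s correlation windows stepped
    0.2 s, lags spanning +-1.28 s (64 lags), 5 s observation windows
    (25 TMCs), line-noise notches at 48-52 and 98-102 Hz, baseline = awake
    eyes-covered, propagation analysis 5-20 min after injection thresholded
    by the anesthetized-period mean.
    """

    slow_lo_hz: float = 0.2
    slow_hi_hz: float = 4.0
    gamma_lo_hz: float = 55.0
    gamma_hi_hz: float = 145.0
    rate_hz: float = 25.0
    window_s: float = 2.56
    step_s: float = 0.2
    observation_s: float = 5.0
    polarity_half_width_s: float = 0.12
    oscillatory_threshold_hz: float = 0.2
    notch_bands_hz: tuple[tuple[float, float], ...] = ((48.0, 52.0), (98.0, 102.0))
    baseline_label: str = "awake_eyes_covered"
    threshold_label: str = "anesthetized"
    analysis_start_s: float = 300.0
    analysis_end_s: float = 1200.0
    apply_car: bool = True
    apply_notch: bool = True
    seed: int = 0

    @property
    def n_obs_tmcs(self) -> int:
        return int(round(self.observation_s / self.step_s))

    # ---- flat key=value round trip -------------------------------------
    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "notch_bands_hz":
                v = ";".join(f"{lo}-{hi}" for lo, hi in v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise KeyError(f"unknown configuration key {key!r}")
            if key == "notch_bands_hz":
                bands = []
                for part in val.split(";"):
                    lo, _, hi = part.partition("-")
                    bands.append((float(lo), float(hi)))
                kwargs[key] = tuple(bands)
            elif key in ("baseline_label", "threshold_label"):
                kwargs[key] = val
            elif key in ("apply_car", "apply_notch"):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif key == "seed":
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_text(fh.read())
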