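"""End-to-end tau-modulation pipeline.

Raw recording -> (CAR, notch) -> band pair at 25 Hz -> TMC series per
channel -> strength / frequency / polarity feature series -> optional
propagation map when an injection marker is present.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .containers import BandPair, Recording
from .features import FeatureSeries, compute_features, default_dictionary, normalize_strength
from .preprocess import common_average_reference, extract_band_pair, notch_line_noise
from .propagation import PropagationMap, propagation_map
from .tmc import LagGrid, TMCSeries, tmc_series

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger("taumod")


@dataclass
class PipelineResult:
    band_pair: BandPair
    tmc: list[TMCSeries]
    features: list[FeatureSeries]
    propagation: PropagationMap | None = None
    timings_s: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    recording: Recording,
    config: PipelineConfig | None = None,
    with_frequency: bool = True,
    with_propagation: bool = True,
) -> PipelineResult:
    """Run the full analysis on every channel of a recording.

    Baseline z-normalization uses the condition interval named by
    ``config.baseline_label`` when the recording carries it; otherwise
    ``strength_z`` stays unset. The propagation map needs an ``injection``
    marker and is skipped (with a log message) without one.
    """
    cfg = config or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    rec = recording
    if cfg.apply_car and rec.n_channels >= 2:
        rec = common_average_reference(rec)
    if cfg.apply_notch:
        rec = notch_line_noise(rec, cfg.notch_bands_hz)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pair = extract_band_pair(
        rec,
        slow_band_hz=(cfg.slow_lo_hz, cfg.slow_hi_hz),
        gamma_band_hz=(cfg.gamma_lo_hz, cfg.gamma_hi_hz),
        rate_hz=cfg.rate_hz,
    )
    timings["band_pair"] = time.perf_counter() - t0

    grid = LagGrid(rate_hz=cfg.rate_hz, n_lags=int(round(cfg.window_s * cfg.rate_hz)))
    dictionary = default_dictionary(grid) if with_frequency else None
    baseline = rec.condition_intervals.get(cfg.baseline_label)

    tmcs: list[TMCSeries] = []
    feats: list[FeatureSeries] = []
    t0 = time.perf_counter()
    for ch in range(pair.n_channels):
        tmc = tmc_series(
            pair, channel=ch, window_s=cfg.window_s, step_s=cfg.step_s, lag_grid=grid
        )
        fs = compute_features(
            tmc,
            baseline_interval_s=None,
            channel=rec.channel_labels[ch],
            polarity_half_width_s=cfg.polarity_half_width_s,
            oscillatory_threshold_hz=cfg.oscillatory_threshold_hz,
            n_obs=cfg.n_obs_tmcs,
            dictionary=dictionary,
            with_frequency=with_frequency,
        )
        if baseline is not None:
            try:
                fs.strength_z = normalize_strength(fs.times_s, fs.strength_raw, baseline)
            except ValueError as err:
                logger.warning("channel %s: %s", fs.channel, err)
        tmcs.append(tmc)
        feats.append(fs)
        logger.info(
            "channel %s: %d windows (%d invalid), %d degenerate strength values",
            rec.channel_labels[ch],
            tmc.n_windows,
            int((~tmc.valid).sum()),
            int(np.isnan(fs.strength_raw).sum()),
        )
    timings["tmc_features"] = time.perf_counter() - t0

    prop: PropagationMap | None = None
    if with_propagation:
        try:
            injection = rec.marker_time("injection")
        except KeyError:
            logger.info("no injection marker; skipping propagation map")
        else:
            t0 = time.perf_counter()
            thr = rec.condition_intervals.get(cfg.threshold_label)
            thr_rel = (thr[0] - injection, thr[1] - injection) if thr else None
            prop = propagation_map(
                feats,
                injection_time_s=injection,
                channel_xy_mm=rec.channel_xy_mm,
                analysis_interval_s=(cfg.analysis_start_s, cfg.analysis_end_s),
                threshold_interval_s=thr_rel,
            )
            timings["propagation"] = time.perf_counter() - t0

    for stage, dt in timings.items():
        logger.info("stage %-12s %.2f s", stage, dt)
    return PipelineResult(
        band_pair=pair, tmc=tmcs, features=feats, propagation=prop, timings_s=timings
    )
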