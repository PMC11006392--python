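"""Signal conditioning of raw track tables into analysis-ready series.

Tip fluorescence is background-subtracted against the growth-cone boundary
signal and normalised to the growth-cone body; tip movement has extreme
values masked (not clipped) and is smoothed with a short centred moving
average; base fluorescence is additionally linearly detrended. Missing
frames stay missing through every step (mask-monotone operations) so the
downstream pairwise-complete correlation machinery sees the gaps.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .io_tables import FilopodiumTrack

__all__ = [
    "ProcessedSeries",
    "PreprocessConfig",
    "normalize_fluorescence",
    "detrend_linear",
    "trim_outliers",
    "moving_average",
    "preprocess_track",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ProcessedSeries:
    """Processed per-frame series for one filopodium.

    F: normalised tip fluorescence (dimensionless); M: smoothed tip movement
    (um/frame); B: detrended, smoothed base fluorescence (optional). All are
    aligned to the track's frame axis with NaN marking masked entries.
    """

    track_id: str
    frame_interval: float
    F: np.ndarray
    M: np.ndarray
    B: np.ndarray | None = None


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    """Processing parameters. The default preset mirrors routine imaging
    (0.5% tail trim, window-3 smoothing); the ``casin`` preset uses the
    harsher 1% trim and window-5 smoothing applied to drug-treatment videos."""

    tail_fraction: float = 0.005
    movement_window: int = 3
    base_window: int = 5
    normalize: bool = True
    detrend_base: bool = True
    divide_by_body_minus_boundary: bool = True

    @classmethod
    def casin(cls) -> "PreprocessConfig":
        return cls(tail_fraction=0.01, movement_window=5)


def normalize_fluorescence(
    raw: np.ndarray,
    boundary: np.ndarray,
    body: np.ndarray,
    divide_by_body_minus_boundary: bool = True,
) -> np.ndarray:
    """Background-subtract and normalise a fluorescence series.

    out_t = (raw_t - boundary_t) / (body_t - boundary_t), or
    (raw_t - boundary_t) / body_t with the alternative convention. Frames
    where the denominator is non-positive are masked with a warning; missing
    inputs propagate.
    """
    raw = np.asarray(raw, dtype=float)
    boundary = np.asarray(boundary, dtype=float)
    body = np.asarray(body, dtype=float)
    denom = (body - boundary) if divide_by_body_minus_boundary else body
    bad = np.isfinite(denom) & (denom <= 0)
    if bad.any():
        logger.warning("masking %d frames with non-positive normalisation denominator", bad.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (raw - boundary) / denom
    out[bad] = np.nan
    return out


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend, keeping the series mean.

    The line is fitted over non-missing frames; the mean over those frames is
    added back so the output stays in interpretable normalised units.
    """
    x = np.asarray(series, dtype=float)
    valid = np.isfinite(x)
    if valid.sum() < 3:
        raise ValueError("detrend_linear requires at least 3 valid frames")
    t = np.arange(len(x), dtype=float)
    slope, intercept = np.polyfit(t[valid], x[valid], 1)
    out = x - (slope * t + intercept) + x[valid].mean()
    return out


def trim_outliers(series: np.ndarray, tail_fraction: float) -> np.ndarray:
    """Mask values strictly beyond the symmetric tail quantiles.

    Quantiles use linear interpolation over valid entries; masked values are
    set to NaN rather than clipped, so gaps flow into the correlation stage.
    """
    if not 0 <= tail_fraction <= 0.1:
        raise ValueError("tail_fraction must lie in [0, 0.1]")
    x = np.asarray(series, dtype=float).copy()
    if tail_fraction == 0:
        return x
    valid = np.isfinite(x)
    if not valid.any():
        return x
    lo, hi = np.quantile(x[valid], [tail_fraction, 1.0 - tail_fraction])
    x[valid & ((x < lo) | (x > hi))] = np.nan
    return x


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average over available values, truncated at the ends.

    The window must be odd and positive. Missing values inside a window are
    simply excluded; the output is missing only where every value in the
    window is missing.
    """
    if window <= 0 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    x = np.asarray(series, dtype=float)
    n = len(x)
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        seg = x[max(0, i - half) : min(n, i + half + 1)]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            out[i] = seg.mean()
    return out


def preprocess_track(
    track: FilopodiumTrack, cfg: PreprocessConfig | None = None
) -> ProcessedSeries:
    """Produce the processed series used by all downstream statistics.

    F = normalised tip fluorescence; M = moving_average(trim_outliers(tip
    movement)); B = moving_average(detrend_linear(normalised base
    fluorescence), base_window) when computable.
    """
    cfg = cfg or PreprocessConfig()
    tip = track.column("tip_fluor")
    boundary = track.column("boundary_fluor")
    body = track.column("body_fluor")
    base = track.column("base_fluor")
    movement = track.column("tip_movement")
    if cfg.normalize:
        F = normalize_fluorescence(tip, boundary, body, cfg.divide_by_body_minus_boundary)
        B_norm = normalize_fluorescence(base, boundary, body, cfg.divide_by_body_minus_boundary)
    else:
        F = tip.copy()
        B_norm = base.copy()
    M = moving_average(trim_outliers(movement, cfg.tail_fraction), cfg.movement_window)
    B: np.ndarray | None
    try:
        B_det = detrend_linear(B_norm) if cfg.detrend_base else B_norm
        B = moving_average(B_det, cfg.base_window)
    except ValueError:
        B = None
    return ProcessedSeries(
        track_id=track.track_id,
        frame_interval=track.frame_interval,
        F=F,
        M=M,
        B=B,
    )
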