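"""Two-channel punctum detection, overlap scoring and SMLM post-processing.

Puncta are connected components (8-connectivity) of a thresholded image,
retained when their physical area lies within [min_area, max_area]
(0.06-1.00 um^2 by default; at a 0.065 um pixel the lower bound is ~14
pixels). Overlap puncta are components of the pixelwise conjunction of the
two channel masks, filtered by the same area rule. Localisation tables from
single-molecule imaging are filtered on photon count, precision, fit quality
and PSF width, then rendered as a 2-D histogram blurred by the mean
localisation precision.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters as skfilters
from skimage import measure

__all__ = [
    "Punctum",
    "PunctaSet",
    "PunctumTrack",
    "EventAlignedSet",
    "threshold_mask",
    "detect_puncta",
    "overlap_puncta",
    "tip_localized",
    "link_puncta",
    "density_by_length_group",
    "align_to_events",
    "smlm_filter",
    "smlm_render",
    "SMLM_DEFAULT_BOUNDS",
]


@dataclasses.dataclass
class Punctum:
    label: int
    pixels: np.ndarray        # (n, 2) array of (row, col) indices
    area: float               # um^2
    centroid: tuple[float, float]  # (row, col) in um
    channel: str              # 'A', 'B' or 'overlap'


@dataclasses.dataclass
class PunctaSet:
    frame_index: int
    pixel_size: float
    puncta: list[Punctum]

    def __len__(self) -> int:
        return len(self.puncta)

    def centroids(self) -> np.ndarray:
        if not self.puncta:
            return np.empty((0, 2))
        return np.array([p.centroid for p in self.puncta])


def threshold_mask(image: np.ndarray, threshold: float | str = "auto") -> np.ndarray:
    """Binary mask of pixels at or above the threshold.

    ``threshold='auto'`` uses Otsu's global method; the imaging data in the
    study was thresholded manually, so a per-channel numeric threshold is the
    first-class path.
    """
    img = np.asarray(image, dtype=float)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError("threshold must be a number or 'auto'")
        threshold = skfilters.threshold_otsu(img)
    return img >= threshold


def detect_puncta(
    mask: np.ndarray,
    pixel_size: float,
    min_area: float = 0.06,
    max_area: float = 1.00,
    frame_index: int = 0,
    channel: str = "A",
) -> PunctaSet:
    """Connected components of a binary mask, filtered by physical area.

    8-connectivity. The area bounds are converted to pixel counts by rounding
    (at a 0.065 um pixel, 0.06 um^2 -> 14 pixels) and a component is retained
    when its pixel count lies within the rounded bounds inclusive, matching
    the particle-analysis convention the bounds come from.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    labelled = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    puncta = []
    px_area = pixel_size**2
    min_px = int(round(min_area / px_area))
    max_px = np.inf if np.isinf(max_area) else int(round(max_area / px_area))
    for region in measure.regionprops(labelled):
        area = region.num_pixels * px_area
        if min_px <= region.num_pixels <= max_px:
            puncta.append(
                Punctum(
                    label=region.label,
                    pixels=region.coords,
                    area=area,
                    centroid=(region.centroid[0] * pixel_size, region.centroid[1] * pixel_size),
                    channel=channel,
                )
            )
    return PunctaSet(frame_index=frame_index, pixel_size=pixel_size, puncta=puncta)


def overlap_puncta(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    pixel_size: float,
    min_area: float = 0.06,
    max_area: float = 1.00,
    frame_index: int = 0,
) -> PunctaSet:
    """Area-filtered components where both channels are simultaneously
    positive (the AND region of the summed binaries)."""
    overlap = np.asarray(mask_a, dtype=bool) & np.asarray(mask_b, dtype=bool)
    return detect_puncta(
        overlap, pixel_size, min_area, max_area, frame_index=frame_index, channel="overlap"
    )


def tip_localized(
    puncta: PunctaSet, tip: tuple[float, float], circle_diameter: float = 1.0
) -> PunctaSet:
    """Subset of puncta at least half inside a circle anchored at the tip.

    "Half" is measured by pixel count with a pixel-centre-inside test; tip
    coordinates are (row, col) in micrometres.
    """
    radius = circle_diameter / 2.0
    ps = puncta.pixel_size
    kept = []
    for p in puncta.puncta:
        centres = (p.pixels + 0.0) * ps  # pixel centres in um
        d2 = (centres[:, 0] - tip[0]) ** 2 + (centres[:, 1] - tip[1]) ** 2
        inside = int((d2 <= radius**2).sum())
        if 2 * inside >= len(p.pixels):
            kept.append(p)
    return PunctaSet(frame_index=puncta.frame_index, pixel_size=ps, puncta=kept)


@dataclasses.dataclass
class PunctumTrack:
    track_id: int
    frames: list[int]
    centroids: list[tuple[float, float]]    # um
    fate: str | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def start_centroid(self) -> tuple[float, float]:
        return self.centroids[0]


def _point_polyline_distance(point: np.ndarray, polyline: np.ndarray) -> float:
    """Minimum distance from a point to a polyline given as (n, 2) vertices."""
    if len(polyline) == 1:
        return float(np.hypot(*(point - polyline[0])))
    best = np.inf
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((point - a) @ ab / denom, 0.0, 1.0))
        proj = a + t * ab
        best = min(best, float(np.hypot(*(point - proj))))
    return best


def link_puncta(
    frames: Sequence[PunctaSet],
    max_link: float = 0.65,
    min_frames: int = 5,
    start_boundary_dist: float = 1.0,
    boundary: np.ndarray | None = None,
) -> list[PunctumTrack]:
    """Greedy nearest-neighbour linking of puncta across consecutive frames.

    Between each pair of frames the globally closest centroid pair is linked
    first, then the next closest among unassigned puncta, while the distance
    stays within ``max_link`` (um); there is no gap closing. Tracks shorter
    than ``min_frames`` or starting farther than ``start_boundary_dist`` from
    the boundary polyline (um coordinates) are discarded.
    """
    active: dict[int, PunctumTrack] = {}   # index in previous frame -> track
    finished: list[PunctumTrack] = []
    next_id = 0
    prev_set: PunctaSet | None = None
    for fs in frames:
        new_active: dict[int, PunctumTrack] = {}
        if prev_set is not None and len(prev_set) and len(fs):
            prev_c = prev_set.centroids()
            cur_c = fs.centroids()
            d = np.linalg.norm(prev_c[:, None, :] - cur_c[None, :, :], axis=2)
            d = d.copy()
            while True:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                if not np.isfinite(d[i, j]) or d[i, j] > max_link:
                    break
                track = active.pop(i, None)
                if track is None:
                    track = PunctumTrack(track_id=next_id, frames=[prev_set.frame_index],
                                         centroids=[tuple(prev_c[i])])
                    next_id += 1
                track.frames.append(fs.frame_index)
                track.centroids.append(tuple(cur_c[j]))
                new_active[j] = track
                d[i, :] = np.inf
                d[:, j] = np.inf
        finished.extend(active.values())
        active = new_active
        prev_set = fs
    finished.extend(active.values())
    kept = []
    for tr in finished:
        if tr.n_frames < min_frames:
            continue
        if boundary is not None:
            dist = _point_polyline_distance(np.asarray(tr.start_centroid), np.asarray(boundary))
            if dist > start_boundary_dist:
                continue
        kept.append(tr)
    for new_id, tr in enumerate(kept):
        tr.track_id = new_id
    return kept


def density_by_length_group(
    filopodia: Sequence[Mapping],
    group_edges: Sequence[float],
) -> pd.DataFrame:
    """Overlap-punctum density (puncta per um) summarised by length group.

    Each filopodium record needs ``length`` (um) and ``count``; zero- or
    negative-length filopodia are excluded. Returns per-group median, IQR and
    n, with groups labelled by their [lo, hi) edges.
    """
    rows = []
    for f in filopodia:
        if f["length"] <= 0:
            continue
        rows.append((f["length"], f["count"] / f["length"]))
    df = pd.DataFrame(rows, columns=["length", "density"])
    if df.empty:
        return pd.DataFrame(columns=["group", "n", "median", "q25", "q75"])
    df["group"] = pd.cut(df["length"], bins=list(group_edges), right=False)
    out = (
        df.groupby("group", observed=True)["density"]
        .agg(n="size", median="median", q25=lambda s: s.quantile(0.25),
             q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    out["group"] = out["group"].astype(str)
    return out


# ---------------------------------------------------------------------------
# Event-aligned traces
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EventAlignedSet:
    """Traces re-indexed to event-relative time with pooled summaries.

    ``rel_time`` is in seconds with 0 at the event frame; the per-event
    matrices have one row per event; ``pooled`` has columns (rel_time,
    prevalence, prev_ci_low, prev_ci_high, n_overlap, velocity, vel_ci_low,
    vel_ci_high, n_velocity). Pooled curves are smoothed with a 3-frame
    moving average.
    """

    rel_time: np.ndarray
    velocity: np.ndarray
    overlap: np.ndarray
    fluor: dict[str, np.ndarray]
    events: list[dict]
    pooled: pd.DataFrame


def _sample_tip(
    arr: np.ndarray, position: np.ndarray, pixel_size: float, reduce: str
) -> np.ndarray:
    """Sample a frames x axial-pixel array over a 5-pixel window at the tip."""
    n, width = arr.shape
    out = np.full(n, np.nan)
    for t in range(n):
        if not np.isfinite(position[t]):
            continue
        c = int(round(position[t] / pixel_size))
        lo, hi = max(0, c - 2), min(width, c + 3)
        if lo >= hi:
            continue
        seg = arr[t, lo:hi]
        if reduce == "any":
            out[t] = float(np.nanmax(seg) > 0)
        else:
            out[t] = float(np.nanmean(seg))
    return out


def align_to_events(
    traces: Sequence[Mapping],
    events: Sequence[Mapping],
    window: float,
    frame_interval: float,
    pixel_size: float = 0.065,
    smooth_window: int = 3,
    ci_method: str = "normal",
) -> EventAlignedSet:
    """Re-index per-filopodium traces to event-relative time and pool.

    Each ``traces[i]`` corresponds to ``events[i]`` and provides ``position``
    (tip position along the straightened axis, um per frame) plus ``overlap``
    and optional ``fluor_*`` series, either per-frame 1-D arrays or
    frames x axial-pixels 2-D arrays sampled over a 5-pixel window centred on
    the tip. Velocity is the per-frame displacement divided by the frame
    interval. Pooled prevalence uses a binomial CI (normal approximation by
    default, Wilson optionally); pooled velocity uses mean +/- 1.96 SEM; both
    are smoothed with a centred 3-frame moving average.
    """
    from .preprocess import moving_average

    if len(traces) != len(events):
        raise ValueError("traces and events must be matched 1:1")
    W = int(round(window / frame_interval))
    rel_frames = np.arange(-W, W + 1)
    n_ev = len(events)
    vel_mat = np.full((n_ev, len(rel_frames)), np.nan)
    ovl_mat = np.full((n_ev, len(rel_frames)), np.nan)
    fluor_keys = sorted(
        {k for tr in traces for k in tr if str(k).startswith("fluor")}
    )
    fluor_mats = {k: np.full((n_ev, len(rel_frames)), np.nan) for k in fluor_keys}
    for i, (tr, ev) in enumerate(zip(traces, events)):
        pos = np.asarray(tr["position"], dtype=float)
        n = len(pos)
        vel = np.full(n, np.nan)
        vel[1:] = np.diff(pos) / frame_interval
        ovl = np.asarray(tr["overlap"], dtype=float)
        if ovl.ndim == 2:
            ovl = _sample_tip(ovl, pos, pixel_size, reduce="any")
        series = {"vel": vel, "ovl": ovl}
        for k in fluor_keys:
            if k not in tr:
                continue
            f = np.asarray(tr[k], dtype=float)
            if f.ndim == 2:
                f = _sample_tip(f, pos, pixel_size, reduce="mean")
            series[k] = f
        t0 = int(ev["frame"])
        for j, df_ in enumerate(rel_frames):
            t = t0 + df_
            if 0 <= t < n:
                vel_mat[i, j] = series["vel"][t]
                ovl_mat[i, j] = series["ovl"][t]
                for k in fluor_keys:
                    if k in series:
                        fluor_mats[k][i, j] = series[k][t]
    rows = []
    for j, rf in enumerate(rel_frames):
        ov = ovl_mat[:, j]
        ov = ov[np.isfinite(ov)]
        if ov.size:
            p = ov.mean()
            if ci_method == "wilson":
                z = 1.96
                den = 1 + z**2 / ov.size
                centre = (p + z**2 / (2 * ov.size)) / den
                half = z * np.sqrt(p * (1 - p) / ov.size + z**2 / (4 * ov.size**2)) / den
                lo, hi = centre - half, centre + half
            else:
                half = 1.96 * np.sqrt(p * (1 - p) / ov.size)
                lo, hi = p - half, p + half
        else:
            p = lo = hi = np.nan
        v = vel_mat[:, j]
        v = v[np.isfinite(v)]
        if v.size:
            vm = v.mean()
            sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
            vlo, vhi = vm - 1.96 * sem, vm + 1.96 * sem
        else:
            vm = vlo = vhi = np.nan
        rows.append((rf * frame_interval, p, lo, hi, ov.size, vm, vlo, vhi, v.size))
    pooled = pd.DataFrame(
        rows,
        columns=[
            "rel_time", "prevalence", "prev_ci_low", "prev_ci_high", "n_overlap",
            "velocity", "vel_ci_low", "vel_ci_high", "n_velocity",
        ],
    )
    for col in ("prevalence", "prev_ci_low", "prev_ci_high",
                "velocity", "vel_ci_low", "vel_ci_high"):
        pooled[col] = moving_average(pooled[col].to_numpy(), smooth_window)
    return EventAlignedSet(
        rel_time=rel_frames * frame_interval,
        velocity=vel_mat,
        overlap=ovl_mat,
        fluor=fluor_mats,
        events=list(events),
        pooled=pooled,
    )


# ---------------------------------------------------------------------------
# SMLM localisation filtering and rendering
# ---------------------------------------------------------------------------

SMLM_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "photons": (50.0, 5000.0),       # inclusive range
    "precision": (0.5, 50.0),        # nm, inclusive range
    "llr": (-np.inf, 150.0),         # strict upper bound on goodness of fit
    "sigma": (50.0, 150.0),          # nm, inclusive range
}


def smlm_filter(
    locs: pd.DataFrame, bounds: Mapping[str, tuple[float, float]] | None = None
) -> pd.DataFrame:
    """Filter a localisation table on photons, precision, fit quality and
    PSF width. Range bounds are inclusive; the log-likelihood-ratio bound is
    strict (< upper). Idempotent by construction."""
    b = dict(SMLM_DEFAULT_BOUNDS, **(bounds or {}))
    keep = np.ones(len(locs), dtype=bool)
    for field in ("photons", "precision", "sigma"):
        lo, hi = b[field]
        keep &= (locs[field] >= lo) & (locs[field] <= hi)
    keep &= locs["llr"] < b["llr"][1]
    return locs.loc[keep].reset_index(drop=True)


def smlm_render(
    locs: pd.DataFrame, pixel_size: float = 16.0, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Render localisations as a 2-D histogram blurred by the mean precision.

    ``pixel_size`` is in nm. The Gaussian blur sd equals the mean precision
    of the provided (already filtered) localisations, in pixels. Away from
    the image border the total intensity equals the localisation count.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if len(locs) == 0:
        return np.zeros(shape or (1, 1))
    x = locs["x"].to_numpy(dtype=float) / pixel_size
    y = locs["y"].to_numpy(dtype=float) / pixel_size
    if shape is None:
        shape = (int(np.floor(y.max())) + 1, int(np.floor(x.max())) + 1)
    img = np.zeros(shape)
    rows = np.floor(y).astype(int)
    cols = np.floor(x).astype(int)
    ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    np.add.at(img, (rows[ok], cols[ok]), 1.0)
    sigma_px = float(locs["precision"].mean()) / pixel_size
    return ndimage.gaussian_filter(img, sigma=sigma_px, mode="constant")
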