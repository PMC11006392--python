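"""Cross-correlation profiles and responder subclustering.

The cross-correlation function (CCF) between tip fluorescence F and tip
movement M is estimated per signed time offset as a pairwise-complete Pearson
correlation: at offset tau = k * frame_interval the pairs are
(F_{t+k}, M_t), so a *negative* offset means fluorescence precedes movement.
Recomputing means and standard deviations per lag keeps every value in
[-1, 1] and tolerates missing frames. Filopodia are then clustered on their
CCF values inside a short window around zero offset, and the cluster with
the higher mean CCF at offset 0 is called the "responding" subpopulation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "CCFProfile",
    "SubclusterAssignment",
    "ccf_profile",
    "ccf_profiles",
    "cluster_filopodia",
    "subcluster_mean_ccf",
    "dividing_point_sweep",
    "pairwise_complete_pearson",
]

RESPONDING = "responding"
OTHER = "other"


class ShortSeriesError(ValueError):
    """Track has fewer jointly valid frames than the minimum required."""


def pairwise_complete_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pearson correlation over pairs where both values are present.

    Returns (r, n_pairs); r is NaN when fewer than 2 pairs remain or either
    sub-series has zero variance.
    """
    valid = np.isfinite(x) & np.isfinite(y)
    n = int(valid.sum())
    if n < 2:
        return np.nan, n
    xv, yv = x[valid], y[valid]
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan, n
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0)), n


@dataclasses.dataclass
class CCFProfile:
    """Per-filopodium CCF value at each signed offset.

    offsets are in seconds on the grid k * frame_interval; ccf entries with
    fewer than ``min_pairs`` supporting pairs are NaN; n_pairs records the
    number of valid pairs per offset.
    """

    track_id: str
    offsets: np.ndarray
    ccf: np.ndarray
    n_pairs: np.ndarray

    def at(self, offset: float) -> float:
        idx = int(np.argmin(np.abs(self.offsets - offset)))
        if not np.isclose(self.offsets[idx], offset):
            raise KeyError(f"offset {offset} not on the profile grid")
        return float(self.ccf[idx])


def ccf_profile(
    F: np.ndarray,
    M: np.ndarray,
    frame_interval: float,
    max_offset: float = 40.0,
    min_pairs: int = 10,
    min_frames: int = 50,
    track_id: str = "",
) -> CCFProfile:
    """Cross-correlation profile of fluorescence F against movement M.

    Raises :class:`ShortSeriesError` when fewer than ``min_frames`` frames
    have both F and M present.
    """
    F = np.asarray(F, dtype=float)
    M = np.asarray(M, dtype=float)
    if F.shape != M.shape:
        raise ValueError("F and M must be aligned to the same frame axis")
    k_max = max_offset / frame_interval
    if not np.isclose(k_max, round(k_max)):
        raise ValueError("max_offset must be a multiple of frame_interval")
    k_max = int(round(k_max))
    n_valid = int((np.isfinite(F) & np.isfinite(M)).sum())
    if n_valid < min_frames:
        raise ShortSeriesError(
            f"track {track_id!r}: {n_valid} jointly valid frames < minimum {min_frames}"
        )
    n = len(F)
    ks = np.arange(-k_max, k_max + 1)
    ccf = np.full(ks.shape, np.nan)
    n_pairs = np.zeros(ks.shape, dtype=int)
    for i, k in enumerate(ks):
        if abs(k) >= n:
            continue
        if k >= 0:
            x, y = F[k:], M[: n - k]
        else:
            x, y = F[: n + k], M[-k:]
        r, np_ = pairwise_complete_pearson(x, y)
        n_pairs[i] = np_
        if np_ >= min_pairs:
            ccf[i] = r
    return CCFProfile(
        track_id=track_id,
        offsets=ks * frame_interval,
        ccf=ccf,
        n_pairs=n_pairs,
    )


def ccf_profiles(
    processed: Sequence,
    max_offset: float = 40.0,
    min_pairs: int = 10,
    min_frames: int = 50,
) -> tuple[list[CCFProfile], dict[str, str]]:
    """Profiles for a collection of ProcessedSeries; returns (profiles,
    excluded) where ``excluded`` maps track_id to the exclusion reason."""
    profiles, excluded = [], {}
    for ps in processed:
        try:
            profiles.append(
                ccf_profile(
                    ps.F, ps.M, ps.frame_interval,
                    max_offset=max_offset, min_pairs=min_pairs,
                    min_frames=min_frames, track_id=ps.track_id,
                )
            )
        except ShortSeriesError as exc:
            excluded[ps.track_id] = str(exc)
    return profiles, excluded


@dataclasses.dataclass
class SubclusterAssignment:
    """Cluster labels plus the dendrogram they were cut from."""

    labels: dict[str, str]                  # track_id -> responding | other
    raw_labels: dict[str, int]              # track_id -> integer cluster id
    linkage_matrix: np.ndarray
    window: float
    excluded: dict[str, str]

    def members(self, label: str) -> list[str]:
        return [tid for tid, lab in self.labels.items() if lab == label]


def _window_matrix(
    profiles: Sequence[CCFProfile], window: float
) -> tuple[np.ndarray, list[CCFProfile], dict[str, str], np.ndarray]:
    """Stack CCF values within |offset| <= window; drop incomplete profiles."""
    usable, rows, excluded = [], [], {}
    sel = None
    for p in profiles:
        sel = np.abs(p.offsets) <= window + 1e-9
        vec = p.ccf[sel]
        if np.all(np.isfinite(vec)):
            usable.append(p)
            rows.append(vec)
        else:
            excluded[p.track_id] = "missing CCF values inside clustering window"
    if not rows:
        return np.empty((0, 0)), usable, excluded, np.empty(0)
    offsets = usable[0].offsets[np.abs(usable[0].offsets) <= window + 1e-9]
    return np.vstack(rows), usable, excluded, offsets


def _label_by_ccf0(usable: Sequence[CCFProfile], raw: np.ndarray) -> dict[str, str]:
    """Name the cluster with the highest mean CCF(0) 'responding'; ties go to
    the smaller cluster."""
    stats = []
    for cid in np.unique(raw):
        members = [usable[i] for i in np.where(raw == cid)[0]]
        mean0 = float(np.nanmean([p.ccf[np.argmin(np.abs(p.offsets))] for p in members]))
        stats.append((cid, mean0, len(members)))
    # highest mean ccf(0) wins; ties broken toward the smaller cluster
    stats.sort(key=lambda s: (-s[1], s[2]))
    top = stats[0][0]
    return {
        p.track_id: (RESPONDING if raw[i] == top else OTHER) for i, p in enumerate(usable)
    }


def cluster_filopodia(
    profiles: Sequence[CCFProfile],
    window: float = 6.0,
    k: int = 2,
    standardize: bool = False,
) -> SubclusterAssignment:
    """Agglomerative clustering of CCF vectors inside +/- window seconds.

    Euclidean distance with complete linkage; the tree is cut to ``k``
    clusters and the cluster whose members have the greatest mean CCF at
    offset 0 is labelled responding. Deterministic, and invariant to input
    permutation up to label identity.
    """
    X, usable, excluded, offsets = _window_matrix(profiles, window)
    if len(usable) < k:
        raise ValueError(f"need at least k={k} usable profiles, got {len(usable)}")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = linkage(X, method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    if np.unique(raw).size < k:
        raise ValueError(
            "degenerate clustering: fewer than k distinct clusters "
            "(identical or tied profiles)"
        )
    labels = _label_by_ccf0(usable, raw)
    return SubclusterAssignment(
        labels=labels,
        raw_labels={p.track_id: int(raw[i]) for i, p in enumerate(usable)},
        linkage_matrix=Z,
        window=window,
        excluded=excluded,
    )


def subcluster_mean_ccf(
    profiles: Sequence[CCFProfile], assignment: SubclusterAssignment
) -> pd.DataFrame:
    """Per-cluster mean CCF curve with a 95% confidence band.

    Returns a tidy frame with columns (cluster, offset, mean, ci_low,
    ci_high, n); the responding cluster's peak offset is the offset of its
    maximum mean.
    """
    by_id = {p.track_id: p for p in profiles}
    rows = []
    for label in (RESPONDING, OTHER):
        members = [by_id[tid] for tid in assignment.members(label) if tid in by_id]
        if not members:
            raise ValueError(f"cluster {label!r} is empty")
        offsets = members[0].offsets
        mat = np.vstack([p.ccf for p in members])
        for j, off in enumerate(offsets):
            col = mat[:, j]
            col = col[np.isfinite(col)]
            if col.size == 0:
                rows.append((label, off, np.nan, np.nan, np.nan, 0))
                continue
            m = col.mean()
            sem = col.std(ddof=1) / np.sqrt(col.size) if col.size > 1 else 0.0
            rows.append((label, off, m, m - 1.96 * sem, m + 1.96 * sem, col.size))
    return pd.DataFrame(rows, columns=["cluster", "offset", "mean", "ci_low", "ci_high", "n"])


def peak_offset(curve: pd.DataFrame, cluster: str = RESPONDING) -> float:
    """Offset (s) at which the given cluster's mean CCF is maximal."""
    sub = curve[curve["cluster"] == cluster]
    return float(sub.loc[sub["mean"].idxmax(), "offset"])


def dividing_point_sweep(
    profiles: Sequence[CCFProfile],
    ks: Sequence[int] = (2, 3, 4, 5),
    window: float = 6.0,
) -> pd.DataFrame:
    """Sensitivity of the responding subcluster to the dendrogram cut.

    For each requested number of clusters, reports the responding-cluster
    size and its mean CCF at offset 0.
    """
    rows = []
    for k in ks:
        assignment = cluster_filopodia(profiles, window=window, k=k)
        members = assignment.members(RESPONDING)
        by_id = {p.track_id: p for p in profiles}
        vals = [by_id[tid].at(0.0) for tid in members]
        rows.append((k, len(members), float(np.nanmean(vals)) if vals else np.nan))
    return pd.DataFrame(rows, columns=["k", "responding_size", "mean_ccf0"])
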