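"""Per-filopodium dynamic parameters and group-comparison statistics.

Persistence of tip movement is the correlation time of the movement series:
the lag at which its autocorrelation function first drops below 1/e,
linearly interpolated between bracketing lags. For an AR(1) process with
coefficient phi this converges to -dt/ln(phi), which the tests use as a
closed-form check.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ccf_cluster import pairwise_complete_pearson
from .io_tables import FilopodiumTrack
from .preprocess import ProcessedSeries

__all__ = [
    "DynamicParams",
    "acf",
    "persistence_time",
    "dynamic_params",
    "formation_rate",
    "compare_groups",
    "export_kymograph",
]


def acf(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelation per lag as pairwise-complete Pearson correlations.

    acf[0] is exactly 1; acf[k] correlates (x_t, x_{t+k}) over valid pairs.
    Raises on zero overall variance.
    """
    x = np.asarray(series, dtype=float)
    valid = x[np.isfinite(x)]
    if valid.size < 2 or valid.std() == 0:
        raise ValueError("zero variance or too few values for ACF")
    out = np.full(max_lag + 1, np.nan)
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        if k >= len(x):
            break
        r, n = pairwise_complete_pearson(x[:-k], x[k:])
        if n >= 2:
            out[k] = r
    return out


@dataclasses.dataclass
class PersistenceResult:
    time_s: float
    capped: bool


def persistence_time(
    M: np.ndarray,
    frame_interval: float,
    max_lag: int = 20,
    threshold: float = float(np.exp(-1)),
) -> PersistenceResult:
    """Correlation time of the movement series in seconds.

    The ACF's first crossing below ``threshold`` (default 1/e) is found and
    linearly interpolated between the bracketing lags. If the ACF never
    crosses within ``max_lag`` lags the value is capped there and flagged.
    """
    a = acf(M, max_lag)
    finite = np.isfinite(a)
    for k in range(1, max_lag + 1):
        if not finite[k]:
            continue
        if a[k] < threshold:
            # previous finite lag brackets the crossing
            prev = max(j for j in range(k) if finite[j])
            frac = (a[prev] - threshold) / (a[prev] - a[k])
            lag_cross = prev + frac * (k - prev)
            return PersistenceResult(time_s=float(lag_cross * frame_interval), capped=False)
    return PersistenceResult(time_s=float(max_lag * frame_interval), capped=True)


@dataclasses.dataclass
class DynamicParams:
    """Summary dynamics of one filopodium."""

    track_id: str
    tip_persistence: float          # seconds (NaN if not computable)
    persistence_capped: bool
    tip_extension_rate: float       # um/s, mean over frames with positive movement
    max_length: float               # um
    base_speed: float               # um/s, mean absolute base movement
    base_stall_fraction: float      # fraction of frames with |base movement| < threshold
    reasons: dict = dataclasses.field(default_factory=dict)


def dynamic_params(
    track: FilopodiumTrack,
    processed: ProcessedSeries,
    stall_threshold: float = 0.05,
    min_frames: int = 10,
) -> DynamicParams:
    """Compute all dynamic parameters for one track.

    ``stall_threshold`` is in um/frame; a base frame counts as stalled when
    its absolute movement is below it.
    """
    reasons: dict[str, str] = {}
    dt = track.frame_interval
    M = processed.M
    valid_M = M[np.isfinite(M)]
    if valid_M.size >= min_frames and valid_M.std() > 0:
        pres = persistence_time(M, dt)
        persistence, capped = pres.time_s, pres.capped
    else:
        persistence, capped = np.nan, False
        reasons["tip_persistence"] = "too few valid movement frames"
    pos = valid_M[valid_M > 0]
    ext_rate = float(pos.mean() / dt) if pos.size else np.nan
    if not pos.size:
        reasons["tip_extension_rate"] = "no frames with positive tip movement"
    length = track.column("length")
    length = length[np.isfinite(length)]
    max_length = float(length.max()) if length.size else np.nan
    base_mv = track.column("base_movement")
    base_mv = base_mv[np.isfinite(base_mv)]
    base_speed = float(np.abs(base_mv).mean() / dt) if base_mv.size else np.nan
    stall = float((np.abs(base_mv) < stall_threshold).mean()) if base_mv.size else np.nan
    return DynamicParams(
        track_id=track.track_id,
        tip_persistence=persistence,
        persistence_capped=capped,
        tip_extension_rate=ext_rate,
        max_length=max_length,
        base_speed=base_speed,
        base_stall_fraction=stall,
        reasons=reasons,
    )


def formation_rate(
    events: Sequence[Mapping],
    duration_min: float,
    max_first_frame_length: float = 2.0,
    pre_rate: float | None = None,
) -> float:
    """New-filopodium formation rate in events/min.

    Events whose filopodium was already longer than ``max_first_frame_length``
    (um) in its first frame are excluded (they pre-existed the movie). When
    ``pre_rate`` is given the result is normalised to that pre-treatment rate.
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    n = sum(
        1 for ev in events
        if ev.get("first_frame_length", 0.0) <= max_first_frame_length
    )
    rate = n / duration_min
    if pre_rate is not None:
        if pre_rate <= 0:
            raise ValueError("pre-treatment rate must be positive for normalisation")
        rate /= pre_rate
    return rate


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def _nemenyi_friedman(samples: list[np.ndarray], names: list[str]) -> list[tuple]:
    """Nemenyi post hoc on within-subject ranks (studentised-range approx)."""
    data = np.column_stack(samples)          # subjects x conditions
    n, k = data.shape
    ranks = stats.rankdata(data, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for i, j in combinations(range(k), 2):
        q = abs(mean_ranks[i] - mean_ranks[j]) / se
        p = float(stats.studentized_range.sf(q * np.sqrt(2.0), k, np.inf))
        rows.append((f"{names[i]} vs {names[j]}", q, p))
    return rows


def compare_groups(samples: Mapping[str, Sequence[float]], test: str) -> pd.DataFrame:
    """Group-comparison statistics used throughout the figures.

    test is one of:
      - ``mann_whitney_holm``: all pairwise two-sided Mann-Whitney U tests
        with Holm adjustment across the family;
      - ``kruskal_wallis``: one omnibus test;
      - ``friedman_nemenyi``: Friedman omnibus on paired conditions plus
        Nemenyi rank post hoc per pair;
      - ``jarque_bera_then_t``: two-tailed unpaired t-test when both samples
        pass Jarque-Bera normality at 0.05, else Kruskal-Wallis.

    Returns one row per comparison with (comparison, statistic, p_raw, p_adj).
    """
    names = list(samples)
    arrays = [np.asarray(samples[n], dtype=float) for n in names]
    rows: list[tuple] = []
    if test == "mann_whitney_holm":
        pvals, labels, ustats = [], [], []
        for i, j in combinations(range(len(names)), 2):
            u, p = stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
            labels.append(f"{names[i]} vs {names[j]}")
            ustats.append(u)
            pvals.append(p)
        adj = _holm(np.asarray(pvals))
        rows = list(zip(labels, ustats, pvals, adj))
    elif test == "kruskal_wallis":
        h, p = stats.kruskal(*arrays)
        rows = [(" vs ".join(names), h, p, p)]
    elif test == "friedman_nemenyi":
        chi2, p = stats.friedmanchisquare(*arrays)
        rows = [("friedman: " + " vs ".join(names), chi2, p, p)]
        for label, q, pp in _nemenyi_friedman(arrays, names):
            rows.append((label, q, pp, pp))
    elif test == "jarque_bera_then_t":
        if len(arrays) != 2:
            raise ValueError("jarque_bera_then_t requires exactly two samples")
        normal = all(stats.jarque_bera(a).pvalue >= 0.05 for a in arrays)
        if normal:
            t, p = stats.ttest_ind(arrays[0], arrays[1])
            rows = [(f"{names[0]} vs {names[1]} (t-test)", t, p, p)]
        else:
            h, p = stats.kruskal(*arrays)
            rows = [(f"{names[0]} vs {names[1]} (kruskal)", h, p, p)]
    else:
        raise ValueError(f"unknown test {test!r}")
    return pd.DataFrame(rows, columns=["comparison", "statistic", "p_raw", "p_adj"])


def export_kymograph(
    profiles: Sequence[np.ndarray],
    camera_offset: float,
    body_median: float,
) -> np.ndarray:
    """Straightened base-to-tip fluorescence profiles as a frames x positions
    matrix, offset-subtracted and normalised by the growth-cone body median.

    Rows shorter than the longest profile are NaN-padded on the tip side.
    Negative values (offset above raw signal) are kept, not clipped.
    """
    if body_median == 0:
        raise ValueError("body_median must be non-zero")
    width = max((len(p) for p in profiles), default=0)
    out = np.full((len(profiles), width), np.nan)
    for i, p in enumerate(profiles):
        p = np.asarray(p, dtype=float)
        out[i, : len(p)] = (p - camera_offset) / body_median
    return out
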