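"""Significance machinery for fluorescence-movement coupling.

Three independent routes are implemented:

* a per-filopodium Markov-chain null — tip movement is discretised into
  quantile states, a first-order transition matrix is fitted, and surrogate
  movement series redrawn from the chain give the null distribution of the
  CCF statistic;
* a dataset-level reshuffling test — tip movement is permuted within each
  track and the full CCF -> clustering pipeline re-run per shuffle;
* Granger causality — nested least-squares autoregressions (reduced: past of
  movement only; full: plus past of fluorescence) compared with an F test,
  with an augmented Dickey-Fuller stationarity gate, BIC lag selection over
  lags 1-5, and Benjamini-Hochberg FDR control at 0.1 across filopodia.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tsa.stattools import adfuller

from .ccf_cluster import (
    RESPONDING,
    CCFProfile,
    ccf_profile,
    ccf_profiles,
    cluster_filopodia,
)

__all__ = [
    "MarkovChain",
    "MarkovNullResult",
    "ReshuffleResult",
    "GCResult",
    "fit_markov_chain",
    "markov_null_pvalue",
    "reshuffle_test",
    "adf_stationary",
    "select_lag_bic",
    "granger_test",
    "bh_fdr",
    "granger_analysis",
]


# ---------------------------------------------------------------------------
# Markov-chain null
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MarkovChain:
    """First-order chain over quantile-binned movement states."""

    transition: np.ndarray          # row-stochastic (n_states x n_states)
    state_values: list[np.ndarray]  # observed values per state
    bin_edges: np.ndarray

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclasses.dataclass
class MarkovNullResult:
    track_id: str
    observed: float
    n_sims: int
    n_exceed: int
    p_value: float
    seed: int

    @property
    def significant(self) -> bool:
        """True when simulated CCFs matched or beat the observed value in
        fewer than 5% of simulations."""
        return self.p_value < 0.05


def fit_markov_chain(M: np.ndarray, n_states: int = 5, min_frames: int = 20) -> MarkovChain:
    """Fit a first-order Markov chain to a movement series.

    Values are discretised into ``n_states`` quantile bins and transition
    counts get add-one smoothing so every row is a proper distribution.
    """
    x = np.asarray(M, dtype=float)
    valid = np.isfinite(x)
    vals = x[valid]
    if vals.size < min_frames:
        raise ValueError(f"need at least {min_frames} valid frames, got {vals.size}")
    edges = np.quantile(vals, np.linspace(0, 1, n_states + 1)[1:-1])
    states_all = np.full(len(x), -1, dtype=int)
    states_all[valid] = np.digitize(vals, edges)
    occupied = np.unique(states_all[valid])
    if occupied.size < 2:
        raise ValueError("fewer than 2 occupied movement states (constant series?)")
    counts = np.ones((n_states, n_states))  # add-one smoothing
    sv = states_all[valid]
    for a, b in zip(sv[:-1], sv[1:]):
        counts[a, b] += 1
    transition = counts / counts.sum(axis=1, keepdims=True)
    state_values = [vals[sv == s] if (sv == s).any() else np.array([0.0]) for s in range(n_states)]
    return MarkovChain(transition=transition, state_values=state_values, bin_edges=edges)


def _simulate_chain_values(
    chain: MarkovChain, n_sims: int, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_sims, n_frames) surrogate movement values drawn from the chain,
    started from its stationary distribution."""
    T = chain.transition
    cum = np.cumsum(T, axis=1)
    pi = np.cumsum(chain.stationary_distribution())
    states = np.empty((n_sims, n_frames), dtype=np.intp)
    states[:, 0] = np.searchsorted(pi, rng.random(n_sims), side="right")
    for t in range(1, n_frames):
        u = rng.random(n_sims)
        rows = cum[states[:, t - 1]]
        states[:, t] = (u[:, None] > rows).sum(axis=1)
    np.clip(states, 0, chain.n_states - 1, out=states)
    values = np.empty((n_sims, n_frames))
    for s in range(chain.n_states):
        pos = states == s
        k = int(pos.sum())
        if k:
            pool = chain.state_values[s]
            values[pos] = pool[rng.integers(0, len(pool), size=k)]
    return values


def _window_lags(frame_interval: float, window: float) -> np.ndarray:
    k_max = int(round(window / frame_interval))
    return np.arange(-k_max, k_max + 1)


def _max_ccf_matrix(
    F: np.ndarray, Msim: np.ndarray, mask_M: np.ndarray, lags: np.ndarray,
    min_pairs: int, statistic: str,
) -> np.ndarray:
    """Per-simulation CCF statistic, vectorised across simulations.

    F is the fixed fluorescence series (with its own mask); Msim rows are
    surrogate movement series sharing the observed mask positions.
    """
    n = len(F)
    n_sims = Msim.shape[0]
    out = np.full((n_sims, len(lags)), np.nan)
    maskF = np.isfinite(F)
    for j, k in enumerate(lags):
        if abs(k) >= n:
            continue
        if k >= 0:
            ix, iy = np.arange(k, n), np.arange(0, n - k)
        else:
            ix, iy = np.arange(0, n + k), np.arange(-k, n)
        ok = maskF[ix] & mask_M[iy]
        if ok.sum() < max(min_pairs, 2):
            continue
        x = F[ix[ok]]
        Y = Msim[:, iy[ok]]
        xc = x - x.mean()
        Yc = Y - Y.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc @ xc) * (Yc * Yc).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, j] = np.clip((Yc @ xc) / denom, -1.0, 1.0)
    if statistic == "max":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmax(out, axis=1)
    # ccf at offset 0
    return out[:, len(lags) // 2]


def markov_null_pvalue(
    F: np.ndarray,
    M: np.ndarray,
    frame_interval: float,
    n_sims: int = 10_000,
    window: float = 6.0,
    n_states: int = 5,
    seed: int = 0,
    min_pairs: int = 10,
    min_frames: int = 50,
    statistic: str = "max",
    track_id: str = "",
) -> MarkovNullResult:
    """Markov-chain simulation null for one filopodium.

    The observed statistic is the maximum CCF inside the +/- ``window``
    clustering offsets (or CCF(0) with ``statistic='ccf0'``). Each surrogate
    redraws the movement series from the fitted chain at the observed mask
    positions and recomputes the statistic against the fixed fluorescence
    series. p = n_exceed / n_sims, counting surrogates >= observed.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    F = np.asarray(F, dtype=float)
    M = np.asarray(M, dtype=float)
    profile = ccf_profile(
        F, M, frame_interval, max_offset=window, min_pairs=min_pairs,
        min_frames=min_frames, track_id=track_id,
    )
    if statistic == "max":
        observed = float(np.nanmax(profile.ccf))
    elif statistic == "ccf0":
        observed = profile.at(0.0)
    else:
        raise ValueError("statistic must be 'max' or 'ccf0'")
    if not np.isfinite(observed):
        raise ValueError("observed CCF statistic is undefined (all offsets missing)")
    chain = fit_markov_chain(M, n_states=n_states)
    rng = np.random.default_rng(seed)
    Msim = _simulate_chain_values(chain, n_sims, len(M), rng)
    lags = _window_lags(frame_interval, window)
    sims = _max_ccf_matrix(F, Msim, np.isfinite(M), lags, min_pairs, statistic)
    n_exceed = int(np.nansum(sims >= observed))
    return MarkovNullResult(
        track_id=track_id,
        observed=observed,
        n_sims=n_sims,
        n_exceed=n_exceed,
        p_value=n_exceed / n_sims,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Reshuffling test
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReshuffleResult:
    observed: float
    n_shuffles: int
    n_exceed: int
    p_value: float
    seed: int


def _responding_mean_ccf0(
    processed: Sequence, window: float, min_pairs: int, min_frames: int, k: int
) -> float:
    profiles, _ = ccf_profiles(
        processed, max_offset=window, min_pairs=min_pairs, min_frames=min_frames
    )
    assignment = cluster_filopodia(profiles, window=window, k=k)
    by_id = {p.track_id: p for p in profiles}
    vals = [by_id[tid].at(0.0) for tid in assignment.members(RESPONDING)]
    return float(np.nanmean(vals))


def reshuffle_test(
    processed: Sequence,
    n_shuffles: int = 1000,
    seed: int = 0,
    window: float = 6.0,
    min_pairs: int = 10,
    min_frames: int = 50,
    k: int = 2,
) -> ReshuffleResult:
    """Dataset-level permutation test of the responding-subcluster CCF.

    Per shuffle, every track's movement values are permuted within the track
    (mask positions fixed), the CCF -> clustering pipeline is re-run, and the
    responding subcluster's mean CCF(0) recorded; p is the fraction of
    shuffles at or above the observed value.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    observed = _responding_mean_ccf0(processed, window, min_pairs, min_frames, k)
    rng = np.random.default_rng(seed)
    n_exceed = 0
    shuffled = [dataclasses.replace(ps) for ps in processed]
    for _ in range(n_shuffles):
        for ps, orig in zip(shuffled, processed):
            m = orig.M.copy()
            valid = np.isfinite(m)
            m[valid] = rng.permutation(m[valid])
            ps.M = m
        stat = _responding_mean_ccf0(shuffled, window, min_pairs, min_frames, k)
        if stat >= observed:
            n_exceed += 1
    return ReshuffleResult(
        observed=observed,
        n_shuffles=n_shuffles,
        n_exceed=n_exceed,
        p_value=n_exceed / n_shuffles,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GCResult:
    """Granger-causality outcome for one filopodium (shared lag p = r = lag)."""

    track_id: str
    lag: int
    f_stat: float
    p_value: float
    q_value: float = np.nan
    causal: bool = False
    stationary_A: bool = True
    stationary_B: bool = True
    n_obs: int = 0


def adf_stationary(series: np.ndarray, alpha: float = 0.05) -> bool:
    """Augmented Dickey-Fuller gate: True iff the unit-root null is rejected."""
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("series too short for the ADF regression")
    if np.ptp(x) == 0:
        raise ValueError("constant series: ADF regression is degenerate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pvalue = adfuller(x, autolag="AIC")[1]
    return bool(pvalue < alpha)


def _lag_embed(A: np.ndarray, B: np.ndarray, max_lag: int) -> tuple[np.ndarray, ...]:
    """Design rows t with B_t and all of B_{t-1..t-L}, A_{t-1..t-L} present."""
    n = len(B)
    t = np.arange(max_lag, n)
    cols_B = np.column_stack([B[t - i] for i in range(1, max_lag + 1)])
    cols_A = np.column_stack([A[t - i] for i in range(1, max_lag + 1)])
    y = B[t]
    ok = np.isfinite(y) & np.all(np.isfinite(cols_B), axis=1) & np.all(np.isfinite(cols_A), axis=1)
    return y[ok], cols_B[ok], cols_A[ok]


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    resid = y - X @ coef
    return float(resid @ resid)


def select_lag_bic(A: np.ndarray, B: np.ndarray, max_lag: int = 5) -> int:
    """Shared lag order minimising the BIC of the full model, lags 1..max_lag.

    All candidate models are fitted on the common sample defined by the
    ``max_lag`` embedding so their BICs are comparable; ties break toward the
    smaller lag. If the sample cannot support ``max_lag``, it is reduced with
    a warning.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    L = max_lag
    while L >= 1:
        y, lags_B, lags_A = _lag_embed(A, B, L)
        if y.size >= 2 * L + 2:
            break
        L -= 1
    else:
        raise ValueError("insufficient data for any lag order")
    if L < max_lag:
        warnings.warn(f"max_lag reduced from {max_lag} to {L} (short series)", stacklevel=2)
    n = y.size
    best_lag, best_bic = None, np.inf
    for lag in range(1, L + 1):
        X = np.column_stack([np.ones(n), lags_B[:, :lag], lags_A[:, :lag]])
        rss = _ols_rss(X, y)
        k = 2 * lag + 1
        bic = n * np.log(max(rss, 1e-300) / n) + k * np.log(n)
        if bic < best_bic - 1e-12:
            best_bic, best_lag = bic, lag
    return int(best_lag)


def granger_test(
    A: np.ndarray, B: np.ndarray, lag: int, track_id: str = ""
) -> GCResult:
    """Nested-model F test: does the past of A improve prediction of B?

    Reduced model: B_t = c + sum a_i B_{t-i}; full model adds sum b_j A_{t-j}
    (i, j = 1..lag). Both are fitted by least squares on the same lag-embedded
    sample; F = ((RSS_red - RSS_full)/lag) / (RSS_full/(n - 2 lag - 1)) is
    referred to F(lag, n - 2 lag - 1).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    y, lags_B, lags_A = _lag_embed(A, B, lag)
    n = y.size
    dof = n - 2 * lag - 1
    if dof < 1 or n < 2 * lag + 2:
        raise ValueError(f"only {n} usable observations for lag {lag}")
    ones = np.ones(n)
    rss_red = _ols_rss(np.column_stack([ones, lags_B]), y)
    rss_full = _ols_rss(np.column_stack([ones, lags_B, lags_A]), y)
    f_stat = max(0.0, (rss_red - rss_full) / lag) / (rss_full / dof)
    p_value = float(stats.f.sf(f_stat, lag, dof))
    return GCResult(
        track_id=track_id, lag=lag, f_stat=float(f_stat), p_value=p_value, n_obs=n
    )


def bh_fdr(p_values: Sequence[float], q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: returns (flags, q_values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, q_values, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, q_values


def granger_analysis(
    processed: Sequence,
    max_lag: int = 5,
    fdr: float = 0.1,
    adf_alpha: float = 0.05,
) -> list[GCResult]:
    """Per-filopodium Granger causality of fluorescence for movement.

    Each track's F and M series must both pass the ADF stationarity gate;
    non-stationary tracks are reported with flags set and excluded from the
    F test. The shared lag is chosen by BIC over 1..max_lag and the raw
    p-values are BH-corrected at the given FDR across the tested tracks.
    """
    results: list[GCResult] = []
    tested_idx: list[int] = []
    for ps in processed:
        try:
            stat_A = adf_stationary(ps.F, adf_alpha)
            stat_B = adf_stationary(ps.M, adf_alpha)
        except ValueError:
            stat_A = stat_B = False
        if not (stat_A and stat_B):
            results.append(
                GCResult(
                    track_id=ps.track_id, lag=0, f_stat=np.nan, p_value=np.nan,
                    stationary_A=stat_A, stationary_B=stat_B,
                )
            )
            continue
        lag = select_lag_bic(ps.F, ps.M, max_lag=max_lag)
        res = granger_test(ps.F, ps.M, lag, track_id=ps.track_id)
        tested_idx.append(len(results))
        results.append(res)
    if tested_idx:
        flags, qvals = bh_fdr([results[i].p_value for i in tested_idx], q=fdr)
        for j, i in enumerate(tested_idx):
            results[i].q_value = float(qvals[j])
            results[i].causal = bool(flags[j])
    return results
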