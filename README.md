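# filocausal

Quantitative analysis of filopodial tip dynamics: does the recruitment of a
tip protein *drive* protrusion, or merely accompany it?

Filopodia are thin actin-rich protrusions whose tips extend and retract on a
timescale of seconds. Given per-filopodium, per-frame measurement tables from
tip-tracking software (tip fluorescence, tip/base movement, length,
waviness), `filocausal` asks whether fluctuations in tip fluorescence of a
candidate regulator *precede and predict* tip movement, using two independent
statistical routes plus rule-based image quantification:

- **Cross-correlation profiling.** For each filopodium the cross-correlation
  function (CCF) between normalised tip fluorescence `F` and smoothed tip
  movement `M` is estimated at signed offsets `tau = k·dt` as a
  pairwise-complete Pearson correlation, `ccf(tau) = corr(F_{t+k}, M_t)`;
  negative offsets mean fluorescence leads movement. Filopodia are
  hierarchically clustered (complete linkage, Euclidean) on their CCF values
  within ±6 s, and the cluster with the higher mean CCF at zero offset forms
  the "responding" subpopulation.
- **Null models.** Per-filopodium significance from a Markov-chain surrogate
  null (movement discretised into quantile states, first-order chain refit,
  surrogate series redrawn); dataset-level significance from a reshuffling
  test that permutes each track's movement and re-runs the whole
  CCF-and-clustering pipeline per shuffle.
- **Granger causality.** Nested autoregressions
  `B_t = c + Σ a_i B_{t−i}` (reduced) vs `… + Σ b_j A_{t−j}` (full) with
  `F = ((RSS_red − RSS_full)/L) / (RSS_full/(n − 2L − 1))`, an augmented
  Dickey–Fuller stationarity gate, BIC lag selection over lags 1–5, and
  Benjamini–Hochberg FDR control at 0.1 across filopodia.
- **Dynamics metrics.** Movement persistence as the 1/e crossing time of the
  movement autocorrelation function (equal to `−dt/ln(phi)` for AR(1)
  movement), extension rates, stall fractions, formation rates, and the
  group-comparison tests used alongside them (Mann–Whitney with Holm,
  Friedman with Nemenyi post hoc, Jarque–Bera-gated t-test).
- **Puncta and overlap.** Two-channel punctum detection as 8-connected
  components within 0.06–1.00 µm² (14–237 pixels at 0.065 µm/pixel), overlap
  puncta from the conjunction of the channel masks, a 1-µm tip-circle rule,
  greedy nearest-neighbour punctum linking (≥5 frames, ≤0.65 µm steps),
  event-aligned overlap/velocity curves, and SMLM localisation filtering
  (photons 50–5000, precision 0.5–50 nm, LLR < 150, sigma 50–150 nm) with
  16-nm histogram rendering.

Because such pipelines are usually validated against undeposited imaging
data, `filocausal.synthetic_data` generates every input with known ground
truth: fluorescence is a latent AR(1) state, responder movement follows it
linearly at a fixed lag, images carry Gaussian puncta with a controlled
shared-centre fraction, and localisation tables straddle the filter bounds.

## Worked example

```python
from filocausal import *
from filocausal.ccf_cluster import RESPONDING, peak_offset, subcluster_mean_ccf

params = CouplingParams()              # dt = 2 s, 1-frame coupling lag
tracks, truth = simulate_dataset(params, 88, seed=1)
processed = [preprocess_track(t) for t in tracks]
profiles, excluded = ccf_profiles(processed, max_offset=40.0)
labels = cluster_filopodia(profiles, window=6.0)
curve = subcluster_mean_ccf(profiles, labels)
resp = curve[(curve.cluster == "responding") & (curve.offset == -2.0)]
print(f"responding filopodia: {len(labels.members(RESPONDING))}/{len(profiles)}")
print(f"peak mean CCF {resp['mean'].iloc[0]:.2f} at offset {peak_offset(curve):+.0f} s")
gc = granger_analysis(processed, max_lag=5, fdr=0.1)
print(f"Granger-causal tracks: {sum(r.causal for r in gc)}/{len(gc)}")
res = reshuffle_test(processed, n_shuffles=1000, seed=1)
print(f"reshuffle null: {res.n_exceed}/1000 shuffles >= observed (p={res.p_value:.3f})")
```

prints

```
responding filopodia: 35/88
peak mean CCF 0.74 at offset -2 s
Granger-causal tracks: 31/88
reshuffle null: 0/1000 shuffles >= observed (p=0.000)
```

The 88-track dataset was generated with a 35/88 responder fraction and a
one-frame (2 s) coupling lag; clustering recovers the responder subcluster,
its mean CCF peaks at the −2 s offset where fluorescence leads movement,
Granger causality flags a heavily overlapping subset, and no reshuffled
dataset reaches the observed subcluster correlation.

The same workflow is scriptable from the shell:

```sh
filocausal simulate-tracks tracks.csv --n-filopodia 88 --seed 1
filocausal filter-tracks tracks.csv kept.csv
filocausal preprocess kept.csv processed.csv
filocausal ccf processed.csv ccf.csv clusters.csv
filocausal granger processed.csv gc.csv --fdr 0.1 --max-lag 5
```

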