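# Methods

## Input model

The pipeline consumes per-filopodium, per-frame measurement tables of the
kind produced by semi-automated tip-tracking tools: columns for frame index
(1-based, frame 1 = time 0, time = (frame−1)·dt), tip/base/body/boundary
fluorescence (arbitrary units), length (µm), tip and base movement
(µm/frame) and waviness (dimensionless). Cells may be missing; missingness
is carried as NaN through every stage and all statistics are computed
pairwise- or listwise-complete, never by imputation. Track-quality filters
(first frame ≥ 1, ≥ 3 frames, maximum length ≥ 1.8 µm, length range
≥ 0.1 µm, mean waviness ≤ 0.38) mirror the tracking tool's published filter
settings and are applied before any statistics.

## Preprocessing

Tip fluorescence is background-corrected and normalised per frame as
`F = (tip − boundary)/(body − boundary)`; frames with a non-positive
denominator are masked with a warning. The phrase "normalisation to body
fluorescence" admits a second reading, `(tip − boundary)/body`, which is
available behind `divide_by_body_minus_boundary=False`; both are invariant
to a common detector gain. Movement is conditioned by masking (not
clipping) values beyond the symmetric 0.5% tail quantiles (1% for the
drug-treatment preset) and smoothing with a centred moving average of
window 3 (5 for the drug preset); base fluorescence is additionally
detrended by removing its least-squares line and adding back the mean, so
units stay interpretable. Quantiles interpolate linearly between order
statistics; window ends use the truncated window so series length is
preserved for alignment. Outliers are masked rather than clipped because
the correlation stage is explicitly pairwise-complete — gaps flow through.
Every operation is mask-monotone: a missing frame never becomes non-missing.

## Cross-correlation and subclustering

At offset `tau = k·dt` the CCF is the Pearson correlation of
`(F_{t+k}, M_t)` over frames where both are present, with means and
standard deviations recomputed per lag. This per-lag estimator (rather than
the FFT/convolution estimator normalised by whole-series variance)
guarantees values in [−1, 1] and handles gaps naturally. Negative offsets
mean fluorescence precedes movement; a generative one-frame lead at
dt = 2 s therefore peaks at −2 s. Offsets supported by fewer than
`min_pairs = 10` valid pairs are masked (unstated in the source workflow;
prevents spurious ±1 values at extreme lags), profiles span ±40 s by
default, and tracks with fewer than 50 jointly valid frames are excluded
with a recorded reason.

Filopodia with complete profiles inside ±6 s are stacked and clustered
agglomeratively (Euclidean metric, complete linkage — the common default of
the R workflow this mirrors; both recorded in the assignment object), the
tree is cut at k = 2, and the cluster with the greater mean CCF(0) is
labelled "responding" (ties go to the smaller cluster; identical profiles
raise a degenerate-clustering error). Vectors are not standardised before
distance computation by default; a switch exists. A dividing-point sweep
reports responding-cluster size and mean CCF(0) for cuts k = 2…5.

## Surrogate nulls

**Markov-chain null (per filopodium).** Movement is discretised into 5
quantile states, a first-order transition matrix is fitted with add-one
smoothing, and surrogate movement series are drawn from the chain (states
sampled from its stationary distribution, values resampled from the
observed pool of each state), preserving the track's missingness mask so
per-offset pair counts stay comparable. The statistic is the maximum CCF
inside the ±6 s clustering window (CCF(0) optionally); the p-value is
`n_exceed/n_sims` with no +1 correction, so "fewer than 500 of 10,000"
corresponds exactly to p < 0.05. Simulation is vectorised across surrogates
and seeded.

**Reshuffling test (per dataset).** Each shuffle permutes every track's
valid movement values in place (mask positions fixed) and re-runs the full
CCF → clustering pipeline; the statistic is the responding subcluster's
mean CCF(0), and the p-value is again the exceedance fraction.

**Calibration and a known limitation.** Both nulls are exact only under
their own null hypotheses: exchangeable movement for the permutation test,
first-order-Markov movement for the chain. When the movement series is
autocorrelated (AR noise and/or moving-average smoothing), permutation
destroys that autocorrelation and the discretised chain under-represents
it, so both tests are mildly anti-conservative — measured at roughly a
0.075 flag rate at nominal 0.05 on decoupled AR(1)+MA-3 movement. The
calibration checks in the test suite and acceptance script therefore run
under the exchangeable null (decoupled tracks with i.i.d. movement and no
smoothing), where the measured rate is ~0.06 at n = 200 tracks and the
reshuffle p-value rank is uniform across master seeds. On real, smoothed
data these nulls should be read as the source workflow used them: a
screening annotation, not an exact size-0.05 test.

## Granger causality

Both series must reject the augmented Dickey–Fuller unit-root null at 0.05
(non-stationary tracks are excluded and flagged, not differenced, since the
workflow this follows confirmed stationarity and describes no transform).
A single shared lag L for the two models is chosen by minimising the BIC of
the full model over lags 1–5 on the common `max_lag` sample (ties toward
the smaller lag; the sample defines comparable BICs). Reduced and full
models are fitted by least squares on the same lag-embedded sample — rows
containing any missing value are dropped listwise — and compared with
`F = ((RSS_red − RSS_full)/L)/(RSS_full/(n − 2L − 1))` against
F(L, n − 2L − 1). Raw p-values are Benjamini–Hochberg corrected across the
tested filopodia at FDR 0.1. With BIC-selected lags at n = 150 the null
p-value distribution is indistinguishable from uniform (KS p ≈ 0.3 over
500 seeds), so lag selection introduces no detectable size distortion at
this length.

## Persistence and group comparisons

The autocorrelation function is computed per lag as pairwise-complete
Pearson correlation with acf(0) = 1. Persistence is the lag time at which
the movement ACF first falls below 1/e, linearly interpolated between
bracketing lags and capped (with a flag) at `max_lag` = 20 lags. For AR(1)
movement this estimator converges to −dt/ln(phi); at phi = 0.78, dt = 2 s
the closed form is 8.05 s and the estimator's mean over 100 seeds of
n = 2000 lands within a few percent (the linear interpolation of an
exponentially decaying ACF biases it slightly; well inside the ±15%
tolerance asserted). The 1/e threshold itself is a design choice validated
by that closed form — only "based on the autocorrelation function" is
specified by the source workflow, which is why absolute persistence medians
are not reproduction targets. The base-stall threshold (0.05 µm/frame) is
likewise invented and exposed in config. Group comparisons wrap
scipy/statsmodels: pairwise Mann–Whitney with Holm, Kruskal–Wallis,
Friedman with a rank-based Nemenyi post hoc (studentised-range
approximation, family = all pairs), and a Jarque–Bera-gated unpaired
t-test.

## Puncta, overlap, events, SMLM

Thresholding is manual-first (per-channel numeric thresholds; Otsu as the
auto fallback used by the synthetic tests). Puncta are 8-connected
components; the 0.06–1.00 µm² area band is converted to pixel counts by
rounding (14 and 237 pixels at 0.065 µm) and applied inclusively to the
pixel count — the convention of the particle-analysis tool the bounds come
from, and the only reading under which a "~14 pixel" punctum passes the
0.06 µm² bound. Overlap puncta are components of the AND of the two channel
masks, filtered by the same rule. The tip rule keeps puncta with at least
half their pixels (by count, pixel-centre-inside test) within a 1-µm-diameter
circle at the tip. Linking is greedy globally-closest-pair between
consecutive frames with a 0.65 µm cap, no gap closing, minimum 5 frames,
and a 1 µm start-near-boundary rule — deliberately mirroring a simple
tracking macro rather than optimal assignment; documented as a limitation.

Event alignment re-indexes per-filopodium traces (tip position along the
straightened axis, channel fluorescences, overlap flag — sampled over a
5-pixel axial window at the tip when 2-D profiles are supplied) to
event-relative time, computes velocity as per-frame displacement over dt,
and pools: proportion-with-overlap with a binomial normal-approximation CI
(Wilson optional) and mean velocity ± 1.96 SEM, both smoothed with a
3-frame moving average.

SMLM tables are filtered on photons [50, 5000], precision [0.5, 50] nm and
sigma [50, 150] nm (inclusive) and log-likelihood ratio < 150 (strict), then
rendered as a 2-D histogram at 16 nm pixels convolved with an isotropic
Gaussian whose sd is the mean precision of the retained localisations;
away from image borders the rendering conserves total counts.

## Synthetic-data generator

`CouplingParams` defines the study conditions the tests run under: a
standardised latent AR(1) fluorescence state Z (coefficient 0.7), responder
movement `M_t = beta·Z_{t−lag} + N_t` with beta = 0.15 µm/frame per sd,
lag = 1 frame, and AR(1) noise N (coefficient 0.3, sd 0.12 µm/frame);
non-responder movement is the noise alone. Defaults: 150 frames at
dt = 2 s, responder fraction 35/88, 2% of cells missing at random
(missingness mechanism is unstated in the source data, so
uniform-at-random is assumed). Recorded fluorescence channels are affine,
strictly positive images of Z with body and boundary levels bracketing it,
so the normalisation stage recovers an affine image of the latent state;
length is the cumulative movement floored at zero. AR(1) was chosen over a
fitted Markov chain as the fluorescence process because its closed-form
ACF enables analytic persistence checks; linear lagged coupling is the
minimal structure making both the CCF peak location and Granger causality
recoverable. Responder counts are floor(fraction·n) with the remainder
dropped deterministically; per-track seeds spawn from the master seed.

The image generator renders Gaussian puncta (sd 0.13 µm, i.e. 2 px) with a
rejection-sampled minimum centre separation of 8 sd so noise-free puncta
never merge, and shares `round(overlap_fraction · min(n_A, n_B))` centres
between channels; ground truth lists every punctum once. Event-trace and
localisation generators produce Bernoulli overlap steps with a velocity
pulse at t = 0, and bound-straddling localisation tables with per-row
keep/drop labels.

What the generator does *not* emulate: photophysics (blinking, bleaching),
growth-cone geometry, segmentation error, drift beyond a linear term,
heavy-tailed measurement noise, or non-random missingness. Passing the
synthetic checks therefore establishes correctness of the estimators and
their calibration under the stated models — not robustness of biological
conclusions to segmentation or imaging artefacts.

## Problem sizes and numerics

The validation suite uses 88-track datasets over 20 master seeds for
responder recovery, 200 tracks × 1000 surrogates for Markov-null
calibration, 20 × 200 shuffles for the reshuffle null, 100/500 seeds for
Granger power/uniformity, and 100 × 2000-frame series for the persistence
limit — sizes chosen so each check is statistically decisive at its stated
tolerance while the whole suite completes in about a minute. Monte Carlo
is seeded everywhere (`numpy.random.default_rng`; per-track substreams via
`SeedSequence.spawn`); OLS uses `numpy.linalg.lstsq` with a rank check that
raises on singular designs; correlations are clipped to [−1, 1] against
floating-point overshoot; BIC ties break toward smaller lags; quantile
bins with duplicate edges collapse states and at least two occupied states
are required to fit a chain.
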