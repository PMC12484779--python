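# Methods

This note documents the models, conventions and numerical choices behind
`creanet`, and what the synthetic-data generators do and do not emulate.

## Text metrics

**Tokenization.** The tokenizer is a pluggable callable; the default
strips a configurable punctuation character class (ASCII plus common CJK
marks; underscores are word characters) and splits on whitespace. A
Chinese word segmenter can be injected for real corpora without touching
the metrics. Tokens missing from the supplied lexicon are dropped and
counted, never imputed: imputing a vector would bias both metrics toward
whatever imputation scheme was chosen, while the drop count makes
coverage auditable per story.

**Global semantic distance (GSD).** Windows of `window=10` tokens start
at 0, `step=5`, `2·step`, …; each full window is represented by the mean
of its token vectors, and the score is the mean of `1 − cos` between
adjacent window means. If tokens remain beyond the last full window, one
trailing partial window is kept when it holds ≥ 2 tokens
(`keep_partial=False` drops it). Keeping the tail retains signal on
short stories; the flag exists because either convention is defensible
and the choice measurably shifts scores on stories whose length is not a
multiple of the step. At least two windows are required; shorter input
raises an error naming the minimum (window + step tokens for two full
windows). Cosine is scale-invariant, so any positive rescaling of the
lexicon leaves GSD and DSI unchanged (asserted in tests).

**Divergent semantic integration (DSI).** An injected provider returns
per-token vectors for two designated layers of a contextual embedding
model. Pairs are pooled across the whole story — sentences only scope
the embedding call, not the pairing — and DSI is the mean cosine
distance over all unordered token pairs, both layers pooled with equal
weight. The alternate reading (average the two layers' vectors per token
first, then one pass of distances) is available as
`average_layers_first=True`; the two readings genuinely differ (a test
constructs layers whose means coincide while each layer is maximally
spread), and pooled distances are the default because averaging vectors
can cancel divergence that each layer sees. A deterministic provider
backed by a static lexicon (`LexiconEmbedder`) supports tests and
desk-scale runs; real transformer weights are out of scope and plug in
through the same contract.

## Semantic network percolation

Nodes are a story's unique in-vocabulary words; the weight of every pair
is the Pearson correlation of the two embedding vectors, signed weights
retained. Thresholding follows the literal removal rule "weight < TH":
at TH = 0 strictly negative edges are already gone, and no absolute
value is taken. The grid is 0 to 1 inclusive in steps of 0.0125 (81
points). 0.0125 is not exactly representable in binary floating point,
so grid points are generated as `start + i·res` with the final point
snapped to 1.0, and edge-keep comparisons use `w ≥ TH − 1e-9`; without
the guard a weight of exactly 1.0 would be dropped at the nominal
threshold 1.0000000000000002.

The giant component counts only nodes with at least one surviving edge
(an isolated node is not a component of interest). The sweep stops at
the first threshold with GC < 3; that threshold's term is excluded from
PI, matching a reading of "the iteration stopped" in which the stopping
state is never accumulated; `include_stop_term=True` exposes the other
reading for sensitivity checks. Internally the GC curve is computed with
an incremental union-find sweeping the grid from high to low threshold
(components only merge as the threshold drops), which makes the 500
noise realizations cheap; tests verify exact agreement with a
brute-force oracle that rebuilds the graph at every threshold.

**Noise analysis.** Each of 500 realizations draws one SD uniformly from
[1/E, 10/E] (E = number of edges) and adds i.i.d. N(0, SD²) to every
edge weight, unclipped; PI is recomputed and averaged. Drawing the SD
once per realization (not per edge) matches "a variable SD ranging
randomly between" the bounds. A caveat worth knowing: when many weights
sit just below a grid region where the GC ≥ 3 band ends, noise extends
that band asymmetrically upward and the mean PI rises by several
percent; the perturbation is only guaranteed "small" when the weight
distribution is well separated from the thresholds where the component
structure changes.

**Link shuffling.** Each iteration samples round(0.8·E) distinct edges
without replacement, pairs them at random, and swaps the weights within
each pair (an odd leftover edge is untouched), preserving the weight
multiset exactly. Iterations are cumulative — each further shuffles the
current network — and PI is recorded after each of the 20 iterations and
averaged. On a fully connected network, rewiring endpoints is
meaningless, so exchanging weights is the only sensible reading of
"exchanging two edges". Twenty iterations at 80% touch each edge at
least once with probability 1 − 0.2²⁰ ≈ 1 − 10⁻¹⁴; the Monte-Carlo
estimate of that coverage is one of the recomputed acceptance
quantities.

**Word-count control.** Longer stories have more unique words and
mechanically larger PI. The control subsamples every token stream to the
shortest per-condition length (order preserved), repeats over seeds, and
averages. On the simulated set this collapses the within-condition PI
variance by an order of magnitude while preserving the condition
difference.

## Edge-centric connectivity

Regions are standardized with the population SD (divisor T), which makes
the time mean of each edge series equal the pair's Pearson r exactly —
the identity the whole construction rests on, asserted to 1e-10 in
tests. Trials are z-scored individually and then concatenated
(column-wise, trial order preserved); z-scoring per trial and per whole
run differ whenever trial means differ, and the per-trial convention is
the default because slow offsets between trials are acquisition
artifacts, not co-fluctuation. The condition-difference series
(imagery − control, computed elementwise) is supported as an alternative
input path; it is not z-scored and callers decide whether to
re-standardize.

Edge time series are averaged across subjects before clustering
(per-subject community maps remain available as a non-default path).
k-means with squared Euclidean distance runs directly on the E×T matrix
for each k in 2..20 with 10 seeded restarts and a 5000-iteration cap per
restart ("5000 iterations" is read as the per-restart cap, following the
public reference implementation of edge-community clustering);
scikit-learn's k-means relocates points into emptied clusters, so no
manual re-initialization loop is needed. Main outputs are reported as
the average over all k, which is what makes the node profiles stable to
the essentially arbitrary choice of k.

Normalized entropy uses natural log with a ln k normalizer (the base
cancels), with 0·ln 0 := 0. Community similarity between nodes i and j
counts matching labels over positions m ∉ {i, j}: the diagonal of the
node-community matrix is empty, implemented as a −1 sentinel that can
never match a genuine label, so the exclusion is automatic and the
denominator is N − 2. An `include_self_positions` variant divides by N
instead, for sensitivity checks. Per-network summaries treat nodes as
observations, so a 17-network comparison over 400 nodes has df = 16.

## Statistics

Mediation standardizes x, m, y (sample SD) before fitting, so paths are
standardized betas and the OLS identity total = direct + indirect holds
exactly (machine precision). The percentile bootstrap case-resamples
rows, refits both regressions per replicate via closed-form centered
cross-moments (vectorized across replicates; identical to per-replicate
least squares), and takes the 2.5th/97.5th percentiles of a·b over 1000
replicates. Note the estimand under standardization is a·b·σ_x/σ_y; for
the generator's default parameters (a = 0.5, b = 0.4, c′ = 0.2, unit
noise) that is ≈ 0.174, and the coverage property test targets exactly
that population value.

Kruskal–Wallis uses the tie-corrected H with ε² = H/(n−1); an
all-identical sample returns H = 0 rather than an error. The DSCF post
hoc computes, for each pair of groups, the Wilcoxon rank sum on the
pair's pooled average ranks with tie-corrected variance, scales the
standardized statistic by √2, and refers |q| to the studentized range
distribution with g groups and infinite df — the large-sample
approximation used by standard implementations; exact small-sample
tables are not implemented. Spearman partial correlation (covariate
control) correlates the residuals of rank-on-rank regressions, with
df = n − 2 − (number of covariates). The FDR family is always exactly
the declared list of pairs; no implicit pooling across tables.

## Synthetic data: what it emulates, and what it does not

Generator defaults mirror the study layout where one is stated:
200-dimensional embeddings; 400 regions in 17 networks, 10 trials per
condition; window 10/step 5; 500 noise realizations; 20 shuffle
iterations at 80%; 1000 bootstrap resamples. Knobs the study does not
pin down (cluster counts, within-cluster noise, block counts, path
coefficients a = 0.5, b = 0.4, c′ = 0.2 with unit noise) are fixed at
values that give realistic effect sizes, and are not tuned per analysis.

*Lexicon*: orthonormal cluster means (QR of a seeded Gaussian matrix)
plus isotropic noise, renormalized — so cluster structure is exact and
within/cross similarities are analytically known. It does not emulate
Zipfian token frequencies, polysemy, or anisotropic embedding geometry.
*Stories*: cluster-first token sampling with explicit weights; no
syntax, no discourse structure — so text-level results here demonstrate
metric behavior under controlled semantic composition, not naturalistic
writing. *BOLD*: each node is a shared block latent (standard normal per
time point) plus white noise; two conditions differ by block assignment.
Block-pair identity induces an exact ground-truth edge partition, which
is what makes edge-community recovery testable (ARI ≥ 0.9 at the true
k). It does not emulate hemodynamics, autocorrelation, scanner drift or
motion — passing recovery tests shows the pipeline's correctness, not
robustness to fMRI artifacts. *Behavior*: linear-Gaussian x→m→y with a
direct path; population indirect effect known in closed form.

## Problem sizes

Drivers and tests run at desk scale, chosen so the full suite finishes
in minutes on one CPU while every planted structure stays recoverable:
60-node / 4-block BOLD with 8 subjects (drivers) and 30-node / 3-block
with 3 subjects (tests), both with 10 × 30 time points; 40 subjects × 2
conditions × 45–75-token stories over a 180-word, 50-dimensional
lexicon; mediation tables of n = 80–5000. The 400-region, 17-network
default spec is exercised structurally (atlas construction, edge
indexing) rather than through full clustering runs.

## Known limitations

- The percolation stop rule excludes the stopping term by design; PI
  values are therefore slightly smaller than under the inclusive
  reading (flag available).
- DSCF p values rely on the asymptotic studentized-range reference;
  with very small groups they are approximate.
- The contextual-embedding provider shipped here is static
  (lexicon-backed); DSI with genuine contextual layers requires
  injecting an external model through the `ContextualEmbedder` contract.
- Noise-analysis PI means are only guaranteed close to the noiseless PI
  on networks whose weights are well separated from the thresholds at
  which components reorganize (see above).
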