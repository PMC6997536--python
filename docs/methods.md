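# Methods

## Rank normalization and imputation

Each prediction source is an ordered list of miRNA::mRNA interactions. Raw
scores are converted to ranks within each source (best = 1), respecting the
source's declared direction (`better-is-lower` for energies/p-values,
`better-is-higher` for probabilities). Tied raw scores receive midranks
(the average of the tied positions): midranks are deterministic,
independent of input order, and standard in rank statistics. Ranks are
normalized by the source's own list length *m_j*, so the worst untied item
in every source has relative rank exactly 1.0, and an interaction a source
never listed is imputed at the maximum relative rank, 1.0. This is the
"missing = ranked last" convention: it is conservative for sparsely listed
interactions and makes the aggregate operate on the union of all sources'
universes rather than their (much smaller) intersection.

An alternative convention normalizes every list by a single shared
denominator (a declared universe size); `build_rank_matrix(...,
universe_size=N)` supports it, but the per-list default is used throughout
because it is the one that puts each source's worst item at 1.0.

## Aggregation functions

Given an interaction's imputed row *r₍₁₎ ≤ … ≤ r₍ₙ₎* over the *n* sources:

* **mean / median / min / geomean** — elementary row summaries. The mean
  method's score is the arithmetic mean itself; the Bates CDF (the null
  distribution of a mean of *n* uniforms, `bates_cdf`) is available as a
  monotone p-value transform, and because the transform is monotone the
  reranking is identical either way.
* **rra** (the robust default) — under the null that the row is *n*
  independent uniforms, *r₍ₖ₎* ~ Beta(*k*, *n*−*k*+1); the score is
  ρ = min over *k* of the beta CDF p-values, multiplied by *n* (Bonferroni
  over the *n* order statistics, since the minimum is selected) and capped
  at 1 so scores stay in (0, 1] and read as significance-like values.
* **stuart** — the exact joint probability that all *n* order statistics
  are at most their observed values, by the alternating recursion
  v₀ = 1, v_k = Σ_{i=1..k} (−1)^{i−1} v_{k−i} r₍ₙ₋ₖ₊₁₎^i / i!,
  q = n!·v_n. The recursion accumulates x^i/i! with a running product, so
  no explicit large factorials appear until the final n! factor; with the
  handful of sources aggregated in practice (n ≤ ~10) double-precision
  arithmetic is exact to within rounding.

All scores are lower-is-better. Output lists are reranked ascending by
score with a deterministic tie-break: more listing sources first, then
lexicographic (miRNA, gene). A score threshold of 0.05 is exposed as the
recommended filter for shortlisting candidate targets; the threshold is a
convention, not a calibrated false-discovery rate.

### Null calibration

Under fully uninformative sources the corrected rra score is
super-uniform — P(score ≤ s) ≤ s — because it is a Bonferroni-corrected
minimum p-value; the acceptance suite verifies this with a one-sided
Kolmogorov–Smirnov check at α = 0.01 on 5,000 simulated items × 4 sources.
The mean score is not a p-value but its Bates transform is, and ranks
identically.

## Evaluation metrics

Scores are lower-is-better; labels mark experimentally validated
interactions. Tied scores are always swept as one threshold step, so the
ordering of tied items never affects any ROC or PR metric.

* **ROC/AUC** — trapezoidal area over distinct-score steps; equal (to
  10⁻⁹, verified by brute force in the tests) to the Mann–Whitney
  probability that a random positive outscores a random negative with ties
  half-credited.
* **Partial AUC** — the raw trapezoidal area of sensitivity over
  specificity ∈ [0.9, 1], with linear interpolation at the band boundary.
  Raw means unstandardized: the maximum is 0.1 and the chance diagonal
  yields 0.005. A `standardize=True` flag applies the McClish map onto
  [0.5, 1] when comparability across band widths is wanted. Sensitivity at
  90% specificity is read off the same interpolated curve; at a vertical
  jump exactly on the boundary the upper envelope is reported.
* **PR/AUC** — walking down the ranking, precision(i) = TP(i)/i and
  recall(i) = TP(i)/P; the area is the average-precision summation
  Σ precision·Δrecall over distinct-score steps. Linear interpolation
  between PR points is deliberately not used (it is optimistic for PR
  curves); this makes the numbers reproducible bit-for-bit.
* **Cumulative F-score** — F(i) = 2PR/(P+R) at every rank cutoff i, with
  F = 0 while no true positive has been retrieved. F at a top-fraction x
  uses cutoff round(x·N) with a minimum of 1. The single-number summary
  `mean_f` is the arithmetic mean of F(i) over all cutoffs: at the 100%
  cutoff every method on the same data set shares one F value, so a
  per-method "overall" F-score is only meaningful as a summary of the whole
  curve. The full-list value is 2p/(1+p) for prevalence p (0.0952 at 5%).

## Benchmark protocol

Compared methods are evaluated on the interactions *common* to all of them
(inner join on canonical (miRNA, gene) keys), carrying each method's own
score. From this parent set, replicate subsets are drawn without
replacement, stratified on the label so each replicate's number of
positives is round(subset_size × prevalence) — prevalence matching is exact
to the nearest integer count, e.g. 2,500 positives in every 50,000-item
replicate at 5%. Replicate *i* uses the independent seed stream
`default_rng([seed, i])`, recorded in its provenance, so the protocol is
reproducible end to end: two runs with one seed are byte-identical.

Per-metric differences are tested with a one-way repeated-measures ANOVA
(replicates as subjects, methods as the within-subject factor; F =
MS_method / MS_method×subject with (k−1, (k−1)(n−1)) df). No sphericity
correction is applied. Many-to-one comparisons against a control method use
paired t statistics with family-wise adjustment from the simulated null of
the maximum |t| over all contrasts: multivariate normal contrast vectors
with the estimated correlation of the observed difference columns, divided
by a shared chi-distributed scale (df n−1), 10⁵ seeded draws by default.
Closed-form Dunnett tables assume an equicorrelation structure that
repeated measures violates; the simulation uses the estimated structure
instead and is itself testable (family-wise error ≈ 5% under a simulated
global null). The adjusted p is clipped from below by the raw paired-t p,
and with a single contrast it equals the paired-t p exactly. With exactly
two methods the harness reports a paired Student t-test directly.
Significance is declared at adjusted p < 0.05.

## Synthetic generator

`simulate_sources` emulates the rank-list structure of a multi-database
benchmark. The universe is n interactions (miRNA × gene grid); exactly
round(prevalence·n) are labeled validated (default prevalence 5%, the
standard figure for prediction benchmarks of this kind). Source j's latent
score is signal_j·label + ε with ε ~ N(0, 1) i.i.d., so signal 0 gives AUC
1/2 and the per-source AUC is monotone in signal (Φ(signal/√2) in
expectation); the default signal 1.0 puts a single source near AUC 0.76,
the realistic "useful but noisy predictor" regime in which ensemble gains
are visible but not trivial. Coverage (the fraction of the universe a
source lists) is sampled independently of the label by default, so
missingness is uninformative; `coverage_bias` (log-odds units) makes
validated interactions more likely to be listed, to probe the sensitivity
of max-rank imputation. An alternative `mallows`-style noise model
(Gaussian displacement of positions in the label-perfect ordering) is
available behind a flag.

Three profiles freeze the study conditions: `tiny` (100 interactions, 3
sources, 80% coverage, signal 2 — inspection and golden files), `bench`
(50,000 interactions, 4 sources, full coverage, signal 1, 5% prevalence —
the replicate design), and `paper_scale` (10⁶ interactions, otherwise as
bench). Fixture files are byte-identical across runs for a fixed seed.

What the generator does *not* model: sequence features, correlated errors
between sources (real databases share features and training data, so their
errors correlate; a passing ensemble-gain test on independent noise shows
the machinery works, not that aggregation must help on any four real
databases), heavy-tailed score distributions, and miRNA- or gene-level
effects (all interactions are exchangeable). Conclusions from the synthetic
benchmark are about the correctness of the pipeline, not about any
particular database.

## Problem sizes in the shipped checks

The end-to-end recovery experiment aggregates 4 equal-signal sources over
50,000 interactions and compares against each single source on 10
stratified replicates of 10,000 interactions each (the parent must exceed
the subsets for the ANOVA error term to exist; 10,000 keeps per-replicate
AUC standard errors near 0.01, small against the designed ≈0.15 AUC gap),
repeated over 20 seeds. Monte-Carlo oracles use 2×10⁶ draws for the
order-statistic closed forms and 5,000 items for null calibration.

## Identifier handling and pathways

miRNA names are matched case-insensitively against the alias table (miRNA
nomenclature changes across releases, e.g. `hsa-miR-16` →
`hsa-miR-16-5p`); gene identifiers are opaque strings matched exactly.
Canonical identifiers are fixed points of the mapping, one alias cannot map
to two canonical ids, and unmapped identifiers pass through unchanged but
are reported — silent dropping would bias any downstream join. Pathways
(GMT format) are ranked for a given miRNA by the proportion of member genes
targeted at the score threshold; the denominator is all member genes by
default, or only those present in the prediction universe with
`denominator="universe"` (both are defensible; the default treats absent
genes as untargeted rather than unknown).

## Known limitations

* The aggregation treats sources symmetrically; there is no per-source
  weighting or reliability estimate.
* Max-rank imputation penalises interactions missing from short, selective
  sources more than a model-based imputation would.
* The RM-ANOVA applies no sphericity correction; with few replicates and
  many methods its p-values can be liberal.
* The Dunnett adjustment plugs in the estimated contrast correlation, which
  is noisy for small replicate counts; the simulated null treats it as
  known.
* PR-AUC by average precision is slightly biased above prevalence for
  random rankings at finite list length (O(1/(n·p))); comparisons between
  methods on the same data set are unaffected.
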