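# Methods

## Statistical model and procedure

`appsig` addresses a two-class classification problem on a gene × sample
intensity matrix with very few samples per class (the motivating design:
13 phlegmonous vs 16 gangrenous pediatric appendicitis patients, ~56,666
genes). Because a single held-out split at n = 29 is dominated by split
noise, discovery (biomarker selection + model fitting) and validation
(performance measurement) alternate over bootstrap resamples.

Per iteration *b* = 1…B:

1. Draw n sample indices with replacement → discovery multiset; the
   out-of-bag (OOB) samples — those never drawn, ~36% of samples in
   expectation (mean OOB size n·(1−1/n)ⁿ ≈ 10.5 at n = 29) — form the
   validation set.
2. Rank all genes by |Welch t| computed **on the discovery samples only**.
3. Build nested candidate signatures: top-1, top-2, …, top-k_max.
4. For each candidate, fit a ridge logistic model on the discovery samples
   and record discovery AUC, OOB class probabilities and OOB AUC.

Aggregation: the winning size k\* maximizes mean OOB AUC across iterations
(ties → smaller size). The reported signature consists of the k\* genes most
frequently ranked into the per-iteration top-k\* (frequency ties →
lexicographic gene id). ROC curves are aggregated per probability threshold
as mean ± SE over iterations; throughout, "SE" is the bootstrap standard
error, i.e. the SD of the per-iteration statistic (not SD/√B). The headline
AUC is the mean of per-iteration OOB AUCs; the area under the
threshold-averaged mean ROC curve is reported alongside. Two lower 95%
confidence limits are emitted — normal approximation (mean − 1.96·SE) and
the 2.5th percentile of per-iteration AUCs — because either convention is
defensible for bootstrap intervals; neither is privileged.

## Key design choices (where the design was genuinely open)

- **Candidate construction.** Nested top-k by discovery-set |Welch t|,
  k = 1…k_max (default 10). This is the simplest rule that yields "a
  sequence of distinct biomarker signatures" and lets a small winner emerge
  from tens of thousands of genes; exhaustive subset search is infeasible at
  this dimensionality.
- **Ranking inside the loop.** Per-discovery-set ranking is the default:
  ranking once on the full data would leak validation samples into gene
  selection and bias OOB AUC upward. A `ranking="global"` mode exists
  precisely to demonstrate that optimism, not for production use.
- **Discovery-quality metric** is the AUC of the fitted probabilities on the
  discovery multiset (duplicates included).
- **OOB constraints.** Splits are redrawn (≤1000 attempts) until the OOB set
  holds both classes — otherwise sensitivity/specificity are undefined — and
  until the discovery multiset holds ≥2 samples of each class, without which
  the Welch ranking and logistic fit are undefined. At n = 29 (13/16) both
  constraints trigger with negligible probability, so OOB-size statistics
  match the unconstrained bootstrap closed form to well within sampling
  error.
- **Regularization.** λ = 1 ridge on z-scored features, intercept
  unpenalized. With ≤29 samples and up to 10 genes, complete separation is
  routine; any λ > 0 keeps coefficients finite, and z-scoring makes one λ
  comparable across genes. The standardization (fit-data mean/SD, population
  SD) is stored in the model and reapplied verbatim to validation samples.
  The unpenalized intercept's score equation forces mean fitted probability
  = class prevalence at any λ.
- **IRLS numerics.** Newton steps on the penalized log-likelihood; stop at
  max |Δβ| < 1e-8 or 100 iterations (`converged` records which). IRLS
  weights are floored at 1e-10 to guard the weighted least-squares solve
  when fitted probabilities saturate. Zero-variance signature columns get
  weight 0 (with a warning) and stored SD 1 so prediction stays defined.
- **Quantile-normalization ties** share the mean of the reference
  distribution over their tied rank span — the convention of the canonical
  microarray implementations — which makes the transform idempotent and
  rank-preserving.
- **Normalization order and leakage.** The matrix is quantile-normalized
  once, on the linear scale, before resampling, then log2-transformed —
  normalization-first mirrors the standard microarray order, and the
  chosen scale is recorded in the run manifest. Renormalizing inside each
  bootstrap draw was considered and not made the default: cross-sample
  quantile normalization uses no label information, so its leakage risk is
  second-order, while per-iteration renormalization makes iteration metrics
  incomparable across iterations.
- **No multiple-testing correction** in the faithful DE mode: the
  significance rule is raw p < 0.05. A Benjamini–Hochberg column
  (`add_bh=True`, via `scipy.stats.false_discovery_control`) is available
  for reference and never feeds the significance flag.
- **Degenerate Welch inputs.** Both variances zero: t = 0, p = 1 if means
  are equal, else p = 0 with signed infinite t and df fixed at n0+n1−2.
  Rows are never dropped, so the DE table always has one row per gene.
- **Thresholds.** Classification is strict (`p > threshold` → GA) so the
  0 and 1 cut-points are well defined; the default ROC grid is 0.05–0.95 in
  steps of 0.05 (19 points).
- **Determinism.** One global seed is expanded through
  `numpy.random.SeedSequence` into independent per-stage streams, so
  changing B leaves the simulated data untouched; outputs contain no
  timestamps, making repeated runs byte-identical.

## The synthetic-data generator

The generator emulates the motivating study design rather than any specific
real dataset: intensities are log-normal (Gaussian on the log2 scale) with
per-gene baseline means uniform on [4, 14] log2 units (a typical
single-channel dynamic range) and within-group SD `sigma_log2 = 1`.
Informative genes shift the GA mean by `delta_log2` (default 2.0, i.e. a
4-fold change — strong but attainable for a recoverable signature at
n = 29), so true log2FC equals `delta_log2` by construction. Genes are
independent by default; `equicorrelation` adds a shared per-sample factor
when correlated noise is wanted.

Default test scale is 2,000 genes with 4 informative; the full-scale preset
(`emulate_study_scale`) uses 56,666 genes, 13 vs 16 samples, 4 strong genes
at Δ = 2.5 and ~3,400 background genes with shifts drawn uniformly from
[0.1, 0.9] log2 units with random sign. That background interval was set by
a closed-form Welch power calculation at n = 13/16, σ = 1: together with
the ~4.7% false-positive floor of 53k null genes at α = 0.05 it puts the
expected significant fraction near the ~6% design point the preset emulates.

What the generator does **not** model: probe-level artifacts, batch and dye
effects, realistic gene–gene correlation structure, heavy-tailed noise, or
mean–variance coupling. Passing tests therefore demonstrate that the
pipeline's mechanics (no leakage, calibration under the null, recovery of a
planted signal, correct aggregation arithmetic) are sound — not that any
particular performance level will transfer to real cohorts.

## Problem sizes used in tests and the acceptance script

Null-calibration and signal-recovery checks run 20 seeded pipelines at
B = 100 iterations on 2,000-gene datasets, and the type-I-error check uses
one 5,000-gene null dataset — sizes at which the binomial/bootstrap bands
being asserted are already tight. The acceptance script runs the
differential-expression pass at the full 56,666-gene scale and the signature
search at the default 2,000-gene scale with the faithful B = 1000.

## Known limitations

- Selection of the best size by maximum mean OOB AUC induces a mild
  optimistic bias in the headline AUC (a max over 10 correlated means); the
  OOB AUCs per fixed size are themselves unbiased.
- Bootstrap iterations share the same 29 samples, so per-iteration OOB AUCs
  are correlated; the bootstrap SE quantifies resampling spread, not
  independent-cohort spread, and per-dataset mean AUC retains
  dataset-to-dataset variance that does not shrink with B.
- With k_max near the sample count, ridge at λ = 1 shrinks aggressively;
  the fixed-λ mode is deliberate (no tuning loop), and λ is surfaced in the
  configuration for sensitivity analysis.
- The OSF deposit layout of the motivating study is unspecified; no adapter
  for it ships, and nothing in the package requires a download.
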