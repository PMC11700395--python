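# Methods

## Problem setting

`xferdrp` predicts a drug's dose–response AUC (area under the
cell-viability-vs-dose curve; lower = more sensitive) from gene-expression
profiles of patient-derived cell cultures. The regime of interest is a
*small* target cohort — a few dozen samples against tens of thousands of
genes — where a regressor trained from scratch is weak and unstable. The
package implements a two-step transfer-learning strategy: pretrain on a
large, heterogeneous source cohort screened with a related drug, refine on a
medium disease-specific domain cohort, then fine-tune on the target cohort,
carrying only the gene-indexed first-layer weights between stages.

AUC is treated strictly as a *relative* measure: dose ranges and curve-fit
conventions differ between screening projects, so absolute values are not
comparable across cohorts. Consequently every model is scored by the Spearman
correlation coefficient (SCC) between predicted and observed AUC — the
Pearson correlation of average ranks — and the response is min-max scaled per
(cohort, drug) to [0, 10] purely to give the network a fixed target range.

## The regressor

A feed-forward network: dense(genes → 1000, sigmoid) → dropout 0.3 →
dense(1000 → 100, softplus) → dropout 0.1 → dense(100 → 1, softplus).
The softplus output keeps predictions non-negative, matching the scaled AUC.
Parameters are initialized uniformly in ±0.05 from a seeded generator; the
loss is mean squared error plus an L2 penalty (1e-4) on all weight matrices
and biases; optimization is minibatch Adam. (build, train, predict) is a pure
function of (config, data, seed): initialization, batch shuffling and dropout
masks all derive from the config seed.

Defaults and rationale:

| parameter | default | why |
|---|---|---|
| hidden widths | 1000, 100 | reference architecture for ~10⁴-gene inputs |
| activations | sigmoid, softplus, softplus | non-negative output; saturating first layer bounds feature scale for transfer |
| dropout | 0.3, 0.1 | regularization after each hidden layer |
| L2 strength | 1e-4 | applied to weights *and* biases of all dense layers |
| init bounds | ±0.05 | small uniform init keeps sigmoid units unsaturated |
| optimizer | Adam, lr 1e-4, 100 epochs, batch 32 | defaults are exposed, not sacred; `grid_search` tunes lr/epochs by CV on the source cohort |

The implementation is plain NumPy (forward/backward passes written out): the
model is small enough that a deep-learning framework buys nothing, and a
self-contained implementation makes bit-exact seeded reproducibility and
gene-addressed weight surgery straightforward.

### Input-layer transfer

The unit of transfer is the first dense layer: a genes × H1 weight matrix
plus H1 biases, always addressed *by gene id, never by position*. Injection
into a target model copies, for each target gene, the source row for that
gene id; source genes absent from the target are ignored; a target gene
missing from the source is an error (strict mode). Upper layers are freshly
initialized at every stage and all parameters remain trainable during
fine-tuning. Immediately after injection and before any training step, the
shared-gene first-layer weights are bitwise-equal to the source's — this is
asserted in the test suite and is what makes archived weights a faithful
currency between cohorts profiled on different platforms (after reducing to
the gene intersection).

## Preprocessing

Per dataset: optional log2 transform (with configurable pseudocount); a
low-variance gene filter that drops genes whose variance falls *strictly
below* the q-quantile (default 0.25, linear-interpolation quantile) of all
per-gene variances — ties at the threshold are kept; min-max scaling of the
AUC to [0, 10].

Two leakage caveats are inherited from the modelled pipeline and kept
deliberately, with a leakage-free alternative available:

* AUC min-max scaling is fit once per (cohort, drug) on all samples before
  CV. Because the transform is strictly monotone, ranks — and therefore every
  SCC reported — are unaffected; only the absolute prediction scale could
  leak.
* Feature standardization (per-gene mean 0, population sd 1) is applied to
  train and test partitions *independently* by default
  (`standardize_mode="per_partition_independent"`). The
  `"fit_on_train"` mode applies training-fold statistics to the test fold
  and is the recommended choice for new analyses.

Zero-variance rows standardize to all-zeros with a warning rather than NaN.

## Evaluation protocol

One frozen `CVPlan` per (dataset, seed): repeated stratified k-fold
assignments (5-fold for the larger cohorts, 3-fold for the small target; 10
repetitions). Stratification of the continuous response uses quantile
binning: samples are sorted by AUC and cut into `strat_bins` near-equal
groups; within each bin a repetition-specific RNG shuffles the members, and
one continuous round-robin deal across bins assigns folds, so overall fold
sizes differ by ≤1 *and* per-bin fold counts differ by ≤1. Every method
compared on a dataset — no-TL, one-step, two-step, elastic net, single-gene
polynomial — consumes the identical plan (asserted via a SHA-256 plan hash),
which licenses paired tests over repetitions.

Each repetition trains one fresh model per fold on the training partition
and predicts the held-out partition; out-of-fold predictions are pooled into
a single vector and scored once per repetition (one SCC per repetition, 10
per experiment). Pooling was chosen over averaging per-fold SCCs because a
3-fold split of 22 samples leaves ~7 test samples per fold — a per-fold rank
correlation at that size is extremely unstable; a `fold_mean` mode is
provided. Constant predictions score 0 with a warning instead of NaN, so
repetition vectors stay complete for paired tests.

Significance: a two-sided Wilcoxon signed-rank test over the 10 paired
per-repetition SCCs. The null distribution is exact — full 2ⁿ sign
enumeration (implemented as subset-sum counting, verified against literal
enumeration in the tests) — for n ≤ 12 non-zero differences, with zeros
dropped and average ranks for ties; a continuity-corrected normal
approximation is used above. A rank-sum test for two independent groups
(exact by enumeration for m+n ≤ 12) supports biomarker-style group
comparisons.

## Transfer pipeline

* **Pretraining** fits one model per source drug on the full source cohort
  (restricted to the common gene intersection, sorted lexicographically for
  determinism) and archives the input layer per drug.
* **Source selection** evaluates each source drug by one-step transfer into
  the domain cohort under the domain's frozen CV plan and picks the drug with
  the highest mean SCC (ties broken lexicographically; margins logged).
* **Refinement** trains a domain model initialized with the selected source's
  first layer on *all* domain samples (no fold model is carried forward —
  the fold models exist only to score the selection; a refit on the full
  domain set uses every sample and keeps the carried-forward weights
  independent of any particular partition).
* **Target evaluation** injects the refined first layer into fresh target
  models inside the frozen repeated CV.

Stage seeds derive as `hash(global_seed, stage, drug)` (SHA-256, reduced
below 2³¹), so adding a source drug never perturbs other stages, and a
two-step run with refinement disabled reproduces the one-step run
bit-for-bit — a degeneracy the tests assert exactly.

## Benchmarks

* **Elastic net** on the top-k features by univariate linear-regression
  F statistic, selection refit on every training fold (never on held-out
  samples; a leakage test asserts this). Mixing 0.5; the penalty strength is
  chosen per training fold by an internal 3-fold CV over a log grid — the
  reference analysis does not state its elastic-net hyper-parameters, so they
  are explicit configuration here.
* **Single-gene polynomial** (degree 2 by default) — the clinical
  biomarker-style baseline: least-squares fit of AUC on powers 1..d of one
  gene's expression per training fold.

## Gene importance

Per-gene scores collapse the genes × H1 first-layer matrix to one scalar:
signed sum (default; `mean` ranks identically), or unsigned L2 row norm. The
signed default lets a downstream preranked enrichment tool distinguish
pathways loaded toward sensitivity from those loaded toward resistance. The
export is the standard two-column, headerless, tab-delimited `.rnk` file,
sorted descending with ties broken by gene id — byte-identical for identical
weights. The enrichment statistic itself is out of scope. How to collapse
H1 outgoing weights into one scalar per gene is genuinely underdetermined;
all three aggregations are provided and the choice is recorded.

## Synthetic cohorts

The generator replaces the external screening cohorts as the test bed. Per
sample, a latent state z ~ N(0, I₈) drives both expression and response:

* **Expression** x = Bz + cohort_shift + ε. B is sparse: each gene loads on
  one latent factor with an N(0,1) coefficient. With the default expression
  noise (sd 3) a single gene carries a signal-to-noise ratio of ~0.1, so
  latent recovery requires aggregating many genes — feasible for a model
  trained on 700 source samples, out of reach for one trained on 15 target
  samples. This calibration reproduces the regime the method addresses: the
  22-sample no-transfer baseline is weak and unstable across simulation
  seeds, and transfer provides a large, consistent gain. Per-cohort shifts
  (sd 0.3) model platform/site offsets.
* **Response** r = logistic(z·w_d + ε), ε with sd 0.5. The target drug acts
  through a unit vector w*; a source drug with mechanism similarity s acts
  through w_d = s·w* + √(1−s²)·w⊥. Similarity 1 shares the response
  mechanism fully; 0 not at all. A `skew` parameter applies r ↦ r^(1/(1+skew)),
  concentrating mass near the resistant bound the way a screen of a broadly
  ineffective drug looks (with skew 9, the median raw AUC exceeds 0.9 and
  ~70% of samples lie above 0.9).
* **Gene spaces**: cohorts share a core of `gene_overlap`·n_genes genes; the
  remainder enters each cohort independently, and each cohort's gene order is
  shuffled — so the pipeline's intersection and gene-addressed injection are
  exercised exactly as mismatched platforms would.

Default conditions (the "default scenario" used by the tests and the
reproduction script): 500 genes, latent dimension 8, source drugs DRUG_A
(s = 0.9, n = 700) and DRUG_B (s = 0, n = 700), domain n = 80, target n = 22,
gene overlap 0.9. The scenario network keeps the reference architecture's
shape at reduced size — hidden 100/20, lr 1e-3, 80 fine-tuning epochs, 30
pretraining and 60 refinement epochs — so a full two-step comparison runs in
about 15 s per seed on one CPU; these problem sizes are the package's own
choice for a desk-scale test bed.

What the generator does *not* emulate: dose–viability curves and AUC
integration conventions (responses come from a logistic link, not curve
fitting), microarray probe effects, batch structure within a cohort, gene-gene
correlation beyond the shared latent factors, and biological pathway
structure. Passing the synthetic acceptance suite therefore demonstrates that
the machinery recovers transfer benefit, source selection and stability
orderings *when the generative assumptions hold* — it does not certify
effect sizes on real screening cohorts.

## Numerical and design choices

* Quantile type for the variance threshold: linear interpolation (the common
  default); the threshold and counts are logged so runs are auditable. The
  filter keeps ties ("strictly below" is removed), so an all-equal-variance
  matrix passes through unchanged.
* Spearman of a constant vector is defined as 0 with a warning (keeps paired
  test vectors complete).
* Duplicate gene rows in input files keep the first occurrence with a
  warning — upstream pipelines deliver gene-level matrices, so duplicates
  indicate dirty input, not a modelling choice. Gene identifiers are matched
  exactly; no cross-platform symbol reconciliation is attempted.
* Weight archives are single-file `.npz` containers of named arrays plus a
  JSON metadata entry (gene ids, network config); numeric payloads round-trip
  bitwise.
* Ascending lexicographic gene order after intersection: no ordering is
  canonical, and a deterministic one makes transferred weights reproducible.

## Known limitations

* The per-partition-independent standardization default reproduces the
  modelled protocol but lets test-fold statistics influence test features;
  use `fit_on_train` for leakage-free analyses.
* With 22 samples, 3-fold pooled SCCs still have high repetition variance;
  the paired design over frozen partitions is what makes comparisons
  meaningful, not the individual SCCs.
* The exact signed-rank enumeration is limited to n ≤ 12 (beyond that the
  normal approximation with tie correction takes over) — adequate for the
  10-repetition design.
* Training is single-threaded NumPy; the default full-width network on
  ~10⁴ genes is minutes per fit, not seconds. The scaled scenario network
  exists for exactly this reason.
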