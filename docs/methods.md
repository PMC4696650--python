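# Methods

## Problem setting

K independent case/control expression studies measure overlapping but
unequal gene panels (different array platforms), on the log2 scale,
normalized within each study but not across studies. The goal is a
*consensus signature*: genes whose differential expression replicates in
direction across studies, ranked so that both effect size (fold change) and
statistical strength (p-value rank) are visible, and usable downstream as a
feature set for sample classification.

## Per-study differential expression

For each probe with at least 2 complete observations per group, the log2
fold change is the difference of group means (missing values excluded
pairwise). The test statistic is a moderated two-sample t: with pooled
variance s² on d = n₁+n₂−2 degrees of freedom, the shrunken variance is

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d)

where the prior variance s₀² is the mean of the per-probe pooled variances
in that study and d₀ (`prior_df`, default 4) controls the shrinkage
strength. The statistic t = (m₁−m₂)/(s̃·√(1/n₁+1/n₂)) is referred to a t
distribution with d₀+d degrees of freedom. This is a deliberately
simplified empirical-Bayes moderation: the prior is a fixed plug-in rather
than a fitted hierarchical model, which keeps the procedure deterministic
and closed-form, and at `prior_df = 0` it reduces exactly to the classical
pooled t-test (a tested invariant). Benjamini–Hochberg q-values are
computed within each study at the probe level, before gene collapse,
matching how per-study web tools adjust their outputs.

A probe is a DEG when |log2FC| ≥ log2(`fc_threshold`), default 1.5 on the
linear scale. The threshold is applied symmetrically on the log2 scale so
up- and down-regulation are treated alike. Probes collapse to genes by
keeping, per gene symbol, the record with maximal |log2FC| (ties: smaller
p, then lexicographic probe ID); unannotated probes are dropped.

## Consensus aggregation

For each gene in the union of the per-study gene tables:

- **CDR** = max(#studies passing up, #studies passing down) / K. The
  denominator is the total number of studies by default (`cdr_denominator =
  "total"`): a gene absent from the small platforms still needs 3 passing
  studies out of 5, which is the conservative reading of "3 out of 5". The
  alternative `"measured"` divides by studies where the gene was measured.
- **Direction**: the majority sign. A gene whose up- and down-counts both
  independently reach the CDR cut, or that ties with equal non-zero counts,
  is labelled `conflict` and excluded — the signature is defined as
  *consistently* up- or down-regulated.
- **Average log2FC** over the studies where the gene was measured, and the
  minimum p across them.
- **Percent significance rank**: within each study, genes are ordered by
  raw p (midranks for ties — ordering by FDR-adjusted p barely changes the
  ranking and is available as an option) and assigned
  100 × rank / (genes tested in that study); the per-gene average over
  measured studies puts studies with 22k-probe and 54k-probe panels on a
  common [0, 100] scale. `top_fraction_count(total, 0.05)` =
  ⌊total × 0.05⌋ defines the "top 5% most significant" set of a study.

The signature keeps genes with CDR ≥ `cdr_threshold` (default 0.6) and an
unambiguous direction, ordered by |average log2FC| descending (ties:
ascending average percent rank, then symbol).

## Batch adjustment and classification

Studies are merged on the signature genes measured in every study (the
per-study collapse chooses which probe represents a gene). Batch effects
are removed by exact per-batch location/scale standardization: per gene,
each batch is centered and scaled by its own mean/SD, the standardized
matrix is rescaled by the pooled SD of the fit data, and the gene's pooled
pre-adjustment mean and SD are restored. This is the closed-form limit of
ComBat with the empirical-Bayes shrinkage disabled — appropriate for a few
batches of moderate size, and deterministic. All parameters (batch means
and SDs, pooled targets, the rescale factor) are estimated on the training
split and applied frozen to held-out samples, so adjustment cannot leak
test information; whether the original analyses did this is typically
unstated, and the leakage-safe choice is adopted here.

Classification is a C-classification SVM with radial kernel. Cost ∈ {0.1,
1, 10, 100} and kernel width γ ∈ {1/(2g), 1/g, 2/g} (g = number of
signature genes) are tuned by stratified k-fold cross-validation (default
10 folds) on the training split; the best pair is refit on the full
training set and scored on the held-out split with a confusion matrix.
The held-out fraction is configurable (`test_fraction`, default 0.25,
per-class rounding with a minimum of one sample); all randomness (split,
fold shuffling) derives from a single user seed.

## QC

Samples are clustered on the batch-adjusted signature matrix with euclidean
distance and complete linkage; the two-cluster cut is compared with the
case/control labels (agreement = best fraction over the two label
permutations). PCA uses gene-wise mean centering without scaling — the
data are already on a common log2 scale — and reports per-component
variance fractions; a first component explaining more than twice the
second indicates a dominant axis, which on signal-bearing data is the
disease axis. Outliers are samples whose first merge height into the tree
exceeds median + 3×MAD computed on *log* merge heights with the
normal-consistent MAD (×1.4826). Nearest-merge distances are right-skewed,
and on the raw scale this rule flags samples even in homogeneous Gaussian
clouds; the log scale makes the rule behave as intended (no flags on
homogeneous data, reliable flagging of a 10σ-displaced sample). The rule
itself is a pragmatic invention — the QC step only requires *some*
criterion for "joins the tree unusually late".

## Over-representation

Signature-vs-gene-set overlap is scored by the hypergeometric upper tail
P(X ≥ k) with BH adjustment across sets. The universe is the union of
genes measured in any analyzed study — the genes the experiment could have
reported — switchable to the all-platform intersection. Commercial
literature-mining enrichment engines score differently and are out of
scope; this is the standard measured-universe test.

## Synthetic data generator

The generator emulates the five-study design the pipeline targets:
per-study (case, control) sizes (21,18), (20,13), (12,6), (10,7), (10,10)
— 127 samples; three full-panel studies and two studies measuring a random
45% of genes, echoing a 54k-probe vs 22k-probe platform split; G = 2000
genes (scaled down from array size so the full pipeline runs in seconds
while preserving the K/platform/size structure); 200 planted genes with
|log2FC| ~ U[0.8, 2.5], random sign, each active in a random ≥ 3 of the
studies that measure it (three full panels guarantee this is possible);
per-gene baselines ~ N(8, 1.5) and residual SD ~ U[0.3, 0.8]; 1–3 probes
per gene with per-probe baseline offsets and effect jitter (SD 0.1); and
per-study batch shifts (location ~ N(0, 0.5), scale ~ U[0.8, 1.25]).

The batch scale multiplies the baseline-plus-noise component only; the
class effect is added afterwards, so an active gene's true per-study log2FC
equals its configured effect — this keeps the truth table exact and the
fold-change estimator unbiased (a tested property). Everything is
deterministic given the seed.

What the generator does **not** emulate: heavy-tailed or intensity-
dependent noise, probe-sequence effects, correlated gene modules, paired
lesional/non-lesional sampling, and platform-specific normalization
artifacts. Passing the synthetic acceptance checks therefore demonstrates
that the pipeline's logic is correct under its stated model — Gaussian
noise, additive effects, location/scale batches — not that real cohorts
will reach the same accuracies.

## Numerical choices and degenerate inputs

- p-values are clipped to [tiny, 1]; BH input is validated to (0, 1].
- Zero within-batch SD (constant gene in a batch): centering only, no
  division; zero shrunken variance raises a dedicated error (only possible
  when both s² and s₀² are 0).
- Probes with < 2 complete observations in either group are skipped;
  a dataset with no testable probe raises an empty-analysis error.
- Rank ties receive midranks, making percent ranks independent of input
  order; probe-collapse and signature ordering use stable sorts with
  explicit tie-breaks, so outputs are byte-reproducible at fixed seed.
- The percent-rank formula is fixed as 100 × position / total (e.g.
  100 × 5 / 22283 = 0.022, reported to three decimals).

## Problem sizes used in validation

The acceptance-level checks run the default design (K = 5, G = 2000, 200
planted, 127 samples) once at seed 42, ten null-design replicates for
false-positive control, twenty null replicates for the chance-level
classification check, and small enumerative oracles (all 3⁵ CDR flag
assignments, hypergeometric universes up to N = 12, 200 random BH
vectors). These sizes were chosen so the entire validation completes in
well under a minute per scenario while leaving the statistical conclusions
stable across seeds.

## Known limitations

- The moderated t uses a fixed prior rather than estimating d₀ and s₀²
  hierarchically; q-values are correspondingly approximate relative to a
  full empirical-Bayes fit.
- CDR treats studies symmetrically regardless of size or quality.
- The location/scale batch model cannot remove batch-by-class interaction
  effects, and with strongly unbalanced class ratios per batch, centering
  can absorb some class signal.
- The merge step requires signature genes to be measured in *every* study,
  which shrinks the classification feature set when platforms differ
  widely (with the default design, roughly a fifth of signature genes
  survive the intersection).
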