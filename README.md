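# consig

Rank-based consensus analysis of gene-expression studies: find the genes
that are differentially expressed *consistently* across several independent
case/control transcriptome datasets, and use that consensus signature to
classify samples.

Single-study differential-expression lists from microarray or RNA
experiments of the same disease often disagree badly — different platforms,
cohorts and batch effects produce different gene lists. `consig` implements
a meta-analytic pipeline built for exactly this situation (its motivating
use case is atopic dermatitis skin biopsies vs healthy controls across five
public microarray studies):

1. **Per-study differential expression.** For each study, per-probe log2
   fold change (case mean − control mean), a moderated t-statistic with
   variance shrinkage s̃² = (d₀s₀² + d·s²)/(d₀ + d) toward the study-wide
   mean pooled variance s₀², and Benjamini–Hochberg FDR q-values. A probe is
   a DEG when |log2FC| ≥ log2(1.5). Probes collapse to genes by keeping the
   probe with the largest |log2FC|.
2. **Common Dataset Ratio (CDR).** For each gene,
   CDR = max(#studies up, #studies down) / K over the K studies. Genes with
   CDR ≥ 0.6 (at K = 5: a direction-consistent DEG in ≥ 3 of 5 studies) and
   an unambiguous direction form the consensus signature, ordered by
   average |log2FC|.
3. **Percent significance rank.** Within each study, genes are sorted by
   p-value and assigned 100 × position / total; a gene's average percent
   rank across studies (e.g. position 5 of 22283 → 0.022) summarizes its
   consensus statistical strength independently of platform size.
4. **Batch-adjusted classification.** Studies are merged on signature
   genes, per-study location/scale batch effects are removed (fit on the
   training split, frozen for the test split), and an RBF-kernel SVM tuned
   by stratified 10-fold cross-validation predicts case vs control.
5. **QC and enrichment.** Hierarchical clustering (euclidean, complete
   linkage) and PCA variance structure of the signature matrix, plus
   hypergeometric over-representation of the signature in GMT gene-set
   collections.

A synthetic multi-study generator with planted, direction-consistent
effects, unequal platform panels, probe multiplicity and batch shifts
provides ground truth for end-to-end validation.

## Worked example

```python
from consig import (PipelineConfig, SimulationConfig, score_recovery,
                    signature_from_datasets, simulate_multistudy)

datasets, truth, annotation = simulate_multistudy(SimulationConfig(seed=42))
result = signature_from_datasets(datasets, annotation, PipelineConfig(seed=42))
print(len(result.signature), result.signature.n_up, result.signature.n_down)
print(score_recovery(result.signature, truth))
```

prints

```
198 106 92
(0.985, 0.00505..., 1.0)
```

i.e. the five simulated studies (2000 genes, 200 planted effects) yield a
198-gene signature that recovers 98.5% of the planted genes, with 0.5% of
signature members not planted and every recovered direction correct.
Continuing with classification (`examples/02_classification.py`): mean
10-fold CV accuracy 1.000 on the training pool and 1.000 on the 32 held-out
samples. The `examples/` scripts walk through each capability and explain
the printed numbers; `consig --help` exposes the same pipeline as
`simulate`, `de`, `consensus`, `classify`, `qc`, `enrich` and `run-all`
subcommands over TSV/GMT files.

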