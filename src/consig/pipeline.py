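"""End-to-end orchestration: DE -> collapse -> consensus -> signature -> reports.

This is the programmatic backbone behind the command-line interface; each
stage is a thin call into the corresponding module so library users can run
any prefix of the pipeline themselves.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (
    BatchAdjuster,
    ClassifierReport,
    merge_on_signature,
    stratified_split,
    tune_train_evaluate,
)
from .consensus import SignatureTable, build_consensus, extract_signature
from .de import DETable, collapse_probes_to_genes, run_dataset_de
from .enrich import enrich_signature
from .errors import StageError
from .io import (
    ExpressionDataset,
    GeneSetCollection,
    ProbeAnnotation,
    write_signature_table,
)
from .qc import QCReport, qc_report


@dataclass
class PipelineConfig:
    """Tunable thresholds for the full pipeline.

    fc_threshold: linear fold-change cut for calling a DEG (1.5).
    cdr_threshold: minimum Common Dataset Ratio for the signature (0.6).
    prior_df: prior degrees of freedom for the moderated t (4).
    top_fraction: fraction of a ranked list called "most significant" (0.05).
    test_fraction: held-out fraction for classification (0.25).
    folds: cross-validation folds (10).
    cdr_denominator: "total" or "measured" studies in the CDR denominator.
    """

    fc_threshold: float = 1.5
    cdr_threshold: float = 0.6
    prior_df: float = 4.0
    top_fraction: float = 0.05
    test_fraction: float = 0.25
    folds: int = 10
    seed: int = 0
    cdr_denominator: str = "total"

    def __post_init__(self):
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1 (linear scale)")
        if not 0 < self.cdr_threshold <= 1:
            raise ValueError("cdr_threshold must be in (0, 1]")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        if self.cdr_denominator not in ("total", "measured"):
            raise ValueError("cdr_denominator must be 'total' or 'measured'")


@dataclass
class PipelineResult:
    """Artifacts of one full run."""

    gene_tables: list[DETable]
    consensus: pd.DataFrame
    signature: SignatureTable
    classifier: ClassifierReport | None = None
    qc: QCReport | None = None
    enrichment: pd.DataFrame | None = None


def signature_from_datasets(
    datasets: list[ExpressionDataset],
    annotation: ProbeAnnotation,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """DE, probe collapse, consensus and signature extraction for K studies."""
    config = config or PipelineConfig()
    try:
        gene_tables = []
        for ds in datasets:
            probe_table = run_dataset_de(
                ds,
                fc_threshold=config.fc_threshold,
                prior_df=config.prior_df,
                annotation=annotation,
            )
            gene_tables.append(collapse_probes_to_genes(probe_table))
    except Exception as exc:
        raise StageError("de", str(exc)) from exc
    try:
        consensus = build_consensus(
            gene_tables,
            cdr_threshold=config.cdr_threshold,
            cdr_denominator=config.cdr_denominator,
        )
        signature = extract_signature(
            consensus,
            cdr_threshold=config.cdr_threshold,
            fc_threshold=config.fc_threshold,
        )
    except Exception as exc:
        raise StageError("consensus", str(exc)) from exc
    return PipelineResult(
        gene_tables=gene_tables, consensus=consensus, signature=signature
    )


def classify_with_signature(
    datasets: list[ExpressionDataset],
    result: PipelineResult,
    config: PipelineConfig,
) -> ClassifierReport:
    """Merge on the signature, batch-adjust (fit on train), tune and test."""
    try:
        merged = merge_on_signature(
            datasets, result.signature, gene_tables=result.gene_tables
        )
        train, test = stratified_split(
            merged, test_fraction=config.test_fraction, seed=config.seed
        )
        adjuster = BatchAdjuster().fit(train)
        report = tune_train_evaluate(
            adjuster.transform(train),
            adjuster.transform(test),
            folds=config.folds,
            seed=config.seed,
        )
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc
    result.classifier = report
    return report


def qc_with_signature(
    datasets: list[ExpressionDataset],
    result: PipelineResult,
) -> QCReport:
    """Clustering/PCA QC on the batch-adjusted signature-gene matrix."""
    try:
        merged = merge_on_signature(
            datasets, result.signature, gene_tables=result.gene_tables
        )
        adjusted = BatchAdjuster().fit(merged).transform(merged)
        report = qc_report(adjusted.values.T, adjusted.sample_class)
    except Exception as exc:
        raise StageError("qc", str(exc)) from exc
    result.qc = report
    return report


def enrich_result(
    result: PipelineResult, sets: GeneSetCollection
) -> pd.DataFrame:
    """Over-representation of the signature against gene sets.

    The universe is the union of genes measured in any analyzed study.
    """
    try:
        universe = set().union(*(set(t.table.index) for t in result.gene_tables))
        table = enrich_signature(result.signature, sets, universe)
    except Exception as exc:
        raise StageError("enrich", str(exc)) from exc
    result.enrichment = table
    return table


def write_artifacts(
    result: PipelineResult, outdir, config: PipelineConfig
) -> dict[str, str]:
    """Write all TSV/JSON artifacts plus a reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for table in result.gene_tables:
        path = outdir / f"de_{table.dataset_id}.tsv"
        table.to_tsv(path)
        written[f"de_{table.dataset_id}"] = str(path)
    cons_path = outdir / "consensus.tsv"
    result.consensus.drop(columns="percent_ranks").to_csv(
        cons_path, sep="\t", index=False, float_format="%.10g"
    )
    written["consensus"] = str(cons_path)
    sig_path = outdir / "signature.tsv"
    write_signature_table(result.signature, sig_path)
    written["signature"] = str(sig_path)
    if result.classifier is not None:
        path = outdir / "classifier.json"
        path.write_text(json.dumps(result.classifier.to_dict(), indent=2) + "\n")
        written["classifier"] = str(path)
    if result.qc is not None:
        path = outdir / "qc.json"
        path.write_text(json.dumps(result.qc.to_dict(), indent=2) + "\n")
        written["qc"] = str(path)
    if result.enrichment is not None:
        path = outdir / "enrichment.tsv"
        result.enrichment.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written["enrichment"] = str(path)
    manifest = {
        "tool": "consig",
        "version": __version__,
        "config": asdict(config),
        "artifacts": sorted(written),
    }
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2) + "\n")
    written["manifest"] = str(man_path)
    return written
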