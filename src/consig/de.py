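"""Per-study differential expression with a simplified moderated t-test.

Fold changes are case-minus-control differences of group means on the log2
scale.  The test statistic shrinks each probe's pooled variance toward the
study-wide mean pooled variance with a fixed prior degree of freedom — an
empirical-Bayes moderation in the spirit of limma's, but with fixed
hyperparameters so the result is deterministic and reduces exactly to the
classical pooled two-sample t-test when ``prior_df = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateVarianceError,
    EmptyAnalysisError,
    InsufficientDataError,
    StructuralError,
)
from .io import UNMAPPED, ExpressionDataset, ProbeAnnotation

DE_COLUMNS = [
    "gene_symbol",
    "log2fc",
    "fc_linear",
    "t_stat",
    "p_value",
    "q_value",
    "direction",
    "passes_fc",
    "n_case",
    "n_control",
]


@dataclass
class DETable:
    """Differential-expression statistics for one study.

    ``table`` is indexed by probe ID (``level="probe"``) or gene symbol
    (``level="gene"``) with the columns in :data:`DE_COLUMNS`.
    ``total_transcripts`` is the number of tested records — the denominator
    of the percent-significance rank.
    """

    dataset_id: str
    level: str  # "probe" | "gene"
    table: pd.DataFrame

    def __post_init__(self):
        if self.level not in ("probe", "gene"):
            raise StructuralError(f"unknown DE level {self.level!r}")
        if self.table.index.has_duplicates:
            raise StructuralError(f"{self.dataset_id}: duplicate IDs in DE table")

    @property
    def total_transcripts(self) -> int:
        return int(len(self.table))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label=self.level, float_format="%.10g")


def log2_fold_change(case_values, control_values) -> float:
    """mean(case) - mean(control) on the log2 scale, missing excluded."""
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    case = case[np.isfinite(case)]
    control = control[np.isfinite(control)]
    if case.size == 0 or control.size == 0:
        raise InsufficientDataError("a group has no non-missing values")
    return float(case.mean() - control.mean())


def moderated_t_test(
    case_values, control_values, prior_df: float = 4.0, prior_var: float = 1.0
) -> tuple[float, float]:
    """Two-sample t-test with variance shrinkage toward a prior.

    The pooled variance s2 with d = n1+n2-2 degrees of freedom is shrunk to
    ``(d0*s0 + d*s2)/(d0 + d)``; the statistic is referred to a t
    distribution with ``d0 + d`` degrees of freedom.  ``prior_df = 0``
    recovers the classical pooled t-test.
    """
    if prior_df < 0:
        raise ValueError("prior_df must be >= 0")
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    case = case[np.isfinite(case)]
    control = control[np.isfinite(control)]
    n1, n2 = case.size, control.size
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need >= 2 non-missing values per group")
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / d
    s2_tilde = (prior_df * prior_var + d * s2) / (prior_df + d)
    if s2_tilde <= 0:
        raise DegenerateVarianceError("shrunken variance is zero")
    t = (case.mean() - control.mean()) / np.sqrt(s2_tilde * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df=prior_df + d)
    return float(t), float(min(max(p, np.finfo(float).tiny), 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction(log2fc: float) -> str:
    if log2fc > 0:
        return "up"
    if log2fc < 0:
        return "down"
    return "flat"


def run_dataset_de(
    dataset: ExpressionDataset,
    fc_threshold: float = 1.5,
    prior_df: float = 4.0,
    annotation: ProbeAnnotation | None = None,
) -> DETable:
    """Probe-level DE table for one study.

    Probes need >= 2 complete observations per group to be tested.  The
    shrinkage target ``s0^2`` is the mean of the per-probe pooled variances
    across all tested probes.  BH adjustment is applied within the study at
    the probe level.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold is on the linear scale and must be >= 1")
    case_mat = dataset.values[dataset.case_columns()].to_numpy(dtype=float)
    ctrl_mat = dataset.values[dataset.control_columns()].to_numpy(dtype=float)

    n1 = np.isfinite(case_mat).sum(axis=1)
    n2 = np.isfinite(ctrl_mat).sum(axis=1)
    testable = (n1 >= 2) & (n2 >= 2)
    if not testable.any():
        raise EmptyAnalysisError(
            f"{dataset.dataset_id}: no probe has >= 2 complete observations per group"
        )

    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(case_mat, axis=1)
        m2 = np.nanmean(ctrl_mat, axis=1)
        v1 = np.nanvar(case_mat, axis=1, ddof=1)
        v2 = np.nanvar(ctrl_mat, axis=1, ddof=1)

    idx = np.where(testable)[0]
    n1, n2, m1, m2, v1, v2 = (a[idx] for a in (n1, n2, m1, m2, v1, v2))
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    s0_sq = float(s2.mean())

    s2_tilde = (prior_df * s0_sq + d * s2) / (prior_df + d)
    log2fc = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / np.sqrt(s2_tilde * (1 / n1 + 1 / n2))
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df=prior_df + d)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_adjust(p)

    probes = dataset.values.index[idx]
    symbols = (
        [annotation.symbol(pid) for pid in probes]
        if annotation is not None
        else [UNMAPPED] * len(probes)
    )
    log2_cut = np.log2(fc_threshold)
    table = pd.DataFrame(
        {
            "gene_symbol": symbols,
            "log2fc": log2fc,
            "fc_linear": 2.0 ** np.abs(log2fc),
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "direction": [_direction(x) for x in log2fc],
            "passes_fc": np.abs(log2fc) >= log2_cut,
            "n_case": n1.astype(int),
            "n_control": n2.astype(int),
        },
        index=probes,
    )
    return DETable(dataset_id=dataset.dataset_id, level="probe", table=table)


def collapse_probes_to_genes(
    table: DETable, annotation: ProbeAnnotation | None = None
) -> DETable:
    """Reduce a probe-level table to one record per gene.

    For each gene the probe with the largest |log2fc| is kept; ties break
    by smaller p-value, then lexicographically smallest probe ID.  Probes
    without a symbol (``unmapped``) are dropped.  Idempotent on gene-level
    tables.
    """
    if table.level == "gene":
        return table
    frame = table.table.copy()
    if annotation is not None:
        frame["gene_symbol"] = [annotation.symbol(pid) for pid in frame.index]
    unmapped_frac = (frame["gene_symbol"] == UNMAPPED).mean() if len(frame) else 0.0
    if unmapped_frac > 0.5:
        warnings.warn(
            f"{table.dataset_id}: {unmapped_frac:.0%} of probes lack a gene symbol",
            stacklevel=2,
        )
    frame = frame[frame["gene_symbol"] != UNMAPPED]
    if frame.empty:
        return DETable(
            dataset_id=table.dataset_id,
            level="gene",
            table=frame.set_index("gene_symbol"),
        )
    frame = frame.reset_index(names="probe_id")
    frame["abs_fc"] = frame["log2fc"].abs()
    frame = frame.sort_values(
        ["gene_symbol", "abs_fc", "p_value", "probe_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = frame.groupby("gene_symbol", sort=True).head(1)
    best = best.set_index("gene_symbol")[
        [c for c in DE_COLUMNS if c != "gene_symbol"] + ["probe_id"]
    ]
    best.insert(0, "gene_symbol", best.index)
    return DETable(dataset_id=table.dataset_id, level="gene", table=best)
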