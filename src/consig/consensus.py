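"""Cross-study consensus: CDR filtering, average fold change, percent ranks.

The Common Dataset Ratio (CDR) of a gene is the fraction of the analyzed
studies in which it is a direction-consistent differentially expressed gene
(fold-change criterion met, same sign).  With five studies, CDR >= 0.6 means
"DEG in at least 3 of 5".  The denominator is the total number of studies by
default — a gene absent from a small platform still needs 3 passing studies —
switchable to the number of studies where the gene was measured.

Within each study every tested gene receives a percent significance rank:
100 x (1-based position in the ascending p-value ordering) / (total genes
tested in that study), with midranks for ties.  A gene's average percent
rank over the studies that measured it summarizes its consensus statistical
strength; the average log2 fold change summarizes its consensus effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .de import DETable
from .errors import StructuralError

CONSENSUS_COLUMNS = [
    "gene_symbol",
    "n_datasets_total",
    "n_measured",
    "n_pass_up",
    "n_pass_down",
    "cdr",
    "consensus_direction",
    "avg_log2fc",
    "min_p",
    "avg_percent_rank",
]


def compute_cdr(
    pass_flags_by_direction,
    k_total: int,
    cdr_threshold: float = 0.6,
) -> tuple[float, str]:
    """CDR and consensus direction from per-study pass flags.

    ``pass_flags_by_direction`` holds one flag per study in
    ``{"up", "down", "none"}``.  CDR = max(#up, #down) / k_total and the
    direction is the majority sign.  A gene qualifying independently in both
    directions (both counts >= ceil(cdr_threshold * k_total)), or tied with
    equal non-zero counts, is direction-inconsistent -> ``"conflict"``.
    No passing study at all -> ``"none"``.
    """
    if k_total < 1:
        raise ValueError("k_total must be >= 1")
    flags = list(pass_flags_by_direction)
    if len(flags) > k_total:
        raise ValueError("more flags than datasets")
    bad = set(flags) - {"up", "down", "none"}
    if bad:
        raise ValueError(f"unknown flags {sorted(bad)!r}")
    n_up = flags.count("up")
    n_down = flags.count("down")
    cdr = max(n_up, n_down) / k_total
    need = math.ceil(cdr_threshold * k_total)
    if n_up == 0 and n_down == 0:
        direction = "none"
    elif n_up >= need and n_down >= need:
        direction = "conflict"
    elif n_up == n_down:
        direction = "conflict"
    elif n_up > n_down:
        direction = "up"
    else:
        direction = "down"
    return cdr, direction


def percent_rank(position: int, total: int) -> float:
    """100 x position / total, the percent significance rank.

    ``position`` is the 1-based rank in the ascending p-value ordering.
    Full precision is returned; outputs round to three decimals.
    """
    if not 1 <= position <= total:
        raise ValueError(f"position {position} out of range [1, {total}]")
    return 100.0 * position / total


def top_fraction_count(total: int, fraction: float) -> int:
    """Number of genes in the top ``fraction`` of a ranked list (floor)."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return math.floor(total * fraction)


def build_consensus(
    tables: list[DETable],
    cdr_threshold: float = 0.6,
    cdr_denominator: str = "total",
    rank_on: str = "p_value",
) -> pd.DataFrame:
    """Aggregate gene-level DE tables into per-gene consensus records.

    Returns one row per gene in the union of the tables, with CDR,
    consensus direction, average log2FC over the studies where measured,
    minimum p, and the average percent significance rank (midranks for
    tied p-values).  ``rank_on`` may be ``"p_value"`` or ``"q_value"``.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 gene-level tables")
    if cdr_denominator not in ("total", "measured"):
        raise ValueError("cdr_denominator must be 'total' or 'measured'")
    if rank_on not in ("p_value", "q_value"):
        raise ValueError("rank_on must be 'p_value' or 'q_value'")
    for t in tables:
        if t.level != "gene":
            raise StructuralError(f"{t.dataset_id}: table is not gene-level")
        if t.table.index.has_duplicates:
            raise StructuralError(f"{t.dataset_id}: duplicate genes in table")

    k_total = len(tables)
    # Per-study percent ranks over that study's full tested gene list.
    pct = {}
    for t in tables:
        ranks = rankdata(t.table[rank_on].to_numpy(), method="average")
        pct[t.dataset_id] = pd.Series(
            100.0 * ranks / t.total_transcripts, index=t.table.index
        )

    genes = sorted(set().union(*(t.table.index for t in tables)))
    records = []
    for gene in genes:
        flags, fcs, ps = [], [], []
        pranks: dict[str, float] = {}
        for t in tables:
            if gene not in t.table.index:
                continue
            row = t.table.loc[gene]
            flags.append(row["direction"] if row["passes_fc"] else "none")
            fcs.append(float(row["log2fc"]))
            ps.append(float(row["p_value"]))
            pranks[t.dataset_id] = float(pct[t.dataset_id].loc[gene])
        n_measured = len(fcs)
        denom = k_total if cdr_denominator == "total" else n_measured
        cdr, direction = compute_cdr(flags, denom, cdr_threshold)
        records.append(
            {
                "gene_symbol": gene,
                "n_datasets_total": k_total,
                "n_measured": n_measured,
                "n_pass_up": flags.count("up"),
                "n_pass_down": flags.count("down"),
                "cdr": cdr,
                "consensus_direction": direction,
                "avg_log2fc": float(np.mean(fcs)),
                "min_p": float(np.min(ps)),
                "percent_ranks": pranks,
                "avg_percent_rank": float(np.mean(list(pranks.values()))),
            }
        )
    return pd.DataFrame(records, columns=CONSENSUS_COLUMNS + ["percent_ranks"])


@dataclass
class SignatureTable:
    """The ordered consensus signature passing the CDR and FC filters."""

    records: pd.DataFrame
    cdr_threshold: float = 0.6
    fc_threshold: float = 1.5
    n_up: int = field(init=False)
    n_down: int = field(init=False)

    def __post_init__(self):
        self.n_up = int((self.records["consensus_direction"] == "up").sum())
        self.n_down = int((self.records["consensus_direction"] == "down").sum())

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> list[str]:
        return list(self.records["gene_symbol"])

    def directions(self) -> dict[str, str]:
        return dict(
            zip(self.records["gene_symbol"], self.records["consensus_direction"])
        )

    def to_frame(self) -> pd.DataFrame:
        frame = self.records.copy()
        frame["direction"] = frame["consensus_direction"]
        return frame


def extract_signature(
    records: pd.DataFrame,
    cdr_threshold: float = 0.6,
    fc_threshold: float = 1.5,
) -> SignatureTable:
    """Filter consensus records to the signature and order them.

    Keeps genes with CDR >= threshold and an unambiguous direction, sorted
    by |avg_log2fc| descending; ties break by ascending average percent
    rank, then gene symbol.
    """
    keep = records[
        (records["cdr"] >= cdr_threshold)
        & records["consensus_direction"].isin(["up", "down"])
    ].copy()
    keep["_abs_fc"] = keep["avg_log2fc"].abs()
    keep = keep.sort_values(
        ["_abs_fc", "avg_percent_rank", "gene_symbol"],
        ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns="_abs_fc")
    keep = keep.reset_index(drop=True)
    return SignatureTable(
        records=keep, cdr_threshold=cdr_threshold, fc_threshold=fc_threshold
    )


def compare_signatures(
    sig: SignatureTable, external: list[tuple[str, str]]
) -> dict:
    """Set overlap between the signature and an external (gene, direction) list.

    Reports shared genes overall and the direction-concordant subset.
    """
    if not external:
        raise ValueError("external list is empty")
    ours = sig.directions()
    theirs = {str(g).upper(): d for g, d in external}
    shared = sorted(set(ours) & set(theirs))
    concordant = sorted(g for g in shared if ours[g] == theirs[g])
    return {
        "n_signature": len(ours),
        "n_external": len(theirs),
        "n_shared": len(shared),
        "n_concordant": len(concordant),
        "shared_genes": shared,
        "concordant_genes": concordant,
    }
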