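"""Gene-set over-representation analysis by the hypergeometric tail test.

For a signature of n genes drawn from a measured universe of N genes, the
overlap k with a gene set of size K is scored by P(X >= k) for
X ~ Hypergeometric(N, K, n), with Benjamini-Hochberg adjustment across the
tested sets.  The universe should be the genes the experiment could have
detected — by default the union of genes measured in any analyzed study.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .consensus import SignatureTable
from .de import bh_adjust
from .io import GeneSetCollection

ENRICH_COLUMNS = [
    "set_name",
    "universe_size",
    "set_size",
    "signature_size",
    "overlap",
    "p_value",
    "q_value",
    "overlap_genes",
]


def hypergeometric_tail(N: int, K_set: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K_set, n)."""
    if not (0 <= k <= min(K_set, n) <= N) or K_set > N or n > N:
        raise ValueError(
            f"inconsistent counts N={N}, K_set={K_set}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K_set, n))


def enrich_signature(
    sig: SignatureTable,
    sets: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """One over-representation record per gene set, BH-adjusted.

    Set members outside the universe are ignored; sets with no member in
    the universe are skipped.  Raises when the universe does not contain
    the signature genes.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise ValueError("empty gene universe")
    sig_genes = {g.upper() for g in sig.genes}
    if not sig_genes <= universe:
        missing = sorted(sig_genes - universe)[:5]
        raise ValueError(f"signature genes outside universe, e.g. {missing}")
    N, n = len(universe), len(sig_genes)
    rows = []
    for name, _desc, members in sets:
        members_in = members & universe
        if not members_in:
            continue
        overlap = sorted(members_in & sig_genes)
        k = len(overlap)
        rows.append(
            {
                "set_name": name,
                "universe_size": N,
                "set_size": len(members_in),
                "signature_size": n,
                "overlap": k,
                "p_value": hypergeometric_tail(N, len(members_in), n, k),
                "overlap_genes": ",".join(overlap),
            }
        )
    frame = pd.DataFrame(rows, columns=[c for c in ENRICH_COLUMNS if c != "q_value"])
    if len(frame):
        frame.insert(6, "q_value", bh_adjust(frame["p_value"].to_numpy()))
        frame = frame.sort_values(
            ["p_value", "set_name"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        frame.insert(6, "q_value", [])
    return frame
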