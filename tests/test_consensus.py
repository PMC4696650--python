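import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from consig import (
    build_consensus,
    compare_signatures,
    compute_cdr,
    extract_signature,
    percent_rank,
    top_fraction_count,
)
from consig.de import DETable


def cdr_oracle(flags, k_total, threshold=0.6):
    """Exhaustive-count reference for CDR and consensus direction."""
    n_up = sum(1 for f in flags if f == "up")
    n_down = sum(1 for f in flags if f == "down")
    cdr = max(n_up, n_down) / k_total
    need = math.ceil(threshold * k_total)
    if n_up == n_down == 0:
        direction = "none"
    elif (n_up >= need and n_down >= need) or n_up == n_down:
        direction = "conflict"
    else:
        direction = "up" if n_up > n_down else "down"
    return cdr, direction


class TestComputeCdr:
    def test_three_of_five_up_gives_cdr_point_six(self):
        assert compute_cdr(["up", "up", "up", "none", "none"], 5) == (0.6, "up")

    def test_unanimous(self):
        assert compute_cdr(["up"] * 5, 5) == (1.0, "up")

    def test_mixed_directions_majority_wins(self):
        assert compute_cdr(["up", "up", "down"], 5) == (0.4, "up")

    def test_matches_oracle_on_all_flag_assignments(self):
        for flags in itertools.product(["up", "down", "none"], repeat=5):
            assert compute_cdr(list(flags), 5) == cdr_oracle(flags, 5)

    def test_invalid_flag_rejected(self):
        with pytest.raises(ValueError):
            compute_cdr(["sideways"], 5)


class TestPercentRank:
    def test_fifth_of_22283_rounds_to_0_022(self):
        assert round(percent_rank(5, 22283), 3) == 0.022

    def test_last_position_is_100(self):
        assert percent_rank(22283, 22283) == 100.0

    def test_first_of_100_is_1(self):
        assert percent_rank(1, 100) == 1.0

    @given(st.integers(min_value=2, max_value=10_000))
    def test_strictly_increasing_in_position(self, total):
        ranks = [percent_rank(p, total) for p in (1, total // 2 + 1, total)]
        assert ranks[0] < ranks[1] <= ranks[2]

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            percent_rank(0, 10)
        with pytest.raises(ValueError):
            percent_rank(11, 10)


class TestTopFractionCount:
    @pytest.mark.parametrize(
        "total, fraction, expected",
        [(22283, 0.05, 1114), (100, 0.05, 5), (19, 0.05, 0)],
    )
    def test_floor_of_product(self, total, fraction, expected):
        assert top_fraction_count(total, fraction) == expected


def _gene_table(dataset_id, rows):
    frame = pd.DataFrame(rows).set_index("gene_symbol", drop=False)
    frame.index.name = None
    return DETable(dataset_id=dataset_id, level="gene", table=frame)


def _row(gene, log2fc, p, passes):
    return {
        "gene_symbol": gene,
        "log2fc": log2fc,
        "fc_linear": 2.0 ** abs(log2fc),
        "t_stat": 0.0,
        "p_value": p,
        "q_value": min(1.0, p * 2),
        "direction": "up" if log2fc > 0 else ("down" if log2fc < 0 else "flat"),
        "passes_fc": passes,
        "n_case": 3,
        "n_control": 3,
    }


class TestBuildConsensus:
    def test_hand_computed_consensus_record(self):
        """Up-passing in 3 of 5 tables; measured in all 5."""
        fcs = [1.0, 1.2, 0.8, 0.1, 0.2]
        tables = [
            _gene_table(
                f"DS{i + 1}",
                [
                    _row("TARGET", fc, 0.01, fc >= 0.585),
                    _row("FILLER", 0.05, 0.5, False),
                ],
            )
            for i, fc in enumerate(fcs)
        ]
        records = build_consensus(tables, cdr_threshold=0.6)
        rec = records.set_index("gene_symbol").loc["TARGET"]
        assert rec["cdr"] == pytest.approx(0.6)
        assert rec["consensus_direction"] == "up"
        assert rec["avg_log2fc"] == pytest.approx(np.mean(fcs))
        assert rec["n_measured"] == 5
        assert rec["min_p"] == pytest.approx(0.01)
        # TARGET has the smaller p in every table of 2 genes -> rank 1 of 2
        assert rec["avg_percent_rank"] == pytest.approx(50.0)

    def test_gene_on_small_platforms_only_diluted_by_total_denominator(self):
        tables = [
            _gene_table("DS1", [_row("A", 1.0, 0.01, True)]),
            _gene_table("DS2", [_row("A", 1.0, 0.01, True)]),
            _gene_table(
                "DS3", [_row("A", 1.0, 0.01, True), _row("B", 2.0, 0.001, True)]
            ),
            _gene_table("DS4", [_row("B", 2.0, 0.001, True)]),
            _gene_table("DS5", [_row("B", 2.0, 0.001, True)]),
        ]
        records = build_consensus(tables).set_index("gene_symbol")
        # B passes in 3 datasets -> kept; with denominator "measured" it
        # would be 3/3, with "total" it is 3/5.
        assert records.loc["B", "cdr"] == pytest.approx(0.6)
        measured = build_consensus(tables, cdr_denominator="measured")
        assert measured.set_index("gene_symbol").loc["B", "cdr"] == pytest.approx(1.0)

    def test_identical_stats_average_to_common_value(self):
        tables = [
            _gene_table(f"DS{i}", [_row("A", 0.9, 0.02, True)]) for i in range(3)
        ]
        rec = build_consensus(tables).iloc[0]
        assert rec["avg_log2fc"] == pytest.approx(0.9)
        assert rec["avg_percent_rank"] == pytest.approx(100.0)

    def test_duplicate_gene_in_one_table_rejected(self):
        frame = pd.DataFrame([_row("A", 1.0, 0.01, True)] * 2)
        frame.index = ["A", "A"]
        with pytest.raises(Exception):
            DETable(dataset_id="DS1", level="gene", table=frame)


class TestExtractSignature:
    def _records(self, cdrs):
        rows = []
        for i, cdr in enumerate(cdrs):
            rows.append(
                {
                    "gene_symbol": f"G{i}",
                    "n_datasets_total": 5,
                    "n_measured": 5,
                    "n_pass_up": int(cdr * 5),
                    "n_pass_down": 0,
                    "cdr": cdr,
                    "consensus_direction": "up" if cdr > 0 else "none",
                    "avg_log2fc": 1.0 + i * 0.1,
                    "min_p": 0.01,
                    "avg_percent_rank": 5.0,
                }
            )
        from consig.consensus import CONSENSUS_COLUMNS

        return pd.DataFrame(rows, columns=CONSENSUS_COLUMNS)

    def test_filter_keeps_cdr_at_or_above_threshold(self):
        sig = extract_signature(self._records([0.6, 0.4, 1.0]), cdr_threshold=0.6)
        assert len(sig) == 2
        assert set(sig.genes) == {"G0", "G2"}

    def test_empty_input_gives_empty_signature(self):
        sig = extract_signature(self._records([]), cdr_threshold=0.6)
        assert len(sig) == 0

    def test_ordering_by_abs_avg_fold_change(self):
        records = self._records([1.0, 1.0, 1.0])
        records.loc[1, "avg_log2fc"] = -9.0
        sig = extract_signature(records)
        assert sig.genes[0] == "G1"

    def test_size_non_increasing_in_cdr_threshold(self, pipeline_default):
        _, _, _, result = pipeline_default
        sizes = [
            len(extract_signature(result.consensus, cdr_threshold=t))
            for t in (0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestCompareSignatures:
    def _sig(self, pairs):
        rows = [
            {
                "gene_symbol": g,
                "n_datasets_total": 5,
                "n_measured": 5,
                "n_pass_up": 3,
                "n_pass_down": 0,
                "cdr": 0.6,
                "consensus_direction": d,
                "avg_log2fc": 1.0,
                "min_p": 0.01,
                "avg_percent_rank": 1.0,
            }
            for g, d in pairs
        ]
        return extract_signature(pd.DataFrame(rows))

    def test_identical_lists_fully_concordant(self):
        sig = self._sig([("A", "up"), ("B", "down")])
        report = compare_signatures(sig, [("A", "up"), ("B", "down")])
        assert report["n_shared"] == 2 and report["n_concordant"] == 2

    def test_disjoint_lists(self):
        sig = self._sig([("A", "up")])
        report = compare_signatures(sig, [("Z", "up")])
        assert report["n_shared"] == 0 and report["n_concordant"] == 0

    def test_shared_but_discordant(self):
        sig = self._sig([("A", "up"), ("B", "down")])
        report = compare_signatures(sig, [("A", "down"), ("C", "up")])
        assert report["n_shared"] == 1 and report["n_concordant"] == 0
        assert report["shared_genes"] == ["A"]
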