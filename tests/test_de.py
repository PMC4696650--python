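import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from consig import (
    bh_adjust,
    collapse_probes_to_genes,
    log2_fold_change,
    moderated_t_test,
    run_dataset_de,
)
from consig.de import DETable
from consig.errors import InsufficientDataError
from consig.io import ProbeAnnotation

from conftest import make_dataset


def bh_brute_force(p):
    """O(m^2) step-up oracle: q_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestLog2FoldChange:
    def test_difference_of_group_means(self):
        assert log2_fold_change([9.0, 9.0], [8.0, 8.0]) == pytest.approx(1.0)

    def test_identical_groups_give_zero(self):
        assert log2_fold_change([5.0, 6.0], [5.0, 6.0]) == 0.0

    def test_missing_values_excluded(self):
        got = log2_fold_change([1, 2, 3], [4, np.nan, 6])
        assert got == pytest.approx(2.0 - 5.0)

    def test_all_missing_group_is_error(self):
        with pytest.raises(InsufficientDataError):
            log2_fold_change([np.nan, np.nan], [1.0, 2.0])


class TestModeratedT:
    def test_zero_prior_reduces_to_pooled_t(self, rng):
        for _ in range(25):
            a = rng.normal(0, 1, size=rng.integers(3, 9))
            b = rng.normal(0.5, 1.2, size=rng.integers(3, 9))
            t, p = moderated_t_test(a, b, prior_df=0.0, prior_var=1.0)
            ref_t, ref_p = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref_t, abs=1e-10)
            assert p == pytest.approx(ref_p, abs=1e-10)

    def test_identical_means_give_t_zero_p_one(self):
        t, p = moderated_t_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0], prior_df=4.0)
        assert t == 0.0 and p == 1.0

    def test_matches_independent_formula_evaluation(self):
        case, control = [10.0, 11.0, 12.0], [8.0, 9.0, 10.0]
        d0, s0_sq = 4.0, 1.0
        # independent evaluation of the shrunken-variance t
        s2 = (np.var(case, ddof=1) * 2 + np.var(control, ddof=1) * 2) / 4
        s2_t = (d0 * s0_sq + 4 * s2) / (d0 + 4)
        exp_t = (np.mean(case) - np.mean(control)) / math.sqrt(s2_t * (2 / 3))
        exp_p = 2 * stats.t.sf(abs(exp_t), df=8)
        t, p = moderated_t_test(case, control, prior_df=d0, prior_var=s0_sq)
        assert t == pytest.approx(exp_t, abs=1e-12)
        assert p == pytest.approx(exp_p, abs=1e-12)


class TestBHAdjust:
    def test_worked_examples(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_adjust([0.05, 0.05, 0.05]), [0.05] * 3)

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 51))
            assert np.allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=40)
    )
    def test_monotone_along_sorted_p(self, p):
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12) and np.all(q <= 1.0)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan]])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


def _two_probe_dataset(diff_pass, diff_fail):
    base = 8.0
    values = {
        "pA": [base + diff_pass] * 3 + [base] * 3,
        "pB": [base + diff_fail] * 3 + [base] * 3,
    }
    # add tiny within-group spread so variances are non-degenerate
    values = {
        k: [v + off for v, off in zip(vals, [0, 0.05, -0.05] * 2)]
        for k, vals in values.items()
    }
    return make_dataset(values, ["case"] * 3 + ["control"] * 3)


class TestRunDatasetDE:
    def test_fc_threshold_on_log2_scale(self):
        ds = _two_probe_dataset(diff_pass=1.2, diff_fail=0.5)
        table = run_dataset_de(ds, fc_threshold=1.5)
        assert bool(table.table.loc["pA", "passes_fc"]) is True  # 1.2 >= log2 1.5
        assert bool(table.table.loc["pB", "passes_fc"]) is False  # 0.5 < 0.585
        assert table.total_transcripts == 2
        assert (table.table["q_value"] >= table.table["p_value"] - 1e-12).all()

    def test_pass_count_non_increasing_in_threshold(self, rng):
        vals = {
            f"p{i}": list(rng.normal(8 + (i % 5) * 0.4, 0.3, 6)) for i in range(40)
        }
        ds = make_dataset(vals, ["case"] * 3 + ["control"] * 3)
        counts = [
            int(run_dataset_de(ds, fc_threshold=f).table["passes_fc"].sum())
            for f in (1.0, 1.3, 1.5, 2.0, 3.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_planted_probes_recovered(self, rng):
        """100 planted probes at |log2fc|=1.5, sd 0.5, n=10/10: >= 90 pass."""
        n_planted, n_null = 100, 200
        values = {}
        for i in range(n_planted):
            eff = 1.5 if i % 2 == 0 else -1.5
            values[f"sig{i}"] = list(
                np.concatenate(
                    [rng.normal(8 + eff, 0.5, 10), rng.normal(8, 0.5, 10)]
                )
            )
        for i in range(n_null):
            values[f"null{i}"] = list(rng.normal(8, 0.5, 20))
        ds = make_dataset(values, ["case"] * 10 + ["control"] * 10)
        table = run_dataset_de(ds, fc_threshold=1.5).table
        planted_pass = table.loc[
            [f"sig{i}" for i in range(n_planted)], "passes_fc"
        ].sum()
        assert planted_pass >= 90


class TestCollapse:
    annotation = ProbeAnnotation(
        {"p1": "GENEA", "p2": "GENEA", "p3": "GENEB", "p4": ""}
    )

    def _probe_table(self, rows):
        import pandas as pd

        frame = pd.DataFrame(rows).set_index("probe")
        return DETable(dataset_id="DS", level="probe", table=frame)

    def test_highest_abs_fold_change_kept(self):
        table = self._probe_table(
            [
                {"probe": "p1", "gene_symbol": "GENEA", "log2fc": 1.1,
                 "fc_linear": 2 ** 1.1, "t_stat": 3.0, "p_value": 0.01,
                 "q_value": 0.02, "direction": "up", "passes_fc": True,
                 "n_case": 3, "n_control": 3},
                {"probe": "p2", "gene_symbol": "GENEA", "log2fc": 0.7,
                 "fc_linear": 2 ** 0.7, "t_stat": 2.0, "p_value": 0.001,
                 "q_value": 0.002, "direction": "up", "passes_fc": True,
                 "n_case": 3, "n_control": 3},
            ]
        )
        gene = collapse_probes_to_genes(table)
        assert gene.level == "gene"
        assert gene.table.loc["GENEA", "log2fc"] == pytest.approx(1.1)
        assert gene.table.loc["GENEA", "probe_id"] == "p1"

    def test_tie_broken_by_smaller_p(self):
        rows = []
        for probe, p in (("p1", 0.04), ("p2", 0.01)):
            rows.append(
                {"probe": probe, "gene_symbol": "GENEA", "log2fc": 1.0,
                 "fc_linear": 2.0, "t_stat": 2.0, "p_value": p,
                 "q_value": p, "direction": "up", "passes_fc": True,
                 "n_case": 3, "n_control": 3}
            )
        gene = collapse_probes_to_genes(self._probe_table(rows))
        assert gene.table.loc["GENEA", "probe_id"] == "p2"

    def test_unmapped_probes_dropped_and_collapse_idempotent(self):
        ds_vals = {
            "p1": [9.1, 9.0, 8.9, 8.0, 8.1, 7.9],
            "p2": [8.6, 8.5, 8.4, 8.0, 8.1, 7.9],
            "p3": [7.0, 7.1, 6.9, 8.0, 8.1, 7.9],
            "p4": [9.9, 9.8, 9.9, 8.0, 8.1, 7.9],
        }
        ds = make_dataset(ds_vals, ["case"] * 3 + ["control"] * 3)
        probe_table = run_dataset_de(ds, annotation=self.annotation)
        gene = collapse_probes_to_genes(probe_table)
        assert set(gene.table.index) == {"GENEA", "GENEB"}  # p4 unmapped
        again = collapse_probes_to_genes(gene)
        assert again.table.equals(gene.table)

    def test_all_unmapped_gives_empty_table(self):
        table = self._probe_table(
            [
                {"probe": "p9", "gene_symbol": "unmapped", "log2fc": 2.0,
                 "fc_linear": 4.0, "t_stat": 5.0, "p_value": 0.001,
                 "q_value": 0.01, "direction": "up", "passes_fc": True,
                 "n_case": 3, "n_control": 3}
            ]
        )
        with pytest.warns(UserWarning):
            gene = collapse_probes_to_genes(table)
        assert gene.total_transcripts == 0
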