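"""Differential pharmacology tests: class calls, hit filters, Fisher/BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from qhtsdiff import (
    CompoundAnnotation,
    bh_adjust,
    class_auc_differential,
    expression_drug_overlay,
    fisher_target_enrichment,
    shared_maxr_hits,
    stringent_potency_hits,
)
from qhtsdiff.differential import fisher_two_tailed

TOP_LOG = np.log10(46e-6)


def ann(cid, moa, targets=None):
    return CompoundAnnotation(cid, cid, frozenset(targets or {moa}), moa)


def metrics(rows):
    return pd.DataFrame(
        rows, columns=["compound_id", "maxr_pct", "logac50", "auc", "crc"]
    )


def hypergeom_two_tail(a, b, c, d):
    """Independent oracle: enumerate all tables with the observed margins and
    sum the probabilities of those no more likely than the observed table."""
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    support = np.arange(max(0, row1 + col1 - n_total), min(row1, col1) + 1)
    if len(support) == 1:  # degenerate margins: only one table possible
        return 1.0
    pmf = hypergeom.pmf(support, n_total, col1, row1)
    p_obs = hypergeom.pmf(a, n_total, col1, row1)
    return float(min(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_all_equal_ps_stay_equal(self):
        q = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_permutation_equivariance(self):
        p = np.array([0.001, 0.2, 0.04, 0.9, 0.04])
        q = bh_adjust(p)
        perm = np.array([3, 0, 4, 1, 2])
        assert np.allclose(bh_adjust(p[perm]), q[perm])

    def test_matches_hand_rule_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            order = np.argsort(p)
            m = len(p)
            # hand step-up: q_(i) = min_{j>=i} p_(j) * m / j
            q_sorted = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1]
            )[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            assert np.allclose(bh_adjust(p), expected)

    @pytest.mark.parametrize("bad", [[-0.1], [1.2], [np.nan]])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestFisher:
    def test_modal_table_is_null(self):
        # observed count equals its hypergeometric expectation
        odds, p = fisher_two_tailed(1, 9, 9, 81)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_derived_example_matches_enumeration(self):
        # selected 10, 5 carry target T; library 100 with 10 T
        _, p = fisher_two_tailed(5, 5, 5, 85)
        assert p == pytest.approx(hypergeom_two_tail(5, 5, 5, 85), rel=1e-9)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_two_tail_matches_hypergeometric_oracle(self, a, b, c, d):
        _, p = fisher_two_tailed(a, b, c, d)
        assert p == pytest.approx(hypergeom_two_tail(a, b, c, d), rel=1e-7)


class TestClassDifferential:
    def _toy_metrics(self, shift_mtor=0.0, seed=0):
        rng = np.random.default_rng(seed)
        anns, rows_a, rows_b = [], [], []
        for k, moa in enumerate(["MTOR", "EGFR", "BRD4", "SRC", "HDAC1", "KIT"]):
            for i in range(10):
                cid = f"{moa}-{i}"
                anns.append(ann(cid, moa))
                auc = rng.uniform(50, 150)
                rows_b.append((cid, 50.0, -6.0, auc, -1.1))
                boost = shift_mtor if moa == "MTOR" else 0.0
                rows_a.append((cid, 50.0, -6.0, auc + boost, -1.1))
        return metrics(rows_a), metrics(rows_b), anns

    def test_identical_inputs_produce_no_calls(self):
        a, b, anns = self._toy_metrics()
        res = class_auc_differential(a, a, anns)
        assert np.allclose(res["auc_ratio_pct"], 100.0)
        assert (res["call"] == "none").all()

    def test_boosted_class_called_selective_a(self):
        a, b, anns = self._toy_metrics(shift_mtor=120.0)
        res = class_auc_differential(a, b, anns)
        row = res[res.moa_class == "MTOR"].iloc[0]
        assert row["call"] == "selective_a"
        assert row["zscore"] >= 2

    def test_antisymmetry_under_line_swap(self):
        a, b, anns = self._toy_metrics(shift_mtor=120.0, seed=3)
        fwd = class_auc_differential(a, b, anns).set_index("moa_class")
        rev = class_auc_differential(b, a, anns).set_index("moa_class")
        assert np.allclose(fwd["zscore"], -rev["zscore"])
        swap = {"selective_a": "selective_b", "selective_b": "selective_a",
                "none": "none"}
        assert (fwd["call"].map(swap) == rev["call"]).all()

    def test_empty_class_omitted_with_warning(self):
        a, b, anns = self._toy_metrics()
        anns.append(ann("ghost-1", "GHOST"))  # no metrics rows
        with pytest.warns(UserWarning, match="GHOST"):
            res = class_auc_differential(a, b, anns)
        assert "GHOST" not in set(res.moa_class)


class TestHitFilters:
    def test_stringent_selection_rules(self):
        rows_a = [
            ("c1", 10.0, -7.5, 300.0, -1.1),   # delta -1.5 -> selected
            ("c2", 10.0, -6.5, 300.0, -1.1),   # delta -0.5 -> rejected
            ("c3", 95.0, np.nan, 5.0, 4.0),    # inactive CRC -> rejected
            ("c4", 30.0, -6.9, 250.0, -2.1),   # high-quality incomplete, -1.4
        ]
        rows_b = [
            ("c1", 40.0, -6.0, 150.0, -1.2),
            ("c2", 40.0, -6.0, 150.0, -1.2),
            ("c3", 95.0, -6.0, 5.0, 4.0),
            ("c4", 80.0, -5.5, 60.0, -2.2),
        ]
        hits = stringent_potency_hits(metrics(rows_a), metrics(rows_b), TOP_LOG)
        assert hits == {"c1", "c4"}

    def test_missing_line_b_potency_right_censored(self):
        # line B inactive: censor at top conc (-4.337); A at -6 -> delta -1.66
        rows_a = [("c1", 10.0, -6.0, 300.0, -1.1)]
        rows_b = [("c1", 95.0, np.nan, 2.0, 4.0)]
        hits = stringent_potency_hits(metrics(rows_a), metrics(rows_b), TOP_LOG)
        assert hits == {"c1"}

    def test_shared_maxr_both_lines_required(self):
        rows_a = [("c1", 20.0, -6, 300, -1.1), ("c2", 20.0, -6, 300, -1.1)]
        rows_b = [("c1", 25.0, -6, 280, -1.1), ("c2", 50.0, -6, 150, -1.2)]
        assert shared_maxr_hits(metrics(rows_a), metrics(rows_b)) == {"c1"}


class TestEnrichment:
    def test_planted_enrichment_flagged(self):
        # T five-fold enriched among hits; N and M close to expectation
        anns = [ann(f"T-{i}", "T") for i in range(10)]
        anns += [ann(f"N-{i}", "N") for i in range(50)]
        anns += [ann(f"M-{i}", "M") for i in range(40)]
        selected = ({f"T-{i}" for i in range(8)}
                    | {f"N-{i}" for i in range(8)}
                    | {f"M-{i}" for i in range(6)})
        res = fisher_target_enrichment(selected, anns).set_index("target")
        assert res.loc["T", "significant_q"]
        assert res.loc["T", "odds_ratio"] > 1
        assert not res.loc["N", "significant_q"]
        assert not res.loc["M", "significant_q"]

    def test_counts_partition_library(self):
        anns = [ann(f"c{i}", "A" if i % 3 else "B") for i in range(30)]
        selected = {f"c{i}" for i in range(10)}
        res = fisher_target_enrichment(selected, anns)
        for _, row in res.iterrows():
            assert row.a + row.b == len(selected)
            assert row.a + row.b + row.c + row.d == 30

    def test_selected_outside_library_rejected(self):
        anns = [ann("c1", "A")]
        with pytest.raises(ValueError):
            fisher_target_enrichment({"zzz"}, anns)

    def test_multi_target_compound_counts_in_each_table(self):
        anns = [ann("c1", "A", {"A", "B"}), ann("c2", "A"), ann("c3", "B")]
        res = fisher_target_enrichment({"c1"}, anns).set_index("target")
        assert res.loc["A", "a"] == 1
        assert res.loc["B", "a"] == 1


class TestOverlay:
    def _fixtures(self):
        de = pd.DataFrame({"gene": ["TOP2A", "EGFR", "KIT"],
                           "log2_fc": [1.5, -0.2, -1.2]})
        anns = [ann(f"t{i}", "TOP2A") for i in range(5)]
        anns += [ann(f"e{i}", "EGFR") for i in range(3)]
        anns += [ann(f"k{i}", "KIT") for i in range(3)]
        rows_a, rows_b = [], []
        for a_ in anns:
            cid = a_.compound_id
            # TOP2A compounds planted 1.5 log units more potent in line A
            la = -7.5 if a_.moa_class == "TOP2A" else -6.0
            rows_a.append((cid, 30.0, la, 200.0, -1.1))
            rows_b.append((cid, 35.0, -6.0, 150.0, -1.1))
        return de, anns, metrics(rows_a), metrics(rows_b)

    def test_upregulated_target_pairs_with_negative_delta_potency(self):
        de, anns, ma, mb = self._fixtures()
        res = expression_drug_overlay(de, anns, ma, mb, TOP_LOG)
        res = res.set_index("target")
        assert set(res.index) == {"TOP2A", "KIT"}  # EGFR below 2-fold
        assert res.loc["TOP2A", "direction"] == "up"
        assert res.loc["TOP2A", "median_delta_logac50"] == pytest.approx(-1.5)
        assert res.loc["KIT", "median_delta_logac50"] == pytest.approx(0.0)

    def test_vacuous_threshold_keeps_all_measured_targets(self):
        de, anns, ma, mb = self._fixtures()
        res = expression_drug_overlay(de, anns, ma, mb, TOP_LOG, fc_threshold=1.0)
        assert set(res.target) == {"TOP2A", "EGFR", "KIT"}

    def test_no_gene_passing_gives_empty_table(self):
        de, anns, ma, mb = self._fixtures()
        de = de.assign(log2_fc=[0.1, 0.0, -0.2])
        res = expression_drug_overlay(de, anns, ma, mb, TOP_LOG)
        assert res.empty

    def test_no_symbol_overlap_warns(self):
        de = pd.DataFrame({"gene": ["XYZ"], "log2_fc": [3.0]})
        _, anns, ma, mb = self._fixtures()
        with pytest.warns(UserWarning, match="no annotated target"):
            res = expression_drug_overlay(de, anns, ma, mb, TOP_LOG)
        assert res.empty
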