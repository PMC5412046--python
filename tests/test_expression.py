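"""Expression workflow tests: normalization, collapse, clustering, DE."""

import numpy as np
import pandas as pd
import pytest

from qhtsdiff import (
    ConfigurationError,
    DataError,
    DESpec,
    ExpressionMatrix,
    collapse_probes,
    generate_expression,
    hierarchical_cluster,
    housekeeping_normalize,
    linkage_to_newick,
    median_center_probes,
    one_vs_rest_de,
)


def toy_matrix(values, samples=None, genes=None, hk=None, lines=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    probes = [f"p{i}" for i in range(values.shape[0])]
    genes = genes or {p: p.upper() for p in probes}
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        sample_to_line=lines or {s: s for s in samples},
        probe_to_gene=genes,
        housekeeping_probes=set(hk or {probes[0]}),
    )


class TestHousekeepingNormalize:
    def test_identical_samples_unchanged(self):
        m = toy_matrix(np.tile([[5.0], [7.0], [9.0]], (1, 3)))
        out = housekeeping_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_global_shift_removed(self):
        base = np.array([[5.0], [7.0], [9.0]])
        m = toy_matrix(np.hstack([base, base + 1.0]))
        out = housekeeping_normalize(m)
        assert np.allclose(out.values.iloc[:, 0], out.values.iloc[:, 1])

    def test_planted_sample_scales_recovered(self):
        matrix, _ = generate_expression(
            n_probes=200, de_spec=DESpec(count=0), noise_sd=0.0,
            sample_scale_sd=0.7, seed=4,
        )
        out = housekeeping_normalize(matrix)
        # after normalization every probe row must be constant across samples
        spread = (out.values.max(axis=1) - out.values.min(axis=1)).max()
        assert spread < 1e-6

    def test_empty_housekeeping_rejected(self):
        m = toy_matrix(np.ones((3, 2)))
        with pytest.raises(ConfigurationError):
            housekeeping_normalize(m, housekeeping_probes=set())

    def test_linear_input_log2_transformed(self):
        m = toy_matrix(np.array([[32.0, 32.0], [64.0, 64.0]]))
        out = housekeeping_normalize(m, input_is_log2=False)
        assert np.allclose(out.values.to_numpy(), [[5.0, 5.0], [6.0, 6.0]])


class TestMedianCenter:
    def test_simple_row(self):
        m = toy_matrix(np.array([[1.0, 2.0, 3.0]]))
        out = median_center_probes(m)
        assert np.allclose(out.values.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = toy_matrix(rng.normal(size=(10, 7)))
        once = median_center_probes(m)
        twice = median_center_probes(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_row_medians_zero(self):
        rng = np.random.default_rng(1)
        m = toy_matrix(rng.normal(size=(25, 9)))
        out = median_center_probes(m)
        assert np.allclose(out.values.median(axis=1), 0.0)

    def test_commutes_with_global_sample_shift(self):
        """Housekeeping normalization followed by centering is invariant to a
        global constant added to one sample."""
        rng = np.random.default_rng(2)
        vals = rng.normal(8, 1, size=(30, 6))
        m1 = toy_matrix(vals.copy())
        vals2 = vals.copy()
        vals2[:, 2] += 3.7
        m2 = toy_matrix(vals2)
        out1 = median_center_probes(housekeeping_normalize(m1))
        out2 = median_center_probes(housekeeping_normalize(m2))
        assert np.allclose(out1.values.to_numpy(), out2.values.to_numpy())


class TestCollapseProbes:
    def test_two_probe_gene_mean(self):
        m = toy_matrix(np.array([[2.0], [4.0]]), genes={"p0": "G", "p1": "G"})
        out = collapse_probes(m)
        assert out.loc["G"].iloc[0] == pytest.approx(3.0)

    def test_single_probe_genes_pass_through(self):
        rng = np.random.default_rng(3)
        m = toy_matrix(rng.normal(size=(5, 4)))
        out = collapse_probes(m)
        assert out.shape == m.values.shape
        assert np.allclose(np.sort(out.to_numpy(), axis=0),
                           np.sort(m.values.to_numpy(), axis=0))

    def test_matches_brute_force_group_means(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(40, 6))
        gene_of = {f"p{i}": f"G{rng.integers(10)}" for i in range(40)}
        m = toy_matrix(vals, genes=gene_of)
        out = collapse_probes(m)
        for gene in set(gene_of.values()):
            probes = [p for p, g in gene_of.items() if g == gene]
            expected = m.values.loc[probes].mean(axis=0)
            assert np.allclose(out.loc[gene], expected)

    def test_unmapped_probe_retained_with_warning(self):
        m = toy_matrix(np.ones((3, 2)), genes={"p0": "G", "p1": "G"})
        with pytest.warns(UserWarning, match="no gene mapping"):
            out = collapse_probes(m)
        assert "p2" in out.index


class TestClustering:
    def test_duplicated_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(20, 4))
        vals[:, 3] = vals[:, 0]  # duplicate column
        Z, labels = hierarchical_cluster(pd.DataFrame(
            vals, columns=["a", "b", "c", "a_dup"]))
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 3}
        assert Z[0, 2] == pytest.approx(0.0)

    def test_planted_outlier_joins_last(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 0.1, size=(50, 6))
        vals[:, 0] += 5.0  # strong distinct signature
        df = pd.DataFrame(vals, columns=[f"s{i}" for i in range(6)])
        Z, labels = hierarchical_cluster(df)
        # the final merge joins the outlier's singleton cluster
        last = Z[-1]
        assert 0 in (int(last[0]), int(last[1]))

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(30, 8)))
        Z, _ = hierarchical_cluster(df)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(DataError):
            hierarchical_cluster(pd.DataFrame(np.ones((5, 1))))

    def test_newick_round_trip_leaf_names(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("wxyz"))
        Z, labels = hierarchical_cluster(df)
        nwk = linkage_to_newick(Z, labels)
        assert nwk.endswith(";")
        for name in "wxyz":
            assert name in nwk


class TestOneVsRestDE:
    def _matrix(self, effect=0.0, noise=0.0, seed=0, n_genes=50):
        rng = np.random.default_rng(seed)
        lines = {f"s{i}": ("L1" if i < 3 else "L2") for i in range(9)}
        base = rng.normal(8, 1, size=(n_genes, 1))
        vals = np.tile(base, (1, 9))
        vals[:10, :3] += effect
        if noise:
            vals = vals + rng.normal(0, noise, vals.shape)
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                          columns=list(lines))
        return df, lines

    def test_exact_fc_readback_at_zero_noise(self):
        df, lines = self._matrix(effect=1.5)
        de = one_vs_rest_de(df, lines, "L1")
        assert np.allclose(de.log2_fc[:10], 1.5)
        assert np.allclose(de.log2_fc[10:], 0.0)

    def test_identical_groups_have_zero_fc(self):
        df, lines = self._matrix(effect=0.0)
        de = one_vs_rest_de(df, lines, "L1")
        assert np.allclose(de.log2_fc, 0.0)

    def test_passes_requires_all_three_criteria(self):
        df, lines = self._matrix(effect=1.5, noise=0.2, seed=1, n_genes=200)
        de = one_vs_rest_de(df, lines, "L1").set_index("gene")
        planted = [f"g{i}" for i in range(10)]
        assert de.loc[planted, "passes"].mean() >= 0.9
        assert not de.drop(planted)["passes"].any()

    def test_column_order_invariance(self):
        df, lines = self._matrix(effect=1.2, noise=0.3, seed=2)
        de1 = one_vs_rest_de(df, lines, "L1")
        shuffled = df[list(df.columns[::-1])]
        de2 = one_vs_rest_de(shuffled, lines, "L1")
        assert (de1.passes == de2.passes).all()
        assert np.allclose(de1.log2_fc, de2.log2_fc)

    def test_insufficient_replicates_rejected(self):
        df, lines = self._matrix()
        lines = dict(lines)
        lines["s0"] = "L3"  # L3 has a single replicate
        with pytest.raises(DataError):
            one_vs_rest_de(df, lines, "L3")
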