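"""Normalization and pairwise-feature computation against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from spred.features import (
    FEATURE_ORDER,
    assemble_ml_input,
    assemble_sp_inputs,
    featurize_grn_ml,
    featurize_grn_sp,
    normalize,
    pairwise_matrices,
    _n_bins,
)
from spred.grn import GrnConfig, sample_grn, sample_interaction_params
from spred.simulate import ExpressionMatrix


def _expr(values, roles=None):
    values = np.asarray(values, dtype=float)
    if roles is None:
        roles = np.array(["TF"] * (values.shape[0] - 1) + ["GENE"])
    return ExpressionMatrix(values, np.asarray(roles),
                            [f"c{j}" for j in range(values.shape[1])])


# ---------------------------------------------------------------------------
# Brute-force oracles (independent, loop-based implementations)


def oracle_cov(x):
    n, m = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.dot(xc[i], xc[j]) / (m - 1)
    return out


def oracle_pearson(x):
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = stats.pearsonr(x[i], x[j]).statistic if i != j else 1.0
    return out


def oracle_spearman(x):
    n = x.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = stats.spearmanr(x[i], x[j]).statistic
    return out


def oracle_bins(row, n_bins):
    """Equal-frequency assignment: sorted positions split into n_bins runs."""
    m = len(row)
    order = np.argsort(row, kind="stable")
    bins = np.empty(m, dtype=int)
    for pos, idx in enumerate(order):
        bins[idx] = (pos * n_bins) // m
    return bins


def oracle_mi(x, n_bins):
    n, m = x.shape
    binned = np.array([oracle_bins(row, n_bins) for row in x])
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            mi = 0.0
            for b in range(n_bins):
                for c in range(n_bins):
                    p_joint = np.mean((binned[i] == b) & (binned[j] == c))
                    p_i = np.mean(binned[i] == b)
                    p_j = np.mean(binned[j] == c)
                    if p_joint > 0:
                        mi += p_joint * np.log(p_joint / (p_i * p_j))
            out[i, j] = mi
    return out


# ---------------------------------------------------------------------------


class TestNormalize:
    def test_rows_are_zero_mean_unit_sd(self, tiny_expression):
        normed = normalize(tiny_expression)
        keep = ~normed.constant_row_flags
        np.testing.assert_allclose(normed.values[keep].mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(normed.values[keep].std(axis=1), 1, atol=1e-10)

    def test_negative_entries_are_handled_by_global_shift(self, rng):
        values = rng.normal(size=(4, 30))  # contains negatives
        normed = normalize(_expr(values))
        assert np.all(np.isfinite(normed.values))
        np.testing.assert_allclose(normed.values.mean(axis=1), 0, atol=1e-10)

    def test_constant_row_is_zeroed_and_flagged(self, rng):
        values = rng.uniform(1, 2, size=(3, 20))
        values[1] = 5.0
        normed = normalize(_expr(values))
        assert normed.constant_row_flags[1]
        assert np.all(normed.values[1] == 0)
        assert not normed.constant_row_flags[[0, 2]].any()

    def test_monotone_shape_preserved_for_positive_data(self, rng):
        # Box-Cox is monotone for any lambda, so ranks are preserved
        values = rng.lognormal(size=(1, 25))
        normed = normalize(_expr(values, roles=["GENE"]))
        assert np.array_equal(np.argsort(normed.values[0]), np.argsort(values[0]))

    def test_too_few_conditions_rejected(self, rng):
        with pytest.raises(ValueError):
            normalize(_expr(rng.uniform(1, 2, size=(2, 2))))


class TestPairwiseMatrices:
    def test_matches_brute_force_on_seeded_input(self, rng):
        values = rng.uniform(0.5, 3.0, size=(5, 20))
        normed = normalize(_expr(values))
        pfs = pairwise_matrices(normed, list(range(5)))
        x = normed.values
        np.testing.assert_allclose(pfs.cov, oracle_cov(x), atol=1e-8)
        np.testing.assert_allclose(pfs.pearson, oracle_pearson(x), atol=1e-8)
        np.testing.assert_allclose(pfs.spearman, oracle_spearman(x), atol=1e-8)
        np.testing.assert_allclose(pfs.mi, oracle_mi(x, _n_bins(20)), atol=1e-12)
        np.testing.assert_allclose(
            pfs.precision, np.linalg.inv(oracle_cov(x) + 1e-3 * np.eye(5)), atol=1e-8
        )

    def test_identity_covariance_gives_analytic_precision(self, rng):
        # whiten a random matrix so its sample covariance is exactly identity
        g = rng.normal(size=(4, 40))
        g -= g.mean(axis=1, keepdims=True)
        cov = g @ g.T / 39
        x = np.linalg.inv(np.linalg.cholesky(cov)) @ g
        expr = _expr(x)
        pfs = pairwise_matrices(expr, list(range(4)))
        np.testing.assert_allclose(pfs.cov, np.eye(4), atol=1e-10)
        np.testing.assert_allclose(pfs.precision, np.eye(4) / (1 + 1e-3), atol=1e-10)

    def test_identical_rows_have_unit_correlation(self, rng):
        base = rng.uniform(0, 1, size=20)
        x = np.vstack([base, base, rng.uniform(0, 1, size=20)])
        pfs = pairwise_matrices(_expr(x), [0, 1, 2])
        assert pfs.pearson[0, 1] == pytest.approx(1.0, abs=1e-10)
        assert pfs.spearman[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_all_matrices_symmetric_and_bounded(self, tiny_expression):
        normed = normalize(tiny_expression)
        rows = list(normed.tf_rows) + [int(normed.gene_rows[0])]
        pfs = pairwise_matrices(normed, rows)
        for name in FEATURE_ORDER:
            mat = getattr(pfs, name)
            np.testing.assert_allclose(mat, mat.T, atol=1e-8)
        assert np.all(pfs.mi >= 0)
        assert np.all((pfs.pearson >= -1) & (pfs.pearson <= 1))
        assert np.all((pfs.spearman >= -1) & (pfs.spearman <= 1))

    @pytest.mark.parametrize("transform", [np.exp, lambda v: v**3])
    def test_spearman_invariant_under_monotone_transforms(self, rng, transform):
        x = rng.normal(size=(4, 25))
        a = pairwise_matrices(_expr(x), [0, 1, 2, 3]).spearman
        b = pairwise_matrices(_expr(transform(x)), [0, 1, 2, 3]).spearman
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_self_information_bounds_pairwise_mi(self, rng):
        """MI(X, X) equals the bin entropy and is >= MI(X, Y) for any Y."""
        x = rng.normal(size=(10, 40))
        pfs = pairwise_matrices(_expr(x), list(range(10)))
        for i in range(10):
            assert pfs.mi[i, i] >= pfs.mi[i].max() - 1e-12

    def test_precision_inverts_regularized_covariance(self, rng):
        x = rng.normal(size=(20, 50))
        pfs = pairwise_matrices(_expr(x), list(range(20)))
        product = pfs.precision @ (pfs.cov + 1e-3 * np.eye(20))
        np.testing.assert_allclose(product, np.eye(20), atol=1e-6)


@pytest.fixture(scope="module")
def small_case():
    cfg = GrnConfig(n_mr=2, n_tf=4, n_gene=3, d_mr_tf=1, d_tf_gene_range=(1, 2))
    grn = sample_interaction_params(sample_grn(cfg, 21), 22)
    rng = np.random.default_rng(23)
    values = rng.uniform(0.2, 4.0, size=(grn.n_nodes, 15))
    roles = ["MR"] * 2 + ["TF"] * 4 + ["GENE"] * 3
    expr = ExpressionMatrix(values, np.array(roles), [f"c{j}" for j in range(15)])
    return grn, expr


class TestAssembly:
    def test_sp_inputs_shapes_labels_and_count(self, small_case):
        grn, expr = small_case
        normed = normalize(expr)
        all_inputs = []
        for gene in grn.gene_ids:
            rows = list(normed.tf_rows) + [gene]
            pfs = pairwise_matrices(normed, rows)
            inputs = assemble_sp_inputs(pfs, grn, gene)
            assert len(inputs) == grn.n_tf
            truth = grn.tf_gene_edge_set()
            for sp in inputs:
                assert sp.features.shape == (grn.n_tf + 1, 5)
                assert sp.label == int((grn.n_mr + sp.tf_index, gene) in truth)
            all_inputs.extend(inputs)
        assert len(all_inputs) == grn.n_tf * grn.n_gene

    def test_sp_rows_are_slices_of_the_relation_matrices(self, small_case):
        grn, expr = small_case
        normed = normalize(expr)
        gene = list(grn.gene_ids)[0]
        pfs = pairwise_matrices(normed, list(normed.tf_rows) + [gene])
        sp = assemble_sp_inputs(pfs, grn, gene)[2]
        tensor = pfs.stack()
        np.testing.assert_array_equal(sp.features[: grn.n_tf], tensor[2, : grn.n_tf])
        np.testing.assert_array_equal(sp.features[-1], tensor[2, grn.n_tf])

    def test_ml_input_shape_and_block_order(self, small_case):
        grn, expr = small_case
        normed = normalize(expr)
        gene = list(grn.gene_ids)[1]
        pfs = pairwise_matrices(normed, list(normed.tf_rows) + [gene])
        ml = assemble_ml_input(pfs, grn, gene)
        n_tf = grn.n_tf
        assert ml.features.shape == (n_tf**2 + n_tf, 5)
        assert ml.labels.shape == (n_tf,)
        assert ml.labels.sum() == len(grn.parents_of(gene))
        tensor = pfs.stack()
        # row-major TF-TF block, then TF-gene rows
        np.testing.assert_array_equal(ml.features[n_tf + 2], tensor[1, 2])
        np.testing.assert_array_equal(ml.features[n_tf**2 + 1], tensor[1, n_tf])

    def test_non_gene_index_rejected(self, small_case):
        grn, expr = small_case
        normed = normalize(expr)
        pfs = pairwise_matrices(normed, list(normed.tf_rows) + [list(grn.gene_ids)[0]])
        with pytest.raises(ValueError):
            assemble_sp_inputs(pfs, grn, 0)

    def test_batch_featurization_matches_per_gene_assembly(self, small_case):
        """The shared-block fast path equals the direct per-gene computation."""
        grn, expr = small_case
        ds = featurize_grn_sp(expr, grn)
        normed = normalize(expr)
        k = 0
        for gene in grn.gene_ids:
            pfs = pairwise_matrices(normed, list(normed.tf_rows) + [gene])
            for sp in assemble_sp_inputs(pfs, grn, gene):
                np.testing.assert_allclose(ds.x_tf[k], sp.features[: grn.n_tf], atol=1e-10)
                np.testing.assert_allclose(ds.x_tg[k, 0], sp.features[-1], atol=1e-10)
                assert ds.y[k] == sp.label
                k += 1

    def test_ml_dataset_dimensions(self, small_case):
        grn, expr = small_case
        ds = featurize_grn_ml(expr, grn)
        assert ds.x_tt.shape == (grn.n_gene, grn.n_tf**2, 5)
        assert ds.x_tg.shape == (grn.n_gene, grn.n_tf, 5)
        assert ds.y.shape == (grn.n_gene, grn.n_tf)

    def test_feature_subset_hook(self, small_case):
        grn, expr = small_case
        ds = featurize_grn_sp(expr, grn, features=("pearson", "precision"))
        assert ds.x_tf.shape[-1] == 2
        full = featurize_grn_sp(expr, grn)
        np.testing.assert_allclose(ds.x_tf[..., 0], full.x_tf[..., 1])
        np.testing.assert_allclose(ds.x_tf[..., 1], full.x_tf[..., 4])
        with pytest.raises(ValueError):
            featurize_grn_sp(expr, grn, features=("nope",))
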