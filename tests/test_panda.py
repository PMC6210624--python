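"""Message-passing core: normalization, similarity, filtering, inference."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import panda_reference, pearson_matrix
from tfcgnet import (
    ExpressionMatrix,
    MotifPrior,
    PandaConfig,
    PPINetwork,
    ValidationError,
    compute_coexpression,
    filter_tfs,
    normalize_expression,
    panda_infer,
    tanimoto,
    zscore_normalize_matrix,
)


def _expr(values, state="normalized", conditions=None):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    cond = conditions or {s: "A" for s in samples}
    return ExpressionMatrix(genes, samples, values, cond, state)


class TestFilterTfs:
    def _inputs(self, counts):
        prior = MotifPrior(["T0", "T1"], ["g0", "g1"], np.ones((2, 2)))
        ppi = PPINetwork(["T0", "T1"], np.eye(2))
        genes = ["T0", "T1", "g0", "g1"]
        values = np.vstack([counts, np.full((2, counts.shape[1]), 10.0)])
        expr = ExpressionMatrix(genes, [f"s{j}" for j in range(counts.shape[1])],
                                values, transform_state="normalized")
        return prior, ppi, expr

    def test_low_count_tf_removed(self):
        # mean normalized count 0.5 is below the count floor of 1
        prior, ppi, expr = self._inputs(np.array([[0.5, 0.5], [5.0, 5.0]]))
        pf, qf = filter_tfs(prior, ppi, expr)
        assert pf.tf_ids == ["T1"] and qf.tf_ids == ["T1"]

    def test_tf_absent_from_ppi_removed(self):
        prior = MotifPrior(["T0", "T1"], ["g0"], np.ones((2, 1)))
        ppi = PPINetwork(["T1"], np.eye(1))
        expr = ExpressionMatrix(["T0", "T1", "g0"], ["s0", "s1"],
                                np.full((3, 2), 10.0))
        pf, _ = filter_tfs(prior, ppi, expr)
        assert pf.tf_ids == ["T1"]

    def test_all_expressed_is_identity(self):
        prior, ppi, expr = self._inputs(np.full((2, 2), 10.0))
        pf, qf = filter_tfs(prior, ppi, expr)
        assert pf.tf_ids == prior.tf_ids
        np.testing.assert_array_equal(pf.weights, prior.weights)

    def test_all_removed_is_error(self):
        prior, ppi, expr = self._inputs(np.zeros((2, 2)))
        with pytest.raises(ValidationError, match="empty TF set"):
            filter_tfs(prior, ppi, expr)


class TestNormalizeExpression:
    def test_constant_gene_centers_to_zero(self):
        out = normalize_expression(_expr([[7, 7, 7]]))
        np.testing.assert_array_equal(out.values, [[0, 0, 0]])
        assert out.transform_state == "log2_median_centered"

    def test_hand_computed_example(self):
        # counts (1,3,7), pseudocount 1 -> log2(2,4,8)=(1,2,3), median 2
        out = normalize_expression(_expr([[1, 3, 7]]))
        np.testing.assert_allclose(out.values, [[-1, 0, 1]])

    def test_double_application_forbidden(self):
        out = normalize_expression(_expr([[1, 3, 7]]))
        with pytest.raises(ValidationError):
            normalize_expression(out)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            normalize_expression(_expr([[-1, 2, 3]]))


class TestCoexpression:
    def test_duplicated_gene_rows_correlate_perfectly(self):
        e = _expr([[1, 2, 3], [1, 2, 3]], state="log2_median_centered")
        C = compute_coexpression(e, "A")
        assert C[0, 1] == pytest.approx(1.0)

    def test_opposite_profiles_give_minus_one(self):
        e = _expr([[1, 0, -1], [-1, 0, 1]], state="log2_median_centered")
        C = compute_coexpression(e, "A")
        assert C[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_gene_gets_zero_off_diagonal(self):
        e = _expr([[0, 0, 0], [1, 2, 3]], state="log2_median_centered")
        C = compute_coexpression(e, "A")
        assert C[0, 1] == 0.0 and C[0, 0] == 1.0

    def test_fewer_than_three_samples_is_error(self):
        e = _expr([[1, 2], [3, 4]], state="log2_median_centered")
        with pytest.raises(ValidationError, match=">= 3"):
            compute_coexpression(e, "A")

    def test_matches_bruteforce_pearson(self, rng):
        X = rng.normal(size=(5, 8))
        e = _expr(X, state="log2_median_centered")
        C = compute_coexpression(e, "A")
        np.testing.assert_allclose(C, pearson_matrix(X), atol=1e-12)


class TestZscoreNormalize:
    def test_constant_matrix_maps_to_zeros(self):
        np.testing.assert_array_equal(
            zscore_normalize_matrix(np.full((3, 4), 5.0)), np.zeros((3, 4))
        )

    def test_row_vector_uses_row_direction_only(self):
        v = np.array([[1.0, 2.0, 3.0]])
        expected = (v - v.mean()) / v.std() / np.sqrt(2.0)
        np.testing.assert_allclose(zscore_normalize_matrix(v), expected)

    def test_matches_bruteforce_on_seeded_matrix(self, rng):
        M = rng.normal(size=(3, 3))
        rz = (M - M.mean(1, keepdims=True)) / M.std(1, keepdims=True)
        cz = (M - M.mean(0, keepdims=True)) / M.std(0, keepdims=True)
        np.testing.assert_allclose(
            zscore_normalize_matrix(M), (rz + cz) / np.sqrt(2), atol=1e-12
        )


class TestTanimoto:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 0], [1, 0], 1.0),
            ([0, 0], [1, 1], 0.0),
            ([1, 1], [1, 0], 1.0 / np.sqrt(2.0)),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert tanimoto(x, y) == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=6),
        st.lists(st.floats(-5, 5), min_size=2, max_size=6),
    )
    @settings(derandomize=True, max_examples=50)
    def test_symmetry_and_norm_bound(self, x, y):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        t = tanimoto(x, y)
        assert t == pytest.approx(tanimoto(y, x))
        bound = np.sqrt(np.linalg.norm(x) * np.linalg.norm(y)) + 1e-9
        assert abs(t) <= bound


def _fixture_inputs(seed=0, n_tfs=3, n_genes=5, n_samples=6):
    rng = np.random.default_rng(seed)
    W0 = (rng.random((n_tfs, n_genes)) < 0.5).astype(float)
    W0[W0.sum(axis=1) == 0, 0] = 1.0
    P0 = np.triu((rng.random((n_tfs, n_tfs)) < 0.5).astype(float), 1)
    P0 = P0 + P0.T
    np.fill_diagonal(P0, 1.0)
    X = rng.normal(size=(n_genes, n_samples))
    prior = MotifPrior([f"T{i}" for i in range(n_tfs)],
                       [f"g{j}" for j in range(n_genes)], W0)
    ppi = PPINetwork(prior.tf_ids, P0)
    expr = _expr(X, state="log2_median_centered")
    expr.gene_ids[:] = prior.gene_ids
    return prior, ppi, expr


class TestPandaInfer:
    def test_vanishing_alpha_returns_zscored_prior(self):
        prior, ppi, expr = _fixture_inputs()
        cfg = PandaConfig(alpha=1e-9, max_iterations=1, hamming_tolerance=1e-12)
        net = panda_infer(prior, ppi, expr, "A", cfg)
        np.testing.assert_allclose(
            net.z, zscore_normalize_matrix(prior.weights), atol=1e-6
        )

    def test_converges_below_tolerance(self):
        prior, ppi, expr = _fixture_inputs()
        net = panda_infer(prior, ppi, expr, "A")
        assert net.converged and net.final_hamming < 1e-5

    def test_matches_straightline_reference(self):
        prior, ppi, expr = _fixture_inputs(seed=0)
        cfg = PandaConfig()
        net = panda_infer(prior, ppi, expr, "A", cfg)
        C0 = compute_coexpression(expr, "A")
        W_ref, it_ref, h_ref = panda_reference(
            prior.weights, ppi.weights, C0, cfg.alpha,
            cfg.hamming_tolerance, cfg.max_iterations,
        )
        np.testing.assert_allclose(net.z, W_ref, atol=1e-10)
        assert net.iterations_run == it_ref

    def test_deterministic(self):
        prior, ppi, expr = _fixture_inputs()
        z1 = panda_infer(prior, ppi, expr, "A").z
        z2 = panda_infer(prior, ppi, expr, "A").z
        np.testing.assert_array_equal(z1, z2)

    def test_gene_permutation_equivariance(self, rng):
        prior, ppi, expr = _fixture_inputs(seed=4)
        perm = rng.permutation(len(prior.gene_ids))
        genes_p = [prior.gene_ids[i] for i in perm]
        prior_p = MotifPrior(list(prior.tf_ids), genes_p, prior.weights[:, perm])
        expr_p = expr.subset_genes(genes_p)
        z = panda_infer(prior, ppi, expr, "A").z
        z_p = panda_infer(prior_p, ppi, expr_p, "A").z
        np.testing.assert_allclose(z_p, z[:, perm], atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_true_edges_outscore_non_edges(self, seed):
        # planted-signal sensitivity of the inferred z-scores
        from tfcgnet import (
            ScenarioConfig, concat_expression, generate_scenario,
        )

        cfg = ScenarioConfig(
            n_tfs=10, n_genes=60, n_samples_per_condition=10,
            planted_groups=((3, 12), (2, 8)), seed=seed,
        )
        prior, ppi, ea, eb, truth = generate_scenario(cfg)
        expr_all = concat_expression(ea, eb)
        pf, qf = filter_tfs(prior, ppi, expr_all)
        net = panda_infer(pf, qf, normalize_expression(expr_all), "A")
        ti = {t: i for i, t in enumerate(net.tf_ids)}
        gi = {g: j for j, g in enumerate(net.gene_ids)}
        mask = np.zeros(net.z.shape, dtype=bool)
        for tf, g, _ in truth.true_edges:
            if tf in ti:
                mask[ti[tf], gi[g]] = True
        assert net.z[mask].mean() > net.z[~mask].mean()
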