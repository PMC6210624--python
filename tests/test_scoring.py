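"""Signature fractions, the paired DE stand-in, stratification, Mann-Whitney."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import mann_whitney_enumeration
from tfcgnet import (
    ExpressionMatrix,
    GeneSetCollection,
    ValidationError,
    mann_whitney,
    simple_paired_de,
    stratify_impact_groups,
    subtype_fraction,
)


def _expr(values, genes=None, samples=None, state="normalized"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, transform_state=state)


class TestSubtypeFraction:
    def test_constant_gene_never_overexpressed(self):
        e = _expr([[5.0, 5.0, 5.0]])
        f = subtype_fraction(e, GeneSetCollection({"S": ["g0"]}), fold=2.0)
        assert (f["S"] == 0.0).all()

    def test_sample_at_four_fold_median_scores_one(self):
        e = _expr([[1.0, 1.0, 1.0, 4.0], [1.0, 1.0, 1.0, 4.0]])
        f = subtype_fraction(e, GeneSetCollection({"S": ["g0", "g1"]}), fold=2.0)
        assert f.loc["s3", "S"] == 1.0
        assert f.loc["s0", "S"] == 0.0

    def test_unmeasured_signature_named_in_error(self):
        e = _expr([[1.0, 2.0]])
        with pytest.raises(ValidationError, match="PCSX"):
            subtype_fraction(e, GeneSetCollection({"PCSX": ["nope"]}))

    def test_invariant_to_gene_and_sample_order(self, rng):
        values = rng.lognormal(size=(6, 5))
        e = _expr(values)
        sets = GeneSetCollection({"S": ["g1", "g3", "g4"]})
        f1 = subtype_fraction(e, sets)
        perm_g = rng.permutation(6)
        perm_s = rng.permutation(5)
        e2 = ExpressionMatrix(
            [e.gene_ids[i] for i in perm_g],
            [e.sample_ids[j] for j in perm_s],
            values[np.ix_(perm_g, perm_s)],
            transform_state="normalized",
        )
        f2 = subtype_fraction(e2, sets)
        for s in e.sample_ids:
            assert f1.loc[s, "S"] == f2.loc[s, "S"]

    def test_summary_means_and_percent_change(self):
        import pandas as pd

        from tfcgnet import summarize_fractions

        fractions = pd.DataFrame(
            {"S": [0.2, 0.4, 0.6, 0.8]}, index=["a1", "a2", "b1", "b2"]
        )
        groups = {"a1": "pre", "a2": "pre", "b1": "post", "b2": "post"}
        summary = summarize_fractions(fractions, groups)
        assert summary.loc["pre", "S"] == pytest.approx(0.3)
        assert summary.loc["post", "S"] == pytest.approx(0.7)
        # post vs pre on sorted group order: (0.3 - 0.7) / 0.7
        assert summary.loc["percent_change", "S"] == pytest.approx(
            100.0 * (0.3 - 0.7) / 0.7
        )

    def test_log2_scale_matches_linear(self, rng):
        values = rng.lognormal(size=(4, 6))
        sets = GeneSetCollection({"S": ["g0", "g1", "g2", "g3"]})
        f_lin = subtype_fraction(_expr(values), sets, fold=2.0)
        f_log = subtype_fraction(
            _expr(np.log2(values), state="log2_median_centered"),
            sets, fold=2.0, scale="log2",
        )
        assert (f_lin.values == f_log.values).all()


class TestSimplePairedDe:
    def _paired(self, n_pairs=6, n_genes=4, seed=0):
        rng = np.random.default_rng(seed)
        pre = [f"pre{i}" for i in range(n_pairs)]
        post = [f"post{i}" for i in range(n_pairs)]
        values = rng.lognormal(mean=3, size=(n_genes, 2 * n_pairs))
        return ExpressionMatrix(
            [f"g{i}" for i in range(n_genes)], pre + post, values
        ), pre, post

    def test_four_fold_shift_gives_log2fc_two(self):
        expr, pre, post = self._paired()
        expr.values[0, 6:] = 4.0 * expr.values[0, :6] + 3.0  # 4x on counts+1
        de = simple_paired_de(expr, pre, post)
        assert de.table.loc[0, "log2_fold_change"] == pytest.approx(2.0)
        # exact signed-rank minimum for n=6 is 2/2^6
        assert de.table.loc[0, "p_value"] == pytest.approx(2.0 / 64.0)

    def test_bh_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_identical_pre_post_passes_nothing(self):
        expr, pre, post = self._paired()
        expr.values[:, 6:] = expr.values[:, :6]
        de = simple_paired_de(expr, pre, post)
        assert (de.table["log2_fold_change"] == 0.0).all()
        assert (de.table["p_value"] == 1.0).all()
        assert not de.table["passes"].any()

    def test_q_monotone_in_p_rank(self):
        expr, pre, post = self._paired(seed=3)
        de = simple_paired_de(expr, pre, post)
        tab = de.table.sort_values("p_value")
        assert (np.diff(tab["q_value"]) >= -1e-12).all()
        assert (tab["q_value"] <= 1.0).all()

    def test_orphan_samples_listed(self):
        expr, pre, post = self._paired()
        with pytest.raises(ValidationError, match="preX"):
            simple_paired_de(expr, ["preX"] + pre[1:], post)

    def test_too_few_pairs_rejected(self):
        expr, pre, post = self._paired()
        with pytest.raises(ValidationError, match=">= 5"):
            simple_paired_de(expr, pre[:3], post[:3])


class TestStratify:
    def _blobs(self, seed=0, n_per=5, sep=6.0):
        rng = np.random.default_rng(seed)
        n_genes = 10
        # downregulated genes: low in the "high impact" blob
        high = rng.normal(0.0, 0.5, size=(n_genes, n_per))
        low = rng.normal(sep, 0.5, size=(n_genes, n_per))
        values = np.hstack([high, low])
        samples = [f"h{i}" for i in range(n_per)] + [f"l{i}" for i in range(n_per)]
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(n_genes)], samples, values,
            transform_state="log2_median_centered",
        )
        import pandas as pd

        from tfcgnet.scoring import DeGeneTable

        de = DeGeneTable(
            pd.DataFrame({
                "gene": expr.gene_ids,
                "log2_fold_change": [-2.0] * n_genes,
                "p_value": [1e-4] * n_genes,
                "q_value": [1e-3] * n_genes,
                "passes": [True] * n_genes,
            }),
            2.0, 0.05,
        )
        return expr, de

    def test_separated_blobs_labelled_correctly(self):
        expr, de = self._blobs()
        labels = stratify_impact_groups(expr, de)
        for s in expr.sample_ids:
            assert labels[s] == ("high" if s.startswith("h") else "low")

    def test_two_samples_each_own_cluster(self):
        expr, de = self._blobs(n_per=1)
        labels = stratify_impact_groups(expr, de)
        assert labels == {"h0": "high", "l0": "low"}

    def test_duplicated_samples_co_cluster(self):
        expr, de = self._blobs()
        labels1 = stratify_impact_groups(expr, de)
        # duplicate every sample; duplicates must land in the same group
        dup = ExpressionMatrix(
            expr.gene_ids,
            expr.sample_ids + [s + "_dup" for s in expr.sample_ids],
            np.hstack([expr.values, expr.values]),
            transform_state="log2_median_centered",
        )
        labels2 = stratify_impact_groups(dup, de)
        for s in expr.sample_ids:
            assert labels2[s] == labels2[s + "_dup"] == labels1[s]

    def test_sample_order_invariance(self):
        expr, de = self._blobs(seed=4)
        labels1 = stratify_impact_groups(expr, de)
        rev = expr.subset_samples(list(reversed(expr.sample_ids)))
        labels2 = stratify_impact_groups(rev, de)
        assert labels1 == labels2

    def test_identical_samples_error(self):
        expr, de = self._blobs()
        expr.values[:, :] = 1.0
        with pytest.raises(ValidationError, match="no structure"):
            stratify_impact_groups(expr, de)


class TestMannWhitney:
    def test_textbook_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1.0 / 3.0)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_all_tied_p_one(self):
        _, p = mann_whitney([5, 5, 5], [5, 5])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
        y = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
        u, p = mann_whitney(x, y)
        u_ref, p_ref = mann_whitney_enumeration(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=6),
        st.lists(st.floats(-10, 10), min_size=2, max_size=6),
    )
    @settings(derandomize=True, max_examples=40)
    def test_p_in_unit_interval(self, x, y):
        _, p = mann_whitney(x, y)
        assert 0.0 < p <= 1.0
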