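"""Binary-matrix statistics: PCA selection, Jaccard, Tanimoto, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from helpers import random_binary_matrix
from metaland.stats import (
    cluster_landscapes,
    differentiating_reactions,
    jaccard,
    jaccard_max,
    pca,
    select_variables,
    tanimoto,
)

binary_vec = st.lists(st.integers(0, 1), min_size=1, max_size=30)


def _df(values):
    a = np.asarray(values)
    return pd.DataFrame(a, index=[f"S{i}" for i in range(a.shape[0])],
                        columns=[f"R{j}" for j in range(a.shape[1])])


class TestPca:
    def test_duplicated_rows_have_identical_scores(self):
        M = _df([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]])
        dec = pca(M, k=2)
        np.testing.assert_allclose(dec.scores.iloc[0], dec.scores.iloc[1], atol=1e-12)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        M = random_binary_matrix(rng, 8, 5)
        k = min(M.shape)
        dec = pca(M, k=k)
        Xc = M.to_numpy(float) - M.to_numpy(float).mean(axis=0)
        recon = dec.scores.to_numpy() @ dec.loadings.to_numpy().T
        assert np.abs(recon - Xc).max() < 1e-8

    def test_anticorrelated_blocks_drive_pc1(self):
        """Two complementary column blocks form a rank-1 +/- pattern;
        PC1 loadings concentrate on them with opposite signs."""
        rows = [[1, 1, 0, 0, 0], [1, 1, 0, 0, 1], [0, 0, 1, 1, 0], [0, 0, 1, 1, 1]]
        dec = pca(_df(rows), k=2)
        l1 = dec.loadings["PC1"]
        block_a, block_b = l1[["R0", "R1"]], l1[["R2", "R3"]]
        assert np.abs(block_a).min() > 5 * abs(l1["R4"])
        assert np.sign(block_a).nunique() == 1 and np.sign(block_b).nunique() == 1
        assert np.sign(block_a.iloc[0]) == -np.sign(block_b.iloc[0])

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(1)
        M = random_binary_matrix(rng, 10, 6)
        d1, d2 = pca(M, 3), pca(M, 3)
        pd.testing.assert_frame_equal(d1.loadings, d2.loadings)
        for col in d1.loadings:
            j = d1.loadings[col].abs().idxmax()
            assert d1.loadings.loc[j, col] > 0

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        M = random_binary_matrix(rng, 12, 7)
        L = pca(M, 4).loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-10)

    def test_constant_matrix_handled(self):
        dec = pca(_df([[1, 1], [1, 1], [1, 1]]), k=1)
        assert np.allclose(dec.scores, 0)


class TestSelectVariables:
    def _dec(self, loadings):
        L = np.asarray(loadings, dtype=float)[:, None]
        lo = pd.DataFrame(L, index=[f"R{j}" for j in range(len(loadings))], columns=["PC1"])
        sc = pd.DataFrame(np.zeros((2, 1)), columns=["PC1"])
        from metaland.stats import PcaDecomposition

        return PcaDecomposition(loadings=lo, scores=sc, explained_variance=np.ones(1))

    def test_max_rule_keeps_ties(self):
        sel = select_variables(self._dec([0.9, 0.9, 0.1]), f="max", k=1)
        assert sel.selected == (0, 1)

    def test_frac_rule(self):
        sel = select_variables(self._dec([0.8, 0.5, 0.3]), f="frac:0.5", k=1)
        assert sel.selected == (0, 1)  # threshold 0.4

    def test_k_zero_selects_nothing(self):
        assert select_variables(self._dec([0.8, 0.5]), f="max", k=0).selected == ()

    def test_frac_zero_selects_all(self):
        rng = np.random.default_rng(3)
        M = random_binary_matrix(rng, 9, 6)
        sel = select_variables(pca(M, 2), f="frac:0", k=2)
        assert sel.selected == tuple(range(6))

    def test_union_of_per_component_sets(self):
        rng = np.random.default_rng(4)
        M = random_binary_matrix(rng, 10, 8)
        sel = select_variables(pca(M, 3), f="frac:0.7", k=3)
        union = set().union(*sel.per_component.values())
        assert set(sel.selected) == union

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="selection rule"):
            select_variables(self._dec([0.5]), f="median", k=1)


class TestJaccard:
    def test_self_similarity_is_one(self):
        assert jaccard([1, 0, 1], [1, 0, 1]) == 1.0

    def test_no_shared_elements_is_zero(self):
        assert jaccard([1, 1, 1], [0, 0, 0, 0]) == 0.0

    def test_count_formula_example(self):
        # x1=2, x0=1 vs y1=1, y0=2 -> (1+1)/(2+2)
        assert jaccard([1, 1, 0], [1, 0, 0]) == pytest.approx(0.5)

    @given(binary_vec, binary_vec)
    def test_symmetric_and_bounded(self, x, y):
        j = jaccard(x, y)
        assert j == jaccard(y, x)
        assert 0.0 <= j <= jaccard_max(len(x), len(y)) + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard([], [])

    def test_set_mode(self):
        assert jaccard([1, 1, 0], [1, 0, 0], mode="sets") == pytest.approx(0.5)
        assert jaccard([0, 0], [0, 0], mode="sets") == 1.0


class TestJaccardMax:
    def test_equal_lengths_reach_one(self):
        assert jaccard_max(4, 4) == 1.0
        assert jaccard_max(1, 1) == 1.0

    def test_matches_direct_search(self):
        # independent re-derivation over count pairs for n=3, m=5
        best = max(
            (min(x1, y1) + min(3 - x1, 5 - y1)) / (max(x1, y1) + max(3 - x1, 5 - y1))
            for x1 in range(4)
            for y1 in range(6)
        )
        assert jaccard_max(3, 5) == pytest.approx(best)

    def test_bounded_by_shorter_over_longer(self):
        for n, m in [(2, 7), (3, 4), (1, 9)]:
            assert jaccard_max(n, m) <= 1.0
            assert jaccard_max(n, m) == jaccard_max(m, n)


class TestTanimoto:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 0, 1, 1], [1, 0, 1, 1], 1.0),
            ([1, 1, 1, 1], [0, 0, 0, 0], 0.0),
            ([1, 0, 1, 1], [1, 0, 0, 1], 0.6),
        ],
    )
    def test_examples(self, x, y, expected):
        assert tanimoto(x, y) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto([1, 0], [1, 0, 1])

    @given(binary_vec)
    def test_self_similarity(self, x):
        assert tanimoto(x, x) == 1.0

    def test_generalised_l1_mode(self):
        # fractional activities from aggregation use d = sum |xi - yi|
        assert tanimoto([0.5, 1.0], [0.0, 1.0]) == pytest.approx((2 - 0.5) / (2 + 0.5))


class TestDifferentiatingReactions:
    def test_fully_opposed_reaction_called(self):
        a = _df([[1, 1], [1, 0]])
        b = _df([[0, 1], [0, 0]])
        assert "R0" in differentiating_reactions(a, b)

    def test_identical_prevalence_not_called(self):
        a = _df([[1, 0], [0, 1]])
        b = _df([[0, 1], [1, 0]])
        assert "R0" not in differentiating_reactions(a, b)

    def test_fraction_one_calls_everything_below_max(self):
        a = _df([[1, 1], [1, 1]])
        b = _df([[0, 1], [0, 1]])
        called = differentiating_reactions(a, b, fraction=1.0)
        assert called == ("R0", "R1")

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(8)
        a, b = random_binary_matrix(rng, 6, 5), random_binary_matrix(rng, 4, 5)
        shuffled = a.sample(frac=1, random_state=1)
        assert differentiating_reactions(a, b) == differentiating_reactions(shuffled, b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            differentiating_reactions(_df([[1]]), _df([[1]]).iloc[:0])


class TestClustering:
    def test_identical_rows_merge_at_zero(self):
        M = _df([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        _, Z = cluster_landscapes(M, k=2)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_complementary_blocks_separate(self):
        block_a = [[1, 1, 1, 0, 0, 0]] * 4
        block_b = [[0, 0, 0, 1, 1, 1]] * 4
        M = _df(block_a + block_b)
        labels, _ = cluster_landscapes(M, k=2)
        assert labels.iloc[:4].nunique() == 1 and labels.iloc[4:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_row_permutation_gives_same_partition(self):
        # long rows keep pairwise distances distinct; with tied merge
        # heights average linkage is not permutation-invariant
        rng = np.random.default_rng(12)
        M = random_binary_matrix(rng, 8, 40)
        labels, _ = cluster_landscapes(M, k=3)
        perm = M.sample(frac=1, random_state=5)
        labels_p, _ = cluster_landscapes(perm, k=3)
        # same partition up to label renaming
        mapping = {}
        for s in M.index:
            mapping.setdefault(labels[s], set()).add(s)
        mapping_p = {}
        for s in perm.index:
            mapping_p.setdefault(labels_p[s], set()).add(s)
        assert sorted(map(sorted, mapping.values())) == sorted(map(sorted, mapping_p.values()))

    def test_requires_cut_spec(self):
        M = _df([[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            cluster_landscapes(M)
        with pytest.raises(ValueError):
            cluster_landscapes(M, k=2, height=0.5)
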