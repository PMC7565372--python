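"""Dunn-index k selection, PAM, unsupervised forest, importances, selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from gravitr import clustering as cl


def blobs(centers, n=10, sd=0.3, p=4, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(c, sd, size=(n, p)) for c in centers])
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])


class TestPam:
    def test_block_diagonal_recovery(self):
        D = np.ones((9, 9))
        for b in range(3):
            D[3 * b:3 * b + 3, 3 * b:3 * b + 3] = 0.0
        labels, medoids = cl.pam_cluster(D, 3)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:6])) == 1
        assert len(set(labels[6:])) == 1
        assert len(set(labels)) == 3

    def test_row_swap_permutes_labels(self):
        X = blobs([0, 5], n=5)
        D = squareform(pdist(X))
        labels, _ = cl.pam_cluster(D, 2)
        perm = np.arange(10)
        perm[[0, 7]] = [7, 0]
        Dp = D[np.ix_(perm, perm)]
        labels_p, _ = cl.pam_cluster(Dp, 2)
        # partition must be identical up to the row swap
        same = labels[perm]
        agree = np.mean(labels_p == same)
        assert agree in (0.0, 1.0)  # labels may be renamed wholesale
        if agree == 0.0:
            assert np.mean(labels_p == 1 - same) == 1.0

    @pytest.mark.parametrize("n,k", [(6, 2), (7, 3), (8, 2)])
    def test_objective_matches_exhaustive_optimum(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        X = rng.normal(size=(n, 3))
        D = squareform(pdist(X))
        _, medoids = cl.pam_cluster(D, k)
        pam_cost = D[:, medoids].min(axis=1).sum()
        brute = min(D[:, list(m)].min(axis=1).sum()
                    for m in itertools.combinations(range(n), k))
        assert pam_cost == pytest.approx(brute, abs=1e-12)

    def test_k_out_of_range_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError):
            cl.pam_cluster(D, 4)


class TestDunn:
    def test_three_blobs_select_three(self):
        f = blobs([0, 5, 10], seed=1)
        k, scores = cl.dunn_select_k(f)
        assert k == 3

    def test_two_blobs_select_two(self):
        f = blobs([0, 6], n=12, seed=2)
        k, _ = cl.dunn_select_k(f)
        assert k == 2

    def test_positive_for_separated_clusters(self):
        f = blobs([0, 8], n=8, seed=3)
        D = squareform(pdist(cl.standardize(f)))
        labels = np.repeat([0, 1], 8)
        assert cl.dunn_index(D, labels) > 0


class TestUnsupervisedForest:
    def test_diagonal_zero_and_symmetric(self):
        f = blobs([0, 4], n=8, seed=4)
        res = cl.urf_dissimilarity(f, mtry=2, ntree=100, seed=0)
        D = res.dissimilarity
        assert np.allclose(np.diag(D), 0.0)
        assert np.allclose(D, D.T)

    def test_duplicate_rows_nearly_indistinguishable(self):
        f = blobs([0, 4, 8], n=6, seed=5)
        f.iloc[1] = f.iloc[0]  # exact duplicate pair
        res = cl.urf_dissimilarity(f, mtry=2, ntree=200, seed=1)
        assert res.dissimilarity[0, 1] < 0.1

    def test_correlates_with_euclidean_distance(self):
        f = blobs([0, 4, 8], n=8, seed=6)
        res = cl.urf_dissimilarity(f, mtry=2, ntree=200, seed=2)
        d_euc = pdist(cl.standardize(f))
        d_urf = squareform(res.dissimilarity, checks=False)
        rho, _ = spearmanr(d_euc, d_urf)
        assert rho > 0.5

    def test_deterministic_under_seed(self):
        f = blobs([0, 5], n=6, seed=7)
        a = cl.urf_dissimilarity(f, mtry=2, ntree=50, seed=9)
        b = cl.urf_dissimilarity(f, mtry=2, ntree=50, seed=9)
        assert np.array_equal(a.dissimilarity, b.dissimilarity)
        assert a.oob_error == b.oob_error

    def test_mtry_beyond_features_rejected(self):
        f = blobs([0, 1], n=5, seed=8)
        with pytest.raises(ValueError):
            cl.urf_dissimilarity(f, mtry=9)


class TestTuneMtry:
    def test_pure_noise_near_chance(self):
        rng = np.random.default_rng(10)
        f = pd.DataFrame(rng.normal(size=(40, 6)))
        f.columns = [f"f{i}" for i in range(6)]
        _, errors = cl.tune_mtry(f, mtry_range=range(1, 5), ntree=60, seed=3)
        for e in errors.values():
            assert 35.0 <= e <= 65.0

    def test_structured_data_low_error(self):
        # strongly clustered rows: real joint structure is easily told apart
        # from the column-permuted synthetic copy
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(c, 0.3, size=(20, 8)) for c in (0, 5, 10)])
        f = pd.DataFrame(X, columns=[f"f{i}" for i in range(8)])
        best, errors = cl.tune_mtry(f, mtry_range=range(1, 6), ntree=100, seed=4)
        assert errors[best] < 15.0

    def test_deterministic_and_tie_break(self):
        rng = np.random.default_rng(12)
        f = pd.DataFrame(rng.normal(size=(30, 5)))
        f.columns = [f"f{i}" for i in range(5)]
        a = cl.tune_mtry(f, mtry_range=range(1, 4), ntree=40, seed=5)
        b = cl.tune_mtry(f, mtry_range=range(1, 4), ntree=40, seed=5)
        assert a == b


class TestImportance:
    def test_constant_feature_has_zero_mdg(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame({"flat": np.ones(40),
                          "good": np.r_[rng.normal(0, 1, 20), rng.normal(8, 1, 20)]})
        y = np.repeat([0, 1], 20)
        imp = cl.class_specific_importance(X, y, ntree=100, mtry=2, seed=0)
        assert imp.loc["flat", "MDG"] == pytest.approx(0.0)
        assert imp.loc["flat", "MDA_overall"] == pytest.approx(0.0)

    def test_separating_feature_dominates(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(60, 5)),
                         columns=[f"n{i}" for i in range(5)])
        X["signal"] = np.repeat([0.0, 6.0, 12.0], 20) + rng.normal(0, 0.3, 60)
        y = np.repeat([0, 1, 2], 20)
        imp = cl.class_specific_importance(X, y, ntree=200, mtry=2, seed=1)
        assert imp["MDG"].idxmax() == "signal"
        assert imp["MDA_overall"].idxmax() == "signal"

    def test_mdg_non_negative(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        X.columns = [f"f{i}" for i in range(4)]
        y = rng.integers(0, 2, 30)
        imp = cl.class_specific_importance(X, y, ntree=50, seed=2)
        assert (imp["MDG"] >= 0).all()


class TestSelectFeatures:
    def test_clear_gap_selects_upper_segment(self):
        mdg = pd.Series([1.0, 1.1, 1.2, 6.0, 7.0],
                        index=list("abcde"))
        selected, split = cl.select_features(mdg)
        assert set(selected) == {"d", "e"}

    def test_exhaustive_split_oracle(self):
        rng = np.random.default_rng(16)
        v = np.sort(rng.uniform(0, 10, 9))
        mdg = pd.Series(v, index=[f"f{i}" for i in range(9)])
        selected, split = cl.select_features(mdg)
        # brute-force: best single split by within-segment SSE
        def sse(seg):
            return ((seg - seg.mean()) ** 2).sum()
        best = min(range(1, 9), key=lambda s: sse(v[:s]) + sse(v[s:]))
        assert split == best
        assert set(selected) == set(mdg.index[best:])

    def test_two_features(self):
        selected, _ = cl.select_features(pd.Series([1.0, 10.0, 1.2],
                                                   index=list("abc")))
        assert selected == ["b"]

    def test_translation_invariance(self):
        mdg = pd.Series([0.5, 0.6, 3.0, 3.3], index=list("abcd"))
        s1, _ = cl.select_features(mdg)
        s2, _ = cl.select_features(mdg + 100.0)
        assert set(s1) == set(s2)

    def test_constant_vector_warns_and_returns_all(self):
        mdg = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        with pytest.warns(UserWarning):
            selected, split = cl.select_features(mdg)
        assert set(selected) == {"a", "b", "c"}
        assert split is None

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            cl.select_features(pd.Series([1.0, 2.0], index=list("ab")))
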