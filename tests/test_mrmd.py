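import numpy as np
import pytest

from seqsvm.matrix import LabeledFeatureMatrix
from seqsvm.mrmd import (
    MRMDSelector,
    choose_m_by_cv,
    distance_scores,
    pearson_correlation,
    rank_features,
    relevance_scores,
    scores_table,
    select_top,
)


def brute_force_scores(X, orientation="distance"):
    """O(M^2) double-loop recomputation of ED/COS/TC on min-max
    normalized columns — the independent oracle."""
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    F = (X - lo) / span
    M = F.shape[1]
    ED = np.zeros(M)
    COS = np.zeros(M)
    TC = np.zeros(M)
    for i in range(M):
        for k in range(M):
            if k == i:
                continue
            fi, fk = F[:, i], F[:, k]
            ED[i] += np.sqrt(np.sum((fi - fk) ** 2))
            ni, nk = np.sqrt(fi @ fi), np.sqrt(fk @ fk)
            if ni == 0 or nk == 0:
                cos_sim = 0.0
                tc_sim = 0.0
            else:
                cos_sim = (fi @ fk) / (ni * nk)
                tc_sim = (fi @ fk) / (fi @ fi + fk @ fk - fi @ fk)
            if orientation == "distance":
                COS[i] += 1.0 - cos_sim
                TC[i] += 1.0 - tc_sim
            else:
                COS[i] += cos_sim
                TC[i] += tc_sim
    ED /= M - 1
    COS /= M - 1
    TC /= M - 1
    return ED, COS, TC, (ED + COS + TC) / 3.0


def lfm_from(X, y):
    X = np.asarray(X, dtype=float)
    return LabeledFeatureMatrix(
        X=X, y=np.asarray(y), feature_names=[f"f{i}" for i in range(X.shape[1])]
    )


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_correlation(x, x) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=10)
            assert pearson_correlation(x, y) == pytest.approx(
                np.corrcoef(x, y)[0, 1], abs=1e-12
            )

    def test_constant_input_returns_zero(self):
        assert pearson_correlation([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2, 3])


class TestRelevance:
    def test_label_copy_has_unit_relevance(self):
        y = np.array([1, 1, -1, -1, 1, -1])
        X = np.column_stack([y.astype(float), np.zeros(6)])
        mr = relevance_scores(X, y)
        assert mr[0] == pytest.approx(1.0)
        assert mr[1] == 0.0  # constant feature

    def test_sign_is_discarded(self):
        y = np.array([1, -1, 1, -1])
        X = (-y.astype(float)).reshape(-1, 1)
        assert relevance_scores(X, y)[0] == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            relevance_scores(np.ones((4, 2)), np.ones(4))

    def test_informative_beats_noise(self):
        # class-shifted column vs pure noise: MR separates them reliably
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.array([1] * 100 + [-1] * 100)
            informative = y + rng.normal(0, 1.0, 200)
            noise = rng.normal(size=200)
            mr = relevance_scores(np.column_stack([informative, noise]), y)
            wins += mr[0] > mr[1]
        assert wins >= 19


class TestDistance:
    def test_identical_columns_zero_distance(self):
        X = np.array([[1.0, 1.0], [0.5, 0.5], [0.0, 0.0]])
        ED, COS, TC, MD = distance_scores(X)
        np.testing.assert_allclose([ED, COS, TC, MD], 0.0, atol=1e-12)

    def test_orthogonal_indicator_columns(self):
        # (1,0) vs (0,1) over two samples: Euclidean distance sqrt(2)
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        ED, COS, TC, MD = distance_scores(X)
        np.testing.assert_allclose(ED, np.sqrt(2.0), atol=1e-12)
        np.testing.assert_allclose(COS, 1.0, atol=1e-12)  # orthogonal
        np.testing.assert_allclose(TC, 1.0, atol=1e-12)

    @pytest.mark.parametrize("orientation", ["distance", "similarity"])
    def test_oracle_equivalence_random_matrices(self, orientation):
        rng = np.random.default_rng(42)
        for _ in range(10):
            N = int(rng.integers(3, 13))
            M = int(rng.integers(2, 9))
            X = rng.uniform(size=(N, M))
            got = distance_scores(X, md_orientation=orientation)
            want = brute_force_scores(X, orientation=orientation)
            for g, w in zip(got, want):
                np.testing.assert_allclose(g, w, atol=1e-10)

    def test_zero_norm_column_warns(self):
        X = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 0.5]])
        with pytest.warns(UserWarning, match="zero-norm"):
            ED, COS, TC, MD = distance_scores(X)
        assert np.isfinite(MD).all()

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            distance_scores(np.ones((3, 1)))


class TestRanking:
    def test_label_duplicate_outranks_constant(self):
        y = np.array([1, -1, 1, -1, 1, -1])
        X = np.column_stack([np.full(6, 0.5), y.astype(float)])
        ranking = rank_features(X, y)
        assert ranking.order[0] == 1

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(12, 6))
        y = np.array([1] * 6 + [-1] * 6)
        perm = np.array([3, 0, 5, 1, 4, 2])
        r1 = rank_features(X, y)
        r2 = rank_features(X[:, perm], y)
        # feature at new position j is old feature perm[j]
        np.testing.assert_array_equal(perm[r2.order], r1.order)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(10, 5))
        y = np.array([1] * 5 + [-1] * 5)
        shuffle = rng.permutation(10)
        r1 = rank_features(X, y)
        r2 = rank_features(X[shuffle], y[shuffle])
        np.testing.assert_array_equal(r1.order, r2.order)

    def test_ties_break_by_lower_index(self):
        y = np.array([1, -1, 1, -1])
        X = np.column_stack([y.astype(float), y.astype(float)])
        ranking = rank_features(X, y)
        assert list(ranking.order) == [0, 1]

    def test_scores_are_nonincreasing_along_order(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(size=(20, 8))
        y = np.array([1] * 10 + [-1] * 10)
        ranking = rank_features(X, y)
        totals = ranking.scores.total[ranking.order]
        assert (np.diff(totals) <= 1e-12).all()


class TestSelectTop:
    def test_m_equals_M_reorders_all_columns(self):
        rng = np.random.default_rng(1)
        lfm = lfm_from(rng.uniform(size=(8, 4)), [1] * 4 + [-1] * 4)
        ranking = rank_features(lfm)
        out = select_top(lfm, ranking, 4)
        assert out.n_features == 4
        assert sorted(out.feature_names) == sorted(lfm.feature_names)

    def test_m_one_keeps_top_column(self):
        rng = np.random.default_rng(2)
        lfm = lfm_from(rng.uniform(size=(8, 4)), [1] * 4 + [-1] * 4)
        ranking = rank_features(lfm)
        out = select_top(lfm, ranking, 1)
        assert out.feature_names == [lfm.feature_names[ranking.order[0]]]

    def test_132_of_188(self):
        rng = np.random.default_rng(4)
        lfm = lfm_from(rng.uniform(size=(12, 188)), [1] * 6 + [-1] * 6)
        out = select_top(lfm, rank_features(lfm), 132)
        assert out.n_features == 132

    @pytest.mark.parametrize("m", [0, 5])
    def test_out_of_range_m_rejected(self, m):
        lfm = lfm_from(np.eye(4), [1, 1, -1, -1])
        with pytest.raises(ValueError):
            select_top(lfm, rank_features(lfm), m)


class TestChooseM:
    def _matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([1] * 15 + [-1] * 15)
        signal = y[:, None] * 2.0 + rng.normal(size=(30, 3))
        noise = rng.normal(size=(30, 5))
        return lfm_from(np.hstack([signal, noise]), y)

    def test_singleton_grid_returned(self):
        lfm = self._matrix()
        ranking = rank_features(lfm)
        assert choose_m_by_cv(lfm, ranking, [8], folds=3) == 8

    def test_deterministic_given_seed(self):
        lfm = self._matrix()
        ranking = rank_features(lfm)
        grid = [2, 4, 8]
        a = choose_m_by_cv(lfm, ranking, grid, folds=3, seed=9)
        b = choose_m_by_cv(lfm, ranking, grid, folds=3, seed=9)
        assert a == b

    def test_informative_subset_competitive_with_all(self):
        from seqsvm.svm import PipelineSpec, kfold_evaluate

        lfm = self._matrix(seed=1)
        ranking = rank_features(lfm)
        m = choose_m_by_cv(lfm, ranking, [3, 8], folds=3, seed=0)
        acc_m = kfold_evaluate(
            select_top(lfm, ranking, m), 3, PipelineSpec(), seed=0
        ).report.Acc
        acc_all = kfold_evaluate(lfm, 3, PipelineSpec(), seed=0).report.Acc
        assert acc_m >= acc_all - 0.02

    def test_empty_grid_rejected(self):
        lfm = self._matrix()
        with pytest.raises(ValueError):
            choose_m_by_cv(lfm, rank_features(lfm), [])


class TestSelectorEstimator:
    def test_transform_keeps_top_features(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 10 + [-1] * 10)
        X = np.column_stack([y.astype(float), rng.uniform(size=20), rng.uniform(size=20)])
        sel = MRMDSelector(n_features=1).fit(X, y)
        assert sel.transform(X).shape == (20, 1)
        assert sel.get_support()[0]

    def test_scores_table_has_rank_order(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(10, 4))
        y = np.array([1] * 5 + [-1] * 5)
        ranking = rank_features(X, y)
        df = scores_table(ranking, [f"f{i}" for i in range(4)])
        assert list(df["rank"]) == [1, 2, 3, 4]
        assert (df["total"].diff().dropna() <= 1e-12).all()

    def test_works_in_sklearn_pipeline(self):
        from sklearn.pipeline import make_pipeline
        from sklearn.svm import SVC

        rng = np.random.default_rng(6)
        y = np.array([1] * 15 + [-1] * 15)
        X = np.hstack([y[:, None] * 2.0 + rng.normal(size=(30, 2)), rng.normal(size=(30, 6))])
        pipe = make_pipeline(MRMDSelector(n_features=2), SVC())
        pipe.fit(X, y)
        assert pipe.score(X, y) > 0.9
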