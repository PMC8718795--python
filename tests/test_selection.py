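"""Fragment t-tests, distance logistic, F-score, mRMR, incremental selection."""

import numpy as np
import pytest

from timgo.selection import (
    fit_distance_logistic,
    fscore,
    fscore_select,
    incremental_selection,
    mrmr_rank,
    significant_fragments,
    weight_promoter_features,
)


class TestSignificantFragments:
    def test_extreme_separation_retained(self):
        rng = np.random.default_rng(0)
        pos = 10 + rng.normal(0, 0.5, size=(20, 1))
        neg = rng.normal(0, 0.5, size=(20, 1))
        filt = significant_fragments(pos, neg, ["frag"])
        assert filt.kept_fragments == ("frag",)

    def test_null_retention_near_alpha(self):
        """Identically distributed groups: ~alpha of 1,000 null fragments kept."""
        rng = np.random.default_rng(12345)
        pos = rng.poisson(3.0, size=(30, 1000)).astype(float)
        neg = rng.poisson(3.0, size=(30, 1000)).astype(float)
        filt = significant_fragments(pos, neg, [f"f{i}" for i in range(1000)])
        frac = len(filt.kept_indices) / 1000
        # binomial 3-sigma band around 0.05 at n=1000
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000) + 0.005

    def test_zero_variance_everywhere_dropped(self):
        pos = np.full((5, 2), 3.0)
        neg = np.hstack([np.full((5, 1), 3.0), np.zeros((5, 1))])
        filt = significant_fragments(pos, neg, ["same", "diff"])
        assert "same" not in filt.kept_fragments

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            significant_fragments(np.ones((1, 3)), np.ones((5, 3)), ["a", "b", "c"])

    def test_report_sorted_by_pvalue(self):
        rng = np.random.default_rng(1)
        pos = np.column_stack([rng.normal(5, 1, 30), rng.normal(1.0, 1, 30)])
        neg = np.column_stack([rng.normal(0, 1, 30), rng.normal(0, 1, 30)])
        df = significant_fragments(pos, neg, ["strong", "weak"]).to_frame()
        assert list(df["pvalue"]) == sorted(df["pvalue"])


class TestDistanceLogistic:
    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(7)
        beta0, beta1, n = 1.5, -1e-4, 400
        d = rng.uniform(200, 40_000, size=n)
        p = 1 / (1 + np.exp(-(beta0 + beta1 * d)))
        y = (rng.random(n) < p).astype(int)
        model = fit_distance_logistic(d, y)
        assert abs(model.slope - beta1) < 3 * model.slope_se
        assert abs(model.intercept - beta0) < 3 * model.intercept_se
        assert model.slope < 0

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single class"):
            fit_distance_logistic([100, 200, 300], [1, 1, 1])

    def test_probability_monotone_decreasing(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(100, 30_000, 300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(1.0 - 2e-4 * d)))).astype(int)
        model = fit_distance_logistic(d, y)
        probs = model.predict_proba(np.arange(0, 30_000, 500))
        assert (np.diff(probs) <= 0).all()


class TestWeighting:
    def _model(self):
        from timgo.selection import DistanceModel

        return DistanceModel(intercept=1.5, slope=-1e-4)

    def test_direction_preserved_norm_scaled(self):
        m = self._model()
        v = np.array([1.0, -2.0, 3.0])
        w1 = weight_promoter_features(v, m, 1_000)
        w30 = weight_promoter_features(v, m, 30_000)
        cos = w1 @ v / (np.linalg.norm(w1) * np.linalg.norm(v))
        assert np.isclose(cos, 1.0)
        ratio = np.linalg.norm(w1) / np.linalg.norm(w30)
        p1, p30 = m.predict_proba([1_000, 30_000])
        assert np.isclose(ratio, p1 / p30)

    def test_near_identity_at_zero_distance_large_intercept(self):
        from timgo.selection import DistanceModel

        m = DistanceModel(intercept=20.0, slope=-1e-4)
        v = np.ones(4)
        np.testing.assert_allclose(weight_promoter_features(v, m, 0), v, atol=1e-6)

    def test_zero_vector_unchanged(self):
        assert not weight_promoter_features(np.zeros(5), self._model(), 5_000).any()


class TestFScore:
    def test_label_column_dominates(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 20)
        X = np.column_stack([y.astype(float), rng.normal(size=40), np.full(40, 2.0)])
        f = fscore(X, y)
        assert f[0] == f.max() and f[2] == 0.0

    def test_hand_oracle_on_toy_matrix(self):
        X = np.array(
            [[1.0, 0.0], [2.0, 1.0], [3.0, 0.0], [10.0, 1.0], [11.0, 0.0]]
        )
        y = np.array([0, 0, 0, 1, 1])
        f = fscore(X, y)
        # column 0 by hand: means 5.4 overall, 2 (neg), 10.5 (pos)
        num = (10.5 - 5.4) ** 2 + (2 - 5.4) ** 2
        den = np.var([10, 11], ddof=1) + np.var([1, 2, 3], ddof=1)
        assert np.isclose(f[0], num / den)

    def test_select_returns_top_columns(self):
        y = np.repeat([0, 1], 10)
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.normal(size=20), y * 5.0 + rng.normal(0, 0.1, 20)])
        cols = fscore_select(X, y, top_fraction=0.5)
        assert cols.tolist() == [1]


class TestMRMR:
    def _toy(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 30)
        strong = y + rng.normal(0, 0.2, 60)
        dup = strong.copy()
        fresh = y + rng.normal(0, 0.6, 60)
        noise = rng.normal(size=60)
        return np.column_stack([strong, dup, fresh, noise]), y

    def test_duplicate_penalized_below_fresh_informative(self):
        X, y = self._toy()
        ranking = mrmr_rank(X, y)
        assert ranking[0] == 0  # max relevance first
        assert ranking.index(2) < ranking.index(1)  # fresh beats duplicate

    def test_noise_ranks_last_among_informative(self):
        X, y = self._toy()
        ranking = mrmr_rank(X[:, [0, 2, 3]], y)
        assert ranking[-1] == 2

    def test_ranking_invariant_to_column_order(self):
        X, y = self._toy()
        perm = [2, 0, 3, 1]
        r1 = mrmr_rank(X, y)
        r2 = mrmr_rank(X[:, perm], y)
        assert [perm[j] for j in r2] == r1


class TestIncrementalSelection:
    def test_perfect_first_column_gives_prefix_one(self):
        from sklearn.svm import SVC

        rng = np.random.default_rng(6)
        y = np.repeat([0, 1], 30)
        X = np.column_stack([y * 2.0 - 1.0] + [rng.normal(size=60) for _ in range(5)])
        best, accs = incremental_selection(
            X, y, list(range(6)), lambda: SVC(kernel="linear"), cv_folds=5, seed=0
        )
        assert best == 1 and accs[0] == 1.0

    def test_planted_signal_prefix_stays_small(self):
        from sklearn.svm import SVC

        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 40)
        informative = [y + rng.normal(0, 0.8, 80) for _ in range(5)]
        noise = [rng.normal(size=80) for _ in range(10)]
        X = np.column_stack(informative + noise)
        best, accs = incremental_selection(
            X, y, list(range(15)), lambda: SVC(), cv_folds=5, seed=0
        )
        assert best <= 8
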