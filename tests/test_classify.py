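"""Nested cross-validation bench: scaling, tuning, LOOCV bookkeeping."""

import numpy as np
import pytest

from stereovr.classify import (
    FoldTransform,
    SearchSpace,
    inner_cv_select,
    outer_loocv,
    rank_features,
    rescale_features,
    run_bench,
)
from stereovr.errors import StereoVRError, StratificationError


def _labels(n_a, n_b):
    return np.array(["control"] * n_a + ["postcovid"] * n_b, dtype=object)


def _separable(n_a=7, n_b=9, n_features=6, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    Xa = rng.normal(0.0, 1.0, (n_a, n_features))
    Xb = rng.normal(gap, 1.0, (n_b, n_features))
    return np.vstack([Xa, Xb]), _labels(n_a, n_b)


class TestRescaling:
    def test_basic_min_max(self):
        train = np.array([[2.0], [4.0]])
        tr, ev = rescale_features(train, np.array([[3.0]]))
        assert ev[0, 0] == pytest.approx(0.5)
        assert tr.min() == 0.0 and tr.max() == 1.0

    def test_out_of_range_not_clipped(self):
        train = np.array([[2.0], [4.0]])
        _, ev = rescale_features(train, np.array([[5.0]]))
        assert ev[0, 0] == pytest.approx(1.5)

    def test_constant_feature_maps_to_zero(self):
        train = np.array([[3.0], [3.0]])
        tr, ev = rescale_features(train, np.array([[7.0]]))
        assert (tr == 0).all() and (ev == 0).all()

    def test_imputation_uses_training_median_only(self):
        train = np.array([[1.0], [2.0], [3.0]])
        tf = FoldTransform(train)
        out = tf(np.array([[np.nan]]))
        assert out[0, 0] == pytest.approx((2.0 - 1.0) / (3.0 - 1.0))

    def test_holdout_outlier_cannot_change_transform(self):
        train = np.array([[0.0], [1.0]])
        tf = FoldTransform(train)
        before = tf(np.array([[0.5]]))[0, 0]
        _ = tf(np.array([[1e9]]))  # scoring an extreme held-out value
        after = tf(np.array([[0.5]]))[0, 0]
        assert before == after == pytest.approx(0.5)


class TestSearchSpaces:
    @pytest.mark.parametrize(
        "clf,size", [("svm_linear", 21), ("svm_rbf", 441), ("knn", 26), ("rf", 27)]
    )
    def test_grid_sizes(self, clf, size):
        assert len(SearchSpace.default(clf).grid) == size

    def test_svm_grid_is_powers_of_two(self):
        space = SearchSpace.default("svm_linear")
        cs = [g["C"] for g in space.grid]
        assert cs[0] == 2.0**-10 and cs[-1] == 2.0**10
        assert all(b / a == 2.0 for a, b in zip(cs, cs[1:]))

    def test_rf_fixed_parameters(self):
        space = SearchSpace.default("rf")
        assert space.fixed == {"n_estimators": 300, "max_features": "sqrt", "bootstrap": True}
        est = space.make_estimator(space.grid[0])
        assert est.random_state == 0


class TestInnerCV:
    def test_separable_data_reaches_perfect_inner_score(self):
        X, y = _separable()
        params, score = inner_cv_select(X, y, SearchSpace.default("knn"))
        assert score == 1.0

    def test_stratification_error_on_small_class(self):
        X, y = _separable(3, 9)  # 3 < 5 folds
        with pytest.raises(StratificationError):
            inner_cv_select(X, y, SearchSpace.default("knn"))

    def test_tie_break_is_first_in_grid(self):
        X, y = _separable()
        space = SearchSpace.default("svm_linear")
        params, score = inner_cv_select(X, y, space)
        # perfectly separable: many C values tie at 1.0; first winner kept
        firsts = [g for g in space.grid]
        scores = []
        for g in firsts:
            if g == params:
                break
            scores.append(g)
        # every grid point before the winner must score < 1.0
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        for g in scores:
            fold_scores = []
            for tr, te in skf.split(X, y):
                tf = FoldTransform(X[tr])
                est = space.make_estimator(g)
                est.fit(tf(X[tr]), y[tr])
                fold_scores.append(np.mean(est.predict(tf(X[te])) == y[te]))
            assert np.mean(fold_scores) < 1.0


class TestOuterLOOCV:
    def test_cohort_too_small(self):
        X, y = _separable(2, 3)
        with pytest.raises(StereoVRError):
            outer_loocv(X, y, SearchSpace.default("knn"))

    def test_identical_vectors_give_majority_rate(self):
        # constant features carry no signal: a depth-limited forest
        # falls back to the training majority class
        n_a, n_b = 6, 9
        X = np.zeros((n_a + n_b, 4))
        y = _labels(n_a, n_b)
        space = SearchSpace(
            "rf",
            grid=({"max_depth": 2, "min_samples_split": 2, "min_samples_leaf": 1},),
            fixed={"n_estimators": 25, "max_features": "sqrt", "bootstrap": True},
        )
        res = outer_loocv(X, y, space)
        assert res.accuracy == pytest.approx(n_b / (n_a + n_b))

    def test_confusion_rows_sum_to_class_counts(self):
        X, y = _separable(7, 9, gap=1.0, seed=3)
        res = outer_loocv(X, y, SearchSpace.default("knn"))
        conf = res.confusion
        assert conf.sum() == 16
        assert conf[0].sum() == 7 and conf[1].sum() == 9

    def test_accuracy_granularity(self):
        X, y = _separable(7, 9, gap=1.0, seed=4)
        res = outer_loocv(X, y, SearchSpace.default("knn"))
        steps = res.accuracy * 16
        assert steps == pytest.approx(round(steps))

    def test_separable_cohort_classified_perfectly(self):
        X, y = _separable(7, 9, gap=6.0)
        res = outer_loocv(X, y, SearchSpace.default("svm_linear"))
        assert res.accuracy == 1.0


class TestFeatureRanking:
    def test_label_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        y = _labels(8, 8)
        X = rng.normal(size=(16, 5))
        X[:, 3] = (y == "postcovid").astype(float)  # duplicates the label
        names = [f"f{i}" for i in range(5)]
        ranking = rank_features(X, y, names, top_k=5)
        assert ranking[0][0] == "f3"

    def test_output_length_and_tags(self):
        rng = np.random.default_rng(1)
        y = _labels(8, 8)
        X = rng.normal(size=(16, 12))
        X[:, 0] += 3 * (y == "postcovid")
        names = [f"f{i}" for i in range(12)]
        tags = {n: "stereo" for n in names}
        ranking = rank_features(X, y, names, groups=tags, top_k=10)
        assert len(ranking) == 10
        assert all(tag == "stereo" for _, tag, _ in ranking)

    def test_informative_beats_noise_across_seeds(self):
        from sklearn.ensemble import RandomForestClassifier

        def small_forest(Xt, yt):
            rf = RandomForestClassifier(n_estimators=60, random_state=0)
            rf.fit(Xt, yt)
            return rf.feature_importances_

        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = _labels(8, 8)
            X = rng.normal(size=(16, 6))
            X[:, 0] += 4 * (y == "postcovid")
            ranking = rank_features(
                X, y, [f"f{i}" for i in range(6)], importance_fn=small_forest
            )
            if ranking[0][0] == "f0":
                wins += 1
        assert wins >= 9


class TestBench:
    def test_cells_and_determinism(self):
        X, y = _separable(7, 9, n_features=8, gap=3.0)
        names = [f"f{i}" for i in range(8)]
        tags = {n: ("stereo" if i < 4 else "gaze") for i, n in enumerate(names)}
        rep1 = run_bench(X, y, names, tags, groups=["stereo", "gaze"],
                         classifiers=["knn"], rank=False)
        rep2 = run_bench(X, y, names, tags, groups=["stereo", "gaze"],
                         classifiers=["knn"], rank=False)
        assert set(rep1["cells"]) == {"knn/stereo", "knn/gaze"}
        assert rep1 == rep2
        for cell in rep1["cells"].values():
            assert np.array(cell["confusion"]).sum() == 16
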