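import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from fcdmvpa.mvpa import (
    FoldResult,
    build_weight_map,
    classification_report,
    fit_linear_svm,
    loocv_classify,
    permutation_test,
    rank_region_weights,
    select_features,
)


def svm_dual_objective_oracle(X, y, C):
    """Independent soft-margin SVM solve via the dual QP (SLSQP), returning
    the primal objective 0.5||w||^2 + C sum(xi)."""
    n = len(y)
    K = (X * y[:, None]) @ (X * y[:, None]).T

    def neg_dual(a):
        return 0.5 * a @ K @ a - a.sum()

    cons = {"type": "eq", "fun": lambda a: a @ y}
    res = optimize.minimize(
        neg_dual,
        np.full(n, C / 2),
        constraints=cons,
        bounds=[(0, C)] * n,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    a = res.x
    w = ((a * y)[:, None] * X).sum(0)
    sv = (a > 1e-8) & (a < C - 1e-8)
    b = np.mean(y[sv] - X[sv] @ w) if sv.any() else 0.0
    xi = np.maximum(0, 1 - y * (X @ w + b))
    return 0.5 * w @ w + C * xi.sum(), w, b


def toy_features(rng, n=12, v=30, gap=4.0, signal_voxels=(3,)):
    y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    X = rng.normal(size=(n, v))
    for sv in signal_voxels:
        X[y == "A", sv] += gap
    return X, y


class TestSelectFeatures:
    def test_identical_maps_trigger_fallback(self):
        X = np.ones((10, 250))
        y = np.array([1] * 5 + [-1] * 5)
        with pytest.warns(UserWarning, match="falling back"):
            idx = select_features(X, y)
        assert len(idx) == 100

    def test_injected_voxel_always_selected(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            X, labels = toy_features(rng, n=16, gap=5.0, signal_voxels=(7,))
            y = np.where(labels == "A", 1, -1)
            assert 7 in select_features(X, y)

    def test_vacuous_threshold_selects_everything(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 40))
        y = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        assert len(select_features(X, y, alpha=1.0)) == 40


class TestLinearSvm:
    def test_separable_pair_textbook_solution(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        w, b = fit_linear_svm(X, y, C=1e6)
        assert w[0] == pytest.approx(1.0, abs=1e-6)  # margin 2/||w|| = 2
        assert b == pytest.approx(0.0, abs=1e-6)
        assert np.sign(X @ w + b).tolist() == [-1, 1]

    def test_label_flip_negates_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        y = np.array([1, -1] * 5)
        w1, b1 = fit_linear_svm(X, y)
        w2, b2 = fit_linear_svm(X, -y)
        assert np.allclose(w1, -w2, atol=1e-5)
        assert b1 == pytest.approx(-b2, abs=1e-5)

    def test_objective_matches_qp_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 2))
        y = np.array([1] * 5 + [-1] * 5)
        X[:5] += 1.5
        w, b = fit_linear_svm(X, y, C=1.0)
        xi = np.maximum(0, 1 - y * (X @ w + b))
        obj = 0.5 * w @ w + 1.0 * xi.sum()
        obj_oracle, _, _ = svm_dual_objective_oracle(X, y, 1.0)
        assert obj == pytest.approx(obj_oracle, abs=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_svm(np.zeros((4, 2)), np.ones(4))


class TestLoocv:
    def test_one_fold_per_subject(self):
        rng = np.random.default_rng(4)
        X, y = toy_features(rng, n=10)
        folds = loocv_classify(X, y)
        assert len(folds) == 10
        assert [f.subject_index for f in folds] == list(range(10))

    def test_strong_signal_classifies_all_folds(self):
        rng = np.random.default_rng(5)
        X, y = toy_features(rng, n=12, gap=8.0, signal_voxels=(3, 4, 5))
        folds = loocv_classify(X, y)
        assert all(f.correct for f in folds)

    def test_matches_hand_scripted_loop(self):
        rng = np.random.default_rng(6)
        X, labels = toy_features(rng, n=6, v=15, gap=3.0)
        y = np.where(labels == "A", 1, -1)
        folds = loocv_classify(X, labels, alpha=0.5)
        for i, fold in enumerate(folds):
            tr = np.delete(np.arange(6), i)
            p = stats.ttest_ind(
                X[tr][y[tr] == 1], X[tr][y[tr] == -1]
            ).pvalue
            sel = np.flatnonzero(p < 0.5)
            assert np.array_equal(fold.selected_voxels, sel)
            mu = X[tr][:, sel].mean(0)
            w, b = fit_linear_svm(X[tr][:, sel] - mu, y[tr])
            d = w @ (X[i, sel] - mu) + b
            assert fold.decision_value == pytest.approx(d, abs=1e-10)

    def test_no_leakage_from_held_out_subject(self):
        rng = np.random.default_rng(7)
        X, y = toy_features(rng, n=10)
        folds = loocv_classify(X, y)
        X2 = X.copy()
        X2[4] = 1e6  # absurd held-out values
        folds2 = loocv_classify(X2, y)
        assert np.array_equal(folds[4].selected_voxels, folds2[4].selected_voxels)
        assert np.allclose(folds[4].weights, folds2[4].weights)

    def test_small_or_single_class_inputs_rejected(self):
        with pytest.raises(ValueError):
            loocv_classify(np.zeros((3, 5)), ["A", "B", "A"])
        with pytest.raises(ValueError):
            loocv_classify(np.zeros((6, 5)), ["A"] * 5 + ["B"])


def _folds_from_confusion(tp, fn, fp, tn, d_correct=2.0):
    folds = []
    i = 0
    for true, pred, count in [
        (1, 1, tp), (1, -1, fn), (-1, 1, fp), (-1, -1, tn),
    ]:
        for _ in range(count):
            folds.append(
                FoldResult(i, true, pred, float(pred) * d_correct, np.array([0]), np.array([0.0]), 0.0)
            )
            i += 1
    return folds


class TestClassificationReport:
    def test_reference_confusion_metrics(self):
        rep = classification_report(_folds_from_confusion(16, 4, 1, 25))
        assert round(100 * rep.accuracy, 2) == 89.13
        assert round(100 * rep.balanced_accuracy, 2) == 88.08
        assert round(100 * rep.sensitivity, 2) == 80.00
        assert round(100 * rep.specificity, 2) == 96.15

    def test_perfect_predictions(self):
        rep = classification_report(_folds_from_confusion(5, 0, 0, 7))
        assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0
        assert rep.auc == 1.0

    def test_all_predicted_positive(self):
        rep = classification_report(_folds_from_confusion(5, 0, 7, 0))
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0
        assert rep.balanced_accuracy == 0.5

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 15), fn=st.integers(0, 15),
        fp=st.integers(0, 15), tn=st.integers(0, 15),
    )
    def test_metric_identities_hold_for_any_confusion(self, tp, fn, fp, tn):
        if tp + fn == 0 or fp + tn == 0:
            return
        rep = classification_report(_folds_from_confusion(tp, fn, fp, tn))
        assert rep.tp + rep.fn == tp + fn
        assert rep.accuracy == pytest.approx((tp + tn) / (tp + fn + fp + tn))
        assert rep.balanced_accuracy == pytest.approx(
            0.5 * (tp / (tp + fn) + tn / (fp + tn))
        )
        assert 0.0 <= rep.auc <= 1.0

    def test_auc_equals_mann_whitney_u(self):
        rng = np.random.default_rng(8)
        y = np.array([1] * 9 + [-1] * 11)
        d = rng.normal(size=20) + 0.8 * (y == 1)
        folds = [
            FoldResult(i, int(y[i]), 1 if d[i] > 0 else -1, float(d[i]),
                       np.array([0]), np.array([0.0]), 0.0)
            for i in range(20)
        ]
        rep = classification_report(folds)
        u = stats.mannwhitneyu(d[y == 1], d[y == -1], alternative="two-sided").statistic
        assert rep.auc == pytest.approx(u / (9 * 11), abs=1e-12)


class TestPermutationTest:
    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(9)
        X, y = toy_features(rng, n=10, gap=10.0, signal_voxels=(0, 1))
        p, perm = permutation_test(X, y, n_perm=19, seed=0)
        assert len(perm) == 19
        # perfect signal: observed accuracy 1.0 beats or ties permutations
        assert p <= (1 + np.sum(perm >= 1.0)) / 20
        assert p >= 1 / 20

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(10)
        X, y = toy_features(rng, n=8, gap=0.0)
        p1, s1 = permutation_test(X, y, n_perm=15, seed=42)
        p2, s2 = permutation_test(X, y, n_perm=15, seed=42)
        assert p1 == p2 and np.array_equal(s1, s2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.zeros((6, 4)), ["A", "A", "A", "B", "B", "B"], n_perm=0)
        with pytest.raises(ValueError):
            permutation_test(
                np.zeros((6, 4)), ["A", "A", "A", "B", "B", "B"], n_perm=5, stat="f1"
            )


class TestWeightMap:
    def test_identical_folds_equal_single_back_projection(self):
        mask = np.ones((2, 2, 1), bool)
        folds = [
            FoldResult(i, 1, 1, 1.0, np.array([0, 2]), np.array([0.5, -1.0]), 0.0)
            for i in range(3)
        ]
        wmap = build_weight_map(folds, mask)
        assert wmap[0, 0, 0] == 0.5 and wmap[1, 0, 0] == -1.0
        assert wmap[0, 1, 0] == 0.0

    def test_half_selected_voxel_averages(self):
        mask = np.ones((2, 1, 1), bool)
        folds = [
            FoldResult(0, 1, 1, 1.0, np.array([0]), np.array([1.0]), 0.0),
            FoldResult(1, 1, 1, 1.0, np.array([1]), np.array([1.0]), 0.0),
        ]
        wmap = build_weight_map(folds, mask)
        assert wmap[0, 0, 0] == 0.5 and wmap[1, 0, 0] == 0.5

    def test_empty_selection_warns_all_zero(self):
        mask = np.ones((2, 1, 1), bool)
        folds = [FoldResult(0, 1, 1, 1.0, np.array([], int), np.array([]), 0.0)]
        with pytest.warns(UserWarning, match="all-zero"):
            wmap = build_weight_map(folds, mask)
        assert not wmap.any()


class TestRegionRanking:
    def test_single_region_holds_everything(self):
        wmap = np.array([[[1.0, -2.0]]])
        atlas = np.array([[[3, 3]]])
        table, top = rank_region_weights(wmap, atlas, top_k=5)
        assert table["percent"].iloc[0] == 100.0 and top == 100.0

    def test_equal_split(self):
        wmap = np.array([[[2.0, -2.0]]])
        atlas = np.array([[[1, 2]]])
        table, top1 = rank_region_weights(wmap, atlas, top_k=1)
        assert np.allclose(table["percent"], [50.0, 50.0])
        assert top1 == 50.0

    def test_share_arithmetic(self):
        wmap = np.array([[[3.0, 1.0, -2.0]]])
        atlas = np.array([[[1, 1, 2]]])
        table, top1 = rank_region_weights(wmap, atlas, top_k=1)
        assert table.iloc[0]["id"] == 1
        assert table.iloc[0]["percent"] == pytest.approx(66.6667, abs=1e-3)
        assert table.iloc[1]["percent"] == pytest.approx(33.3333, abs=1e-3)
        assert top1 == pytest.approx(66.6667, abs=1e-3)
        assert table["percent"].sum() == pytest.approx(100.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            rank_region_weights(np.zeros((2, 2, 2)), np.zeros((3, 3, 3), int))
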