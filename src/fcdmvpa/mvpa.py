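"""Linear-SVM multivariate pattern analysis on FCD maps.

The classifier pipeline follows the standard nested MVPA recipe: within each
leave-one-out fold, voxels are selected by a two-sample t-test (p < alpha) on
the *training* subjects only, features are mean-centered with training
statistics, a soft-margin linear SVM (C = 1) is fit, and the held-out subject
is scored by its signed decision value. Significance of the cross-validated
accuracy (or AUC) is assessed by rerunning the entire pipeline — including
feature selection — under uniformly random label permutations, with
p = (1 + #{permuted >= observed}) / (n_perm + 1). Fold weight vectors are
back-projected to a voxel weight map (mean over folds, zero where never
selected) and aggregated over atlas regions by summed absolute weight.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

__all__ = [
    "FoldResult",
    "ClassificationReport",
    "stack_maps",
    "select_features",
    "fit_linear_svm",
    "loocv_classify",
    "classification_report",
    "permutation_test",
    "build_weight_map",
    "rank_region_weights",
]

logger = logging.getLogger(__name__)

FALLBACK_K = 100  # voxels kept when no voxel clears the selection threshold


@dataclass
class FoldResult:
    """One leave-one-out fold: held-out prediction plus fold provenance."""

    subject_index: int
    true_label: int  # +1 positive class, -1 negative
    predicted_label: int
    decision_value: float
    selected_voxels: np.ndarray
    weights: np.ndarray
    bias: float

    @property
    def correct(self) -> bool:
        return self.predicted_label == self.true_label


@dataclass
class ClassificationReport:
    """Cross-validated classifier performance."""

    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    roc_points: np.ndarray  # (k, 2) of (fpr, tpr)
    auc: float | None
    permutation_p: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_dict(self) -> dict:
        d = {
            "confusion": {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn},
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "permutation_p": self.permutation_p,
        }
        return d


def stack_maps(maps, mask: np.ndarray) -> np.ndarray:
    """Stack per-subject 3D maps (or FcdMap objects) into subjects x voxels."""
    rows = []
    mask = np.asarray(mask, bool)
    for m in maps:
        data = m.data if hasattr(m, "data") else np.asarray(m)
        rows.append(data[mask])
    return np.asarray(rows, float)


def _signed_labels(labels, positive_label) -> np.ndarray:
    y = np.where(np.asarray(labels) == positive_label, 1, -1)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def _train_t_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized pooled two-sample t-test p per column (feature)."""
    pos, neg = y == 1, y == -1
    n1, n2 = int(pos.sum()), int(neg.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("feature selection needs >= 2 training subjects per class")
    m1, m2 = X[pos].mean(axis=0), X[neg].mean(axis=0)
    v1 = X[pos].var(axis=0, ddof=1)
    v2 = X[neg].var(axis=0, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    return 2.0 * stats.t.sf(np.abs(t), df)


def select_features(
    train_X: np.ndarray, train_y: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Voxels discriminating the training groups at p < alpha (two-sample t).

    If nothing clears the threshold the ``FALLBACK_K`` smallest-p voxels are
    kept with a warning, so downstream folds always have features.
    """
    p = _train_t_pvalues(np.asarray(train_X, float), np.asarray(train_y))
    idx = np.flatnonzero(p < alpha)
    if idx.size == 0:
        k = min(FALLBACK_K, p.size)
        idx = np.sort(np.argsort(p, kind="stable")[:k])
        warnings.warn(
            f"no voxel passed p<{alpha}; falling back to the {k} smallest-p voxels",
            stacklevel=2,
        )
    return idx


def fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> tuple[np.ndarray, float]:
    """Soft-margin linear SVM; returns the primal weight vector and bias.

    The decision value is ``w . x + b``; its sign is the predicted class.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    clf = SVC(kernel="linear", C=C, tol=1e-6)
    clf.fit(np.asarray(X, float), y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def loocv_classify(
    X: np.ndarray,
    labels,
    alpha: float = 0.05,
    C: float = 1.0,
    positive_label="A",
) -> list[FoldResult]:
    """Leave-one-out cross-validation with nested feature selection.

    Each fold selects voxels and computes centering statistics from the
    n - 1 training subjects only; the held-out subject never influences its
    own fold's features or weights.
    """
    X = np.asarray(X, float)
    y = _signed_labels(labels, positive_label)
    n = X.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    if min((y == 1).sum(), (y == -1).sum()) < 2:
        raise ValueError("each class needs at least 2 subjects")
    folds: list[FoldResult] = []
    train_mask = np.ones(n, dtype=bool)
    for i in range(n):
        train_mask[i] = False
        Xtr, ytr = X[train_mask], y[train_mask]
        sel = select_features(Xtr, ytr, alpha=alpha)
        mu = Xtr[:, sel].mean(axis=0)
        w, b = fit_linear_svm(Xtr[:, sel] - mu, ytr, C=C)
        d = float(w @ (X[i, sel] - mu) + b)
        folds.append(
            FoldResult(
                subject_index=i,
                true_label=int(y[i]),
                predicted_label=1 if d > 0 else -1,
                decision_value=d,
                selected_voxels=sel,
                weights=w,
                bias=b,
            )
        )
        train_mask[i] = True
    return folds


def classification_report(fold_results: list[FoldResult]) -> ClassificationReport:
    """Pool held-out predictions into confusion metrics and a ROC/AUC.

    The ROC is built from the signed decision values pooled over folds
    (threshold sweep over unique values, trapezoid AUC — equivalently the
    Mann-Whitney statistic with ties counting one half).
    """
    y = np.array([f.true_label for f in fold_results])
    pred = np.array([f.predicted_label for f in fold_results])
    d = np.array([f.decision_value for f in fold_results])
    tp = int(((y == 1) & (pred == 1)).sum())
    fn = int(((y == 1) & (pred == -1)).sum())
    fp = int(((y == -1) & (pred == 1)).sum())
    tn = int(((y == -1) & (pred == -1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    roc_points = np.empty((0, 2))
    auc_value: float | None = None
    if np.all(np.isfinite(d)):
        fpr, tpr, _ = roc_curve(y, d, pos_label=1)
        roc_points = np.column_stack([fpr, tpr])
        auc_value = float(_trapezoid_auc(fpr, tpr))
    else:
        warnings.warn("missing decision values; ROC/AUC omitted", stacklevel=2)
    return ClassificationReport(
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        accuracy=(tp + tn) / len(y),
        balanced_accuracy=0.5 * (sens + spec),
        sensitivity=sens,
        specificity=spec,
        roc_points=roc_points,
        auc=auc_value,
    )


def _loocv_statistic(X, labels, alpha, C, positive_label, stat: str) -> float:
    folds = loocv_classify(X, labels, alpha=alpha, C=C, positive_label=positive_label)
    report = classification_report(folds)
    return report.accuracy if stat == "accuracy" else float(report.auc)


def permutation_test(
    X: np.ndarray,
    labels,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    C: float = 1.0,
    positive_label="A",
    stat: str = "accuracy",
    observed: float | None = None,
) -> tuple[float, np.ndarray]:
    """Label-permutation significance of the cross-validated statistic.

    Every permutation reruns the entire nested pipeline (feature selection
    included). Returns ``(p, permuted_statistics)`` with
    p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if stat not in ("accuracy", "auc"):
        raise ValueError("stat must be 'accuracy' or 'auc'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels)
    if observed is None:
        observed = _loocv_statistic(X, labels, alpha, C, positive_label, stat)
    perm_stats = np.empty(n_perm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fallback-selection warnings are expected under null
        for b in range(n_perm):
            perm = rng.permutation(labels)
            while len(np.unique(perm)) < 2:  # cannot happen for 2-group input, guard anyway
                perm = rng.permutation(labels)
            perm_stats[b] = _loocv_statistic(X, perm, alpha, C, positive_label, stat)
    p = (1.0 + np.sum(perm_stats >= observed)) / (n_perm + 1.0)
    return float(p), perm_stats


def build_weight_map(
    fold_results: list[FoldResult], mask: np.ndarray
) -> np.ndarray:
    """Back-project fold weight vectors to the voxel grid.

    A voxel's value is the mean over folds of its weight, counting 0 in folds
    where it was not selected; voxels never selected stay exactly 0.
    """
    mask = np.asarray(mask, bool)
    n_vox = int(mask.sum())
    total = np.zeros(n_vox)
    for f in fold_results:
        total[f.selected_voxels] += f.weights
    total /= len(fold_results)
    if not np.any(total):
        warnings.warn("all-zero weight map: no voxel was ever selected", stacklevel=2)
    out = np.zeros(mask.shape)
    out[mask] = total
    return out


def rank_region_weights(
    weight_map: np.ndarray,
    atlas: np.ndarray,
    names: dict[int, str] | None = None,
    top_k: int = 20,
) -> tuple[pd.DataFrame, float]:
    """Aggregate |voxel weights| over atlas regions and rank by share.

    Returns the ranked table (rank, id, name, weight, percent,
    cumulative_percent) over regions with nonzero weight, and the cumulative
    percentage captured by the first ``top_k`` regions.
    """
    atlas = np.asarray(atlas)
    if atlas.shape != np.asarray(weight_map).shape:
        raise ValueError("atlas grid does not match the weight map grid")
    ids = np.unique(atlas)
    ids = ids[ids > 0]
    scores = {int(r): float(np.abs(weight_map[atlas == r]).sum()) for r in ids}
    total = sum(scores.values())
    if total == 0:
        raise ValueError("weight map is all zero within the atlas")
    rows = []
    for r, s in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])):
        if s == 0:
            continue
        rows.append(
            {
                "id": r,
                "name": (names or {}).get(r, f"region_{r}"),
                "weight": s,
                "percent": 100.0 * s / total,
            }
        )
    table = pd.DataFrame(rows)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    table["cumulative_percent"] = table["percent"].cumsum()
    k = min(top_k, len(table))
    top_cum = float(table["cumulative_percent"].iloc[k - 1]) if k else 0.0
    return table, top_cum
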