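"""Group-level statistics: voxelwise covariate-adjusted comparison of FCD
maps and the demographic/clinical table tests.

The voxelwise model is an ordinary least-squares fit per gray-matter voxel,

    FCD ~ intercept + group + age + gender + education,

whose group-coefficient t statistic (two-sided Student-t p, df = n - p) is
the unpaired covariate-adjusted group test. With no covariates it reduces
exactly to the classic pooled two-sample t-test. Demographic rows use pooled
(or Welch) t for continuous summaries and chi-square (with or without Yates
continuity correction) or Fisher's exact test for 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VoxelStatMap",
    "voxelwise_group_glm",
    "significance_mask",
    "two_sample_t_from_summary",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "table1_report",
]


@dataclass
class VoxelStatMap:
    """Voxelwise group-contrast t and p maps (NaN outside the mask)."""

    t: np.ndarray
    p: np.ndarray
    df: int
    mask: np.ndarray
    design_columns: list[str]


def _design_matrix(
    labels: np.ndarray, covariates: pd.DataFrame | None, positive_label
) -> tuple[np.ndarray, list[str]]:
    group = (np.asarray(labels) == positive_label).astype(float)
    cols = [np.ones(len(group)), group]
    names = ["intercept", "group"]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object or str(col.dtype) == "category":
                # gender-style binary factor -> 0/1 indicator
                levels = sorted(col.unique())
                if len(levels) > 2:
                    raise ValueError(f"covariate {name!r} has >2 levels; encode it numerically")
                cols.append((col == levels[-1]).to_numpy(float))
            else:
                cols.append(col.to_numpy(float))
            names.append(name)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"collinear design columns: {bad}")
    return X, names


def voxelwise_group_glm(
    maps: np.ndarray,
    labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
    mask: np.ndarray | None = None,
    positive_label="A",
) -> VoxelStatMap:
    """Covariate-adjusted unpaired group comparison at every masked voxel.

    Parameters
    ----------
    maps
        Either a ``(n_subjects, ...grid)`` stack of 3D maps, or an
        ``(n_subjects, n_masked_voxels)`` matrix (then ``mask`` is required).
    labels
        Per-subject group labels; ``positive_label`` defines the contrast
        direction (positive t = that group higher).
    covariates
        Optional per-subject DataFrame (e.g. age, gender, education); a
        two-level object column is encoded as a 0/1 indicator.
    """
    maps = np.asarray(maps, float)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) != 2 or counts.min() < 2:
        raise ValueError("need exactly two groups with >= 2 subjects each")
    if maps.ndim == 2:
        if mask is None:
            raise ValueError("mask is required with a (subjects x voxels) matrix")
        Y = maps
    else:
        if mask is None:
            mask = np.ones(maps.shape[1:], bool)
        Y = maps[:, mask]
    mask = np.asarray(mask, bool)
    X, names = _design_matrix(labels, covariates, positive_label)
    n, k = X.shape
    df = n - k
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], np.finfo(float).tiny))
    t = beta[1] / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.maximum(p, np.finfo(float).tiny)
    t_map = np.full(mask.shape, np.nan)
    p_map = np.full(mask.shape, np.nan)
    t_map[mask], p_map[mask] = t, p
    return VoxelStatMap(t=t_map, p=p_map, df=df, mask=mask, design_columns=names)


def significance_mask(stat: VoxelStatMap, alpha: float = 0.05, correction: str = "none") -> np.ndarray:
    """Threshold the voxelwise p map: True where p strictly below alpha.

    Uncorrected by default; ``correction`` may be ``"fdr"``
    (Benjamini-Hochberg over masked voxels) or ``"bonferroni"``.
    """
    p = stat.p[stat.mask]
    if correction == "none":
        sig = p < alpha
    elif correction == "fdr":
        sig = stats.false_discovery_control(p, method="bh") < alpha
    elif correction == "bonferroni":
        sig = np.minimum(p * p.size, 1.0) < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out = np.zeros(stat.mask.shape, bool)
    out[stat.mask] = sig
    return out


def two_sample_t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float, pooled: bool = True
) -> tuple[float, float, float]:
    """Unpaired t-test from group summary statistics.

    Returns ``(t, df, p_two_sided)``; pooled-variance Student t by default,
    Welch otherwise. Two zero-variance groups with equal means give p = 1.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return float(np.inf) * np.sign(mean1 - mean2), float(n1 + n2 - 2), 0.0
    if pooled:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _check_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise ValueError("cell counts must be nonnegative integers")
        arr = arr.astype(int)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero margin")
    return arr


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test on a 2x2 table, optional Yates continuity
    correction; p from the chi-square distribution with 1 df."""
    arr = _check_table(table)
    stat, p, _, _ = stats.chi2_contingency(arr, correction=yates)
    return float(stat), float(p)


def fisher_exact_2x2(table) -> float:
    """Fisher's exact test, two-sided: sum of hypergeometric probabilities of
    all same-margin tables no more probable than the observed one."""
    arr = _check_table(table)
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def table1_report(
    continuous: dict[str, tuple[tuple[int, float, float], tuple[int, float, float]]] | None = None,
    tables: dict[str, tuple[np.ndarray, str]] | None = None,
) -> pd.DataFrame:
    """Demographics/clinical comparison table.

    ``continuous`` maps a variable name to ((n, mean, sd), (n, mean, sd));
    ``tables`` maps a name to (2x2 counts, test) with test one of
    ``"chi2"``, ``"chi2_yates"``, ``"fisher"``.
    """
    rows = []
    for name, (a, b) in (continuous or {}).items():
        t, df, p = two_sample_t_from_summary(*a, *b)
        rows.append(
            {
                "variable": name,
                "group_a": f"{a[1]:.2f} +/- {a[2]:.2f} (n={a[0]})",
                "group_b": f"{b[1]:.2f} +/- {b[2]:.2f} (n={b[0]})",
                "test": "pooled t",
                "statistic": round(t, 4),
                "p": round(p, 4),
            }
        )
    for name, (tab, test) in (tables or {}).items():
        arr = _check_table(tab)
        if test == "fisher":
            stat, p = float("nan"), fisher_exact_2x2(arr)
        elif test in ("chi2", "chi2_yates"):
            stat, p = chi_square_2x2(arr, yates=test == "chi2_yates")
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "variable": name,
                "group_a": f"{arr[0, 0]}/{arr[0, 1]}",
                "group_b": f"{arr[1, 0]}/{arr[1, 1]}",
                "test": test,
                "statistic": round(stat, 4) if np.isfinite(stat) else "",
                "p": round(p, 4),
            }
        )
    return pd.DataFrame(rows)
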