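"""End-to-end study runners on synthetic cohorts.

These functions wire the generator, temporal preprocessing, FCD mapping,
group statistics and MVPA into the three study designs the package validates
itself against:

* a *signal* study at the reference scale (20 vs 26 subjects, 24^3 grid,
  240 timepoints at TR 2.4 s) where the group coupling gap places group A's
  cross-hub population correlation above the 0.6 connection threshold and
  group B's below it — the classifier must recover the groups and the hub
  parcels;
* a *null MVPA calibration* at reduced spatial scale (12^3 grid, 8 parcels)
  with equal couplings, replicated to estimate the permutation-test false
  positive rate;
* a *type-I calibration* of the voxelwise GLM on null cohorts with many
  small parcels, pooling >= 10,000 voxel-tests.

The reduced scales keep replicated studies tractable on a single CPU while
preserving the statistical structure being checked (exchangeability under
the null does not depend on grid size).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .cohort import Cohort, CohortSpec, generate_cohort
from .fcd import FcdParams, compute_gfcd, normalize_fcd, smooth_fcd
from .groupstats import voxelwise_group_glm
from .mvpa import (
    build_weight_map,
    classification_report,
    loocv_classify,
    permutation_test,
    rank_region_weights,
)
from .preprocess import preprocess_series, threshold_gm_mask

__all__ = [
    "signal_cohort_spec",
    "null_cohort_spec",
    "type1_cohort_spec",
    "cohort_gfcd_features",
    "run_signal_study",
    "run_null_mvpa_study",
    "run_type1_study",
]

logger = logging.getLogger(__name__)


def signal_cohort_spec(seed: int = 0) -> CohortSpec:
    """The reference two-group cohort with a designed hub-coupling gap."""
    return CohortSpec(seed=seed)


def null_cohort_spec(seed: int = 0) -> CohortSpec:
    """Reduced-scale cohort with exchangeable groups (equal couplings).

    The voxel noise places the within-parcel population correlation near the
    0.6 connection threshold (c=1, sigma=0.85 gives rho ~ 0.58), so each
    subject's connectivity degree genuinely fluctuates. A null far above the
    threshold would saturate every count at parcel size - 1, leaving the
    classifier a degenerate constant-feature problem in which permutation
    statistics are all tied and no false positive rate can be estimated.
    """
    return CohortSpec(
        grid_shape=(12, 12, 12),
        n_parcels=8,
        hub_parcels=frozenset({1, 8}),
        coupling_a=1.0,
        coupling_b=1.0,
        noise_sd=0.85,
        seed=seed,
    )


def type1_cohort_spec(seed: int = 0) -> CohortSpec:
    """Reduced-scale null cohort with many small parcels, for voxelwise GLM
    calibration (more quasi-independent voxel-tests per cohort); noise as in
    :func:`null_cohort_spec` so per-voxel degrees vary across subjects."""
    return CohortSpec(
        grid_shape=(12, 12, 12),
        n_parcels=64,
        hub_parcels=frozenset({1, 64}),
        coupling_a=1.0,
        coupling_b=1.0,
        noise_sd=0.85,
        seed=seed,
    )


def cohort_gfcd_features(
    cohort: Cohort,
    params: FcdParams = FcdParams(),
    gm_threshold: float = 0.20,
    n_drop: int = 10,
    preprocess: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject normalized+smoothed gFCD over the gray-matter mask.

    Returns ``(X, mask)`` with ``X`` of shape (subjects, masked voxels), rows
    ordered as the cohort table. ``preprocess=False`` skips the temporal
    pipeline (used by calibration studies where the raw generative
    correlation structure is the quantity of interest).
    """
    mask = threshold_gm_mask(cohort.gm_probability, gm_threshold)
    rows = []
    for sid in cohort.table["subject_id"]:
        series = cohort.series[sid]
        if preprocess:
            series = preprocess_series(series, cohort.motion[sid], cohort.masks, n_drop=n_drop)
        fmap = smooth_fcd(normalize_fcd(compute_gfcd(series, mask, params)))
        rows.append(fmap.data[mask])
    return np.asarray(rows), mask


def run_signal_study(
    seed: int = 0,
    n_perm: int = 199,
    alpha: float = 0.05,
    C: float = 1.0,
    top_k: int = 20,
) -> dict:
    """Full pipeline on the reference signal cohort.

    Returns the cohort, classification report (with permutation p), the
    back-projected weight map and the hub-parcel region ranking.
    """
    spec = signal_cohort_spec(seed)
    cohort = generate_cohort(spec)
    X, mask = cohort_gfcd_features(cohort)
    labels = cohort.labels
    folds = loocv_classify(X, labels, alpha=alpha, C=C, positive_label="A")
    report = classification_report(folds)
    p, perm_stats = permutation_test(
        X,
        labels,
        n_perm=n_perm,
        seed=np.random.default_rng(np.random.SeedSequence((seed, 1))),
        alpha=alpha,
        C=C,
        positive_label="A",
        observed=report.accuracy,
    )
    report.permutation_p = p
    weight_map = build_weight_map(folds, mask)
    names = {
        p_: f"parcel_{p_:02d}" + ("_hub" if p_ in spec.hub_parcels else "")
        for p_ in range(1, spec.n_parcels + 1)
    }
    region_table, top_cum = rank_region_weights(
        weight_map, cohort.parcel_labels, names=names, top_k=top_k
    )
    return {
        "spec": spec,
        "cohort": cohort,
        "mask": mask,
        "features": X,
        "folds": folds,
        "report": report,
        "permuted_statistics": perm_stats,
        "weight_map": weight_map,
        "region_table": region_table,
        "top_k_cumulative_percent": top_cum,
    }


def run_null_mvpa_study(
    seed: int = 0,
    n_replicates: int = 50,
    n_perm: int = 99,
    alpha_sel: float = 0.05,
    preprocess: bool = True,
) -> dict:
    """Permutation-test calibration on replicated exchangeable cohorts.

    For each replicate null cohort the full LOOCV + permutation pipeline runs;
    under exchangeability the permutation p is (super)uniform, so the
    rejection rate at 0.05 estimates the false positive rate.
    """
    ss = np.random.SeedSequence((seed, 2))
    accuracies = np.empty(n_replicates)
    pvals = np.empty(n_replicates)
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cohort = generate_cohort(null_cohort_spec(rep_seed))
        X, _ = cohort_gfcd_features(cohort, preprocess=preprocess)
        labels = cohort.labels
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # selection fallback is routine under the null
            folds = loocv_classify(X, labels, alpha=alpha_sel, positive_label="A")
        report = classification_report(folds)
        p, _ = permutation_test(
            X,
            labels,
            n_perm=n_perm,
            seed=np.random.default_rng(child.spawn(1)[0]),
            alpha=alpha_sel,
            positive_label="A",
            observed=report.accuracy,
        )
        accuracies[rep] = report.accuracy
        pvals[rep] = p
        logger.info("null replicate %d: accuracy %.3f p %.3f", rep, report.accuracy, p)
    return {
        "accuracies": accuracies,
        "pvals": pvals,
        "rejection_rate": float(np.mean(pvals <= 0.05)),
    }


def run_type1_study(seed: int = 0, n_cohorts: int = 25, alpha: float = 0.05) -> dict:
    """Voxelwise-GLM false positive rate on null cohorts.

    Pools the per-voxel covariate-adjusted group tests across replicate null
    cohorts and reports the fraction with p < alpha.
    """
    ss = np.random.SeedSequence((seed, 3))
    n_sig = 0
    n_tests = 0
    for child in ss.spawn(n_cohorts):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cohort = generate_cohort(type1_cohort_spec(rep_seed))
        X, mask = cohort_gfcd_features(cohort, preprocess=False)
        covs = cohort.table[["age", "gender", "education"]]
        stat = voxelwise_group_glm(X, cohort.labels, covariates=covs, mask=mask)
        pvox = stat.p[mask]
        n_sig += int((pvox < alpha).sum())
        n_tests += pvox.size
    return {
        "n_tests": n_tests,
        "n_significant": n_sig,
        "fraction": n_sig / n_tests,
    }
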