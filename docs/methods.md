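# Methods

## Scope and problem

`fcdmvpa` implements a voxelwise functional-connectivity-density (FCD)
analysis of resting-state BOLD fMRI with a linear-SVM multivariate pattern
analysis (MVPA) on top: the kind of pipeline used to ask whether whole-brain
connectivity degree can classify two clinical groups (here: patients who
later develop radiation encephalopathy after nasopharyngeal-carcinoma
radiotherapy versus patients who do not) at the individual level. Real
patient images are not available, so the package ships a synthetic cohort
generator whose covariance structure is chosen so that every downstream
quantity has a known expectation; all statistical claims of the test suite
are claims about this generator, not about patients.

## Synthetic cohort model

Voxel `i` in parcel `p` of a subject in group `g` follows

    y_i(t) = c * z_p(t) + b_{p,g} * h(t) + sigma * e_i(t)

with `z_p`, `h`, `e_i` independent unit-variance white Gaussian signals
(`z_p` per parcel, `h` per subject, `e_i` per voxel). Closed forms follow
immediately: within-parcel correlation `(c^2+b^2)/(c^2+b^2+sigma^2)`,
cross-parcel correlation `b_i b_j / sqrt((c^2+b_i^2+sigma^2)(c^2+b_j^2+sigma^2))`
(zero unless both parcels are hubs). Defaults: 20 "pre-symptomatic" (group A)
vs 26 "control" (group B) subjects, 240 timepoints at TR 2.4 s, 3 mm
isotropic 24^3 grid. Parcels are 64 cubic blocks of 4^3 voxels tiling a
centered 16^3 gray-matter region (~70% of the grid edge); the margin is
split into white-matter and CSF compartments of unit-variance noise. Four
hub parcels sit at the corners of the parcel lattice (ids 1, 16, 52, 61)
so that spatial smoothing of hub-concentrated SVM weights does not pile up
in any single neighbouring parcel.

The group effect is a hub-coupling gap: with `c = 1`, `sigma = 0.5`,
`b_A = 3.0` and `b_B = 1.0`, the cross-hub population correlation is 0.878
in group A and 0.444 in group B — on opposite sides of the 0.6 connection
threshold. Because nuisance regression includes the global mean signal,
which contains part of the shared hub signal, the post-regression cross-hub
correlation is lower; the couplings were chosen from the closed-form
post-regression correlation (≈0.67 for A, ≈0.36 for B) so the gap survives
the full preprocessing chain. No effect-size information exists for the real
disorder; the gap is a designed property of the validation cohort, not a
claim about patients.

Demographics are drawn to match the reference group summaries (age
45.10±9.63 vs 44.54±11.24 years, male proportion 15/20 vs 17/26); education
has no published summary and defaults to 12±3 years in both groups. Group
assignment is independent of demographics (a matched design). Motion traces
are bounded random walks kept well inside the 2.0 mm / 2.0° exclusion
limits, so the motion QC screen flags nobody by default. An optional AR(1)
coefficient adds temporal autocorrelation (default off, keeping closed-form
correlations exact); an optional soft gray-matter edge exercises the
probability threshold.

What the generator deliberately omits: hemodynamic convolution, physiological
noise spectra, scanner drift/artifacts, spatial autocorrelation within
parcels, registration error, lesions. Passing tests therefore demonstrate
correctness of the computations and calibration of the inference under the
stated model — not robustness to the full complexity of real rs-fMRI.

## Preprocessing

Fixed order: drop the first 10 volumes; regress nuisance covariates; bandpass
0.01–0.08 Hz. The nuisance design holds the Friston 24-parameter motion
expansion (`R(t)`, `R(t-1)`, and their squares for the 6 rigid-body
parameters; the backward lag zero-filled at the first sample — the common
convention), the global, white-matter and CSF mean signals, and an
intercept. Rank-deficient designs are pruned (earlier columns win) with a
warning. The filter is a zero-phase forward–backward order-4 Butterworth
bandpass — standard in rs-fMRI packages, no phase distortion; the contract
is gain ≥ 90% in the passband and ≤ 10% at twice the upper cutoff, not the
specific filter family. The gray-matter mask takes probability strictly
greater than 0.20 ("more than 20%"). Spatial steps (slice timing,
realignment, normalization, segmentation) are out of scope; inputs are
assumed to share a common grid.

## FCD mapping

A connection is a voxel pair with Pearson r strictly above 0.6 (negative
correlations never count). gFCD is the voxel's whole-brain suprathreshold
degree, computed blockwise (seed block × all voxels via unit-norm
standardized series products) with a contract identical to the O(N^2)
double loop. lFCD uses the growing algorithm: the adjacency-connected
component (26-neighbourhood by default; 6/18 configurable) containing the
seed within the set of voxels whose correlation *with the seed* exceeds
threshold. Both counts exclude the seed itself, mirroring the "connections"
semantics of gFCD (the count an isolated voxel gets is 0); the source
convention is ambiguous on seed inclusion and this choice is isolated in one
place. Zero-variance voxels are removed from the mask (logged) before any
correlation. Maps are normalized by the gray-matter mean (mask mean exactly
1) and then smoothed with an 8 mm FWHM Gaussian (sigma = FWHM/sqrt(8 ln 2)
per axis in voxel units), in that order; smoothing operates on the map
embedded in zeros and values outside the mask are re-zeroed.

## Group statistics

Voxelwise comparison is an OLS fit of `FCD ~ intercept + group + age +
gender + education` per masked voxel; the group-coefficient t with
`df = n - p` gives a two-sided p. With no covariates this reduces exactly to
the pooled two-sample t-test (tested). Gender enters as a 0/1 indicator;
education in years. No multiple-testing correction by default ("p < 0.05",
strict); Benjamini–Hochberg and Bonferroni are available as options. The
demographics table uses pooled-variance t for continuous summaries (Welch
available), Pearson chi-square with or without Yates continuity correction,
and Fisher's exact test for 2×2 tables. The reference table is internally
inconsistent about which test produced which row: its gender and
chemotherapy rows match Fisher's exact test (not the stated chi-square), its
clinical-stage row matches uncorrected chi-square, its treatment-option row
matches Yates-corrected chi-square, and its radiotherapy-time p (0.89) is
not reproduced by pooled or Welch t on the printed summaries (both give
≈0.24) — possibly a rank test or a typo; that row is documented, not
reproduced. The module exposes all three tests so each row's match is
explicit.

## MVPA

Features are the normalized + smoothed gFCD values over the gray-matter mask
(lFCD available behind a flag). Leave-one-out cross-validation with fully
nested feature selection: each fold selects voxels with two-sample-t
p < 0.05 on the 45 training subjects only (fallback: the 100 smallest-p
voxels, warned), mean-centers with training statistics (no variance scaling
— maps are already whole-brain normalized), fits a soft-margin linear SVM
(C = 1, exposed), and scores the held-out subject by its signed decision
value. The confusion matrix, accuracy, balanced accuracy, sensitivity and
specificity come from the pooled held-out predictions; the ROC sweeps the
pooled decision values and AUC is the trapezoid area (equal to the
Mann–Whitney statistic with ties counting one half — tested). Permutation
significance reruns the *entire* pipeline, feature selection included, under
uniformly random label permutations, with p = (1 + #{permuted ≥ observed})
/ (n_perm + 1); the default is 5,000 permutations, the statistic is total
accuracy (AUC selectable). The p-value is deterministic given the seed; under
reordering of the input subjects it is invariant in distribution (the
realized permutations pair differently), which is the strongest
order-invariance a label-permutation scheme admits. Fold weight vectors are
back-projected to the grid as the mean over folds (zero where unselected)
and aggregated per atlas region by summed absolute weight; regions are
ranked by their percentage share. The per-region weighting of the original
MATLAB toolchain is undocumented, so the cumulative top-k share is reported
but not treated as a reference value.

## Validation studies and problem sizes

Three self-validation studies (in `fcdmvpa.experiments`) are run by the
acceptance script and the acceptance tests:

* **Signal study** — reference scale (46 subjects, 24^3 grid, 4096
  gray-matter voxels, 240 timepoints), full pipeline, 199 permutations for
  the calibration property (the package default for a real analysis remains
  5,000). Expected outcome: LOOCV accuracy ≥ 80%, permutation p at its
  minimum, hub parcels top-ranked.
* **Null MVPA calibration** — 50 replicate cohorts with equal couplings at
  reduced spatial scale (12^3 grid, 8 parcels of 4^3, 512 gray-matter
  voxels), 99 permutations each. The voxel noise is raised to sigma = 0.85
  so the within-parcel correlation (≈0.58) sits near the 0.6 threshold and
  per-subject degrees genuinely vary: a null far above threshold saturates
  every count at parcel-size − 1, making features constant and all
  permutation statistics tied, a regime in which no false-positive rate can
  be estimated. Expected outcome: mean accuracy inside the n = 46 binomial
  chance band, rejection rate at alpha = 0.05 within [0.01, 0.12] (the
  discreteness of LOOCV accuracy makes the test somewhat conservative).
* **Type-I GLM calibration** — 25 null cohorts with 64 parcels of 2^3
  voxels (12,800 pooled voxel-tests, small parcels to increase the number of
  quasi-independent tests). Expected fraction of p < 0.05 in [0.04, 0.06].

The reduced scales are the package's own choice of validation size; the
null properties being checked (exchangeability, test level) do not depend on
grid size.

## Numerical choices and degenerate inputs

Strict inequalities throughout (r > 0.6, p < alpha, probability > 0.20).
Correlations via unit-norm demeaned series products; exact integer counts.
Normalization refuses a zero-mean map; smoothing with FWHM 0 is the
identity. The summary t-test returns p = 1 for two zero-variance groups with
equal means. Collinear GLM covariates raise an error naming the columns;
collinear nuisance regressors are pruned with a warning (the GLM is
inference, the nuisance fit is not). Permutation p can never be 0 by the
(1+B)/(1+N) convention. All randomness flows from explicit integer seeds
through `numpy` `SeedSequence` spawning, so cohorts are bit-reproducible and
subjects can be regenerated in isolation.

## Known limitations

White-noise signals mean the bandpass filter only reduces effective degrees
of freedom rather than removing structured noise; the AR(1) option exists
but closed-form FCD expectations then no longer account for the filter.
lFCD on strongly coherent parcels saturates at parcel size − 1 and carries
little group information under this generator — consistent with the choice
of gFCD as the classification feature. The chance band used for the null
accuracy check is centered at 0.5; leave-one-out cross-validation has a
known small below-chance bias on null data, which the band absorbs but does
not model. Region ranking assumes the atlas shares the map grid exactly.
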