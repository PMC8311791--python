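"""Synthetic two-group resting-state fMRI cohort with analytically known connectivity.

The generative model is deliberately simple so that population voxel-pair
correlations — and hence expected connectivity-density maps — have closed
forms. Voxel ``i`` belonging to parcel ``p`` of a subject in group ``g``
follows

    y_i(t) = c * z_p(t) + b_{p,g} * h(t) + sigma * e_i(t)

where ``z_p`` (one per parcel), ``h`` (one per subject, the shared "hub"
signal) and ``e_i`` (one per voxel) are independent unit-variance white
Gaussian processes, ``c`` is the within-parcel loading, ``sigma`` the voxel
noise, and ``b_{p,g}`` equals the group's hub coupling for designated hub
parcels and 0 elsewhere. Two voxels of the same parcel therefore correlate at
``(c^2 + b^2) / (c^2 + b^2 + sigma^2)`` and voxels of two distinct hub
parcels at ``b^2 / (c^2 + b^2 + sigma^2)``; all other cross-parcel pairs are
uncorrelated. Choosing the group couplings so that the cross-hub correlation
straddles the connection threshold in the two groups yields a cohort whose
group difference lives in whole-brain (global) connectivity degree of the hub
parcels.

Parcels are contiguous axis-aligned cubic blocks tiling a centered
sub-region of the grid (the "gray matter" region); voxels outside it carry
independent unit-variance noise and are split into white-matter and CSF
compartments for nuisance extraction. Demographics are drawn to match the
study group summaries; group assignment is independent of demographics
(a matched design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .bold import BoldSeries, default_affine, save_bold, save_volume

__all__ = [
    "DemographicsModel",
    "CohortSpec",
    "Cohort",
    "CohortConfigError",
    "generate_cohort",
    "generate_subject_series",
    "expected_correlation",
    "expected_gfcd",
    "parcel_label_map",
    "tissue_masks",
    "write_cohort",
]

logger = logging.getLogger(__name__)

MOTION_COLUMNS = ["tx", "ty", "tz", "rx", "ry", "rz"]


class CohortConfigError(ValueError):
    """Raised for an invalid cohort specification."""


@dataclass(frozen=True)
class DemographicsModel:
    """Group-wise demographic sampling parameters (age yr, education yr)."""

    age_mean_a: float = 45.10
    age_sd_a: float = 9.63
    age_mean_b: float = 44.54
    age_sd_b: float = 11.24
    male_prop_a: float = 15 / 20
    male_prop_b: float = 17 / 26
    education_mean: float = 12.0
    education_sd: float = 3.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults mirror the study conditions this generator emulates: 20 vs 26
    subjects, 240 timepoints at TR 2.4 s on a 3 mm isotropic grid. The
    connectivity parameters place group A's cross-hub population correlation
    above the conventional 0.6 connection threshold and group B's below it.
    """

    n_group_a: int = 20
    n_group_b: int = 26
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 240
    tr_seconds: float = 2.4
    n_parcels: int = 64
    hub_parcels: frozenset[int] = frozenset({1, 16, 52, 61})
    coupling_a: float = 3.0
    coupling_b: float = 1.0
    parcel_loading: float = 1.0
    noise_sd: float = 0.5
    ar_coeff: float = 0.0
    gm_soft_edge: float | None = None
    demographics: DemographicsModel = field(default_factory=DemographicsModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_group_a", "n_group_b", "n_timepoints", "n_parcels"):
            if int(getattr(self, name)) < 1:
                raise CohortConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if len(self.grid_shape) != 3 or any(int(g) < 1 for g in self.grid_shape):
            raise CohortConfigError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.voxel_size_mm <= 0 or self.tr_seconds <= 0:
            raise CohortConfigError("voxel_size_mm and tr_seconds must be positive")
        for name in ("coupling_a", "coupling_b", "parcel_loading", "noise_sd"):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{name} must be >= 0")
        if not (0 <= self.ar_coeff < 1):
            raise CohortConfigError("ar_coeff must be in [0, 1)")
        per_axis = self.parcels_per_axis
        if per_axis**3 != self.n_parcels:
            raise CohortConfigError(f"n_parcels must be a perfect cube, got {self.n_parcels}")
        bad = set(self.hub_parcels) - set(range(1, self.n_parcels + 1))
        if bad:
            raise CohortConfigError(f"hub_parcels outside 1..{self.n_parcels}: {sorted(bad)}")
        if any(b < 1 for b in self.parcel_block):
            raise CohortConfigError("grid too small to host the parcel lattice")

    @property
    def parcels_per_axis(self) -> int:
        return int(round(self.n_parcels ** (1 / 3)))

    @property
    def parcel_block(self) -> tuple[int, int, int]:
        """Edge length of one cubic parcel per axis; the parcel region covers
        ~70% of the grid, leaving a margin of non-gray tissue."""
        k = self.parcels_per_axis
        return tuple(int(g * 0.7) // k for g in self.grid_shape)

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    def hub_coupling(self, group: str, parcel: int) -> float:
        if group not in ("A", "B"):
            raise CohortConfigError(f"group must be 'A' or 'B', got {group!r}")
        if parcel not in range(1, self.n_parcels + 1):
            raise CohortConfigError(f"unknown parcel id {parcel}")
        if parcel not in self.hub_parcels:
            return 0.0
        return self.coupling_a if group == "A" else self.coupling_b


def parcel_label_map(spec: CohortSpec) -> np.ndarray:
    """Integer label volume: 0 outside the parcel region, 1..n_parcels inside.

    Parcels are cubic blocks in raster (x-fastest) order on the parcel
    lattice, centered in the grid.
    """
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    k = spec.parcels_per_axis
    block = spec.parcel_block
    offset = [(g - b * k) // 2 for g, b in zip(spec.grid_shape, block)]
    pid = 0
    for kz in range(k):
        for ky in range(k):
            for kx in range(k):
                pid += 1
                x0 = offset[0] + kx * block[0]
                y0 = offset[1] + ky * block[1]
                z0 = offset[2] + kz * block[2]
                labels[x0 : x0 + block[0], y0 : y0 + block[1], z0 : z0 + block[2]] = pid
    return labels


def tissue_masks(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Boolean masks: gray matter = parcel region; the margin is split into
    white-matter (lower x half) and CSF (upper x half) compartments."""
    labels = parcel_label_map(spec)
    gm = labels > 0
    outside = ~gm
    xs = np.arange(spec.grid_shape[0])[:, None, None]
    wm = outside & np.broadcast_to(xs < spec.grid_shape[0] // 2, spec.grid_shape)
    csf = outside & ~wm
    return {"gm": gm, "wm": wm, "csf": csf, "brain": np.ones(spec.grid_shape, bool)}


def gm_probability_map(spec: CohortSpec) -> np.ndarray:
    """Gray-matter probability: 1 inside the parcel region, 0 outside.

    With ``gm_soft_edge`` set, the one-voxel border of the region takes that
    probability instead, exercising the downstream threshold.
    """
    gm = parcel_label_map(spec) > 0
    prob = gm.astype(np.float64)
    if spec.gm_soft_edge is not None:
        interior = ndimage.binary_erosion(gm)
        prob[gm & ~interior] = float(spec.gm_soft_edge)
    return prob


def expected_correlation(spec: CohortSpec, group: str, parcel_i: int, parcel_j: int) -> float:
    """Closed-form population correlation between voxels of two parcels.

    Same parcel: ``(c^2 + b^2) / (c^2 + b^2 + sigma^2)``; distinct parcels:
    ``b_i b_j / sqrt((c^2+b_i^2+sigma^2)(c^2+b_j^2+sigma^2))`` which is zero
    unless both are hubs. Symmetric in ``(i, j)``.
    """
    c2 = spec.parcel_loading**2
    s2 = spec.noise_sd**2
    bi = spec.hub_coupling(group, parcel_i)
    bj = spec.hub_coupling(group, parcel_j)
    vi = c2 + bi**2 + s2
    vj = c2 + bj**2 + s2
    if vi == 0 or vj == 0:
        raise CohortConfigError("degenerate zero-variance voxel model")
    if parcel_i == parcel_j:
        return (c2 + bi**2) / vi
    return bi * bj / np.sqrt(vi * vj)


def expected_gfcd(spec: CohortSpec, group: str, parcel: int, r_threshold: float = 0.6) -> int:
    """Expected global connectivity degree of a voxel in ``parcel`` under the
    population correlations (a connection where expected r > threshold)."""
    block = spec.parcel_block
    per_parcel = int(np.prod(block))
    degree = 0
    for other in range(1, spec.n_parcels + 1):
        r = expected_correlation(spec, group, parcel, other)
        if r > r_threshold:
            degree += per_parcel - 1 if other == parcel else per_parcel
    return degree


def _whiten_or_ar1(rng: np.random.Generator, shape: tuple[int, ...], phi: float) -> np.ndarray:
    """Unit-variance white noise, or a stationary unit-variance AR(1) stream.

    x_t = phi x_{t-1} + sqrt(1-phi^2) w_t with x_0 ~ N(0,1) is stationary
    with unit variance for |phi| < 1.
    """
    w = rng.standard_normal(shape)
    if phi == 0.0:
        return w
    a = np.sqrt(1 - phi**2)
    # seed the filter state with x_0 = w_0 (already unit variance)
    scaled = a * w
    scaled[..., 0] = w[..., 0]
    out, _ = signal.lfilter([1.0], [1, -phi], scaled, axis=-1, zi=np.zeros(shape[:-1] + (1,)))
    return out


def generate_subject_series(
    spec: CohortSpec, group: str, rng: np.random.Generator | int
) -> BoldSeries:
    """Draw one subject's 4D BOLD run from the block-covariance model."""
    if group not in ("A", "B"):
        raise CohortConfigError(f"group must be 'A' or 'B', got {group!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = parcel_label_map(spec)
    T = spec.n_timepoints
    c, sig, phi = spec.parcel_loading, spec.noise_sd, spec.ar_coeff
    z = _whiten_or_ar1(rng, (spec.n_parcels, T), phi)
    h = _whiten_or_ar1(rng, (T,), phi)
    data = np.empty(spec.grid_shape + (T,), dtype=np.float64)
    flat = data.reshape(-1, T)
    lab_flat = labels.ravel()
    noise = _whiten_or_ar1(rng, (flat.shape[0], T), phi)
    # non-gray voxels: independent unit-variance noise
    out = lab_flat == 0
    flat[out] = noise[out]
    b = np.zeros(spec.n_parcels + 1)
    for p in spec.hub_parcels:
        b[p] = spec.coupling_a if group == "A" else spec.coupling_b
    inside = ~out
    p_idx = lab_flat[inside]
    flat[inside] = c * z[p_idx - 1] + b[p_idx][:, None] * h[None, :] + sig * noise[inside]
    return BoldSeries(data=data, tr=spec.tr_seconds, affine=default_affine(spec.voxel_size_mm))


def generate_motion_trace(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Bounded random-walk rigid-body motion: 3 translations (mm), 3 rotations
    (deg), kept well inside the 2.0 mm / 2.0 deg exclusion limits."""
    steps = rng.normal(0.0, 0.02, size=(spec.n_timepoints, 6))
    walk = np.clip(np.cumsum(steps, axis=0), -1.0, 1.0)
    return pd.DataFrame(walk, columns=MOTION_COLUMNS)


def _draw_demographics(spec: CohortSpec, group: str, rng: np.random.Generator) -> dict:
    d = spec.demographics
    if group == "A":
        age = rng.normal(d.age_mean_a, d.age_sd_a)
        male = rng.random() < d.male_prop_a
    else:
        age = rng.normal(d.age_mean_b, d.age_sd_b)
        male = rng.random() < d.male_prop_b
    age = float(np.clip(age, 20.0, 60.0))
    edu = float(np.clip(rng.normal(d.education_mean, d.education_sd), 6.0, 22.0))
    return {"age": round(age, 1), "gender": "male" if male else "female", "education": round(edu, 1)}


@dataclass
class Cohort:
    """An in-memory generated cohort: table plus per-subject arrays."""

    spec: CohortSpec
    table: pd.DataFrame
    series: dict[str, BoldSeries]
    motion: dict[str, pd.DataFrame]
    gm_probability: np.ndarray
    parcel_labels: np.ndarray
    masks: dict[str, np.ndarray]
    affine: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        return self.table["group"].to_numpy()


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full two-group cohort deterministically from ``spec.seed``.

    Every subject draws from an independent child stream of the spec seed, so
    the cohort is bit-reproducible and individual subjects can be regenerated
    in isolation.
    """
    root = np.random.SeedSequence(spec.seed)
    n = spec.n_subjects
    children = root.spawn(n + 1)
    demo_rng = np.random.default_rng(children[n])
    rows = []
    series: dict[str, BoldSeries] = {}
    motion: dict[str, pd.DataFrame] = {}
    groups = ["A"] * spec.n_group_a + ["B"] * spec.n_group_b
    for i, group in enumerate(groups):
        sid = f"sub-{i + 1:03d}"
        rng = np.random.default_rng(children[i])
        series[sid] = generate_subject_series(spec, group, rng)
        motion[sid] = generate_motion_trace(spec, rng)
        demo = _draw_demographics(spec, group, demo_rng)
        rows.append({"subject_id": sid, "group": group, **demo})
    table = pd.DataFrame(rows)
    return Cohort(
        spec=spec,
        table=table,
        series=series,
        motion=motion,
        gm_probability=gm_probability_map(spec),
        parcel_labels=parcel_label_map(spec),
        masks=tissue_masks(spec),
        affine=default_affine(spec.voxel_size_mm),
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> pd.DataFrame:
    """Write the cohort to disk: per-subject BOLD NIfTI + motion TSV, cohort
    table TSV, GM probability map, tissue masks, parcel atlas + lookup TSV.

    Returns the cohort table augmented with file paths (also written as
    ``cohort.tsv``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = cohort.table.copy()
    bold_paths, motion_paths = [], []
    for sid in table["subject_id"]:
        bp = outdir / f"{sid}_bold.nii.gz"
        mp = outdir / f"{sid}_motion.tsv"
        save_bold(cohort.series[sid], bp)
        cohort.motion[sid].to_csv(mp, sep="\t", index=False)
        # paths are stored relative to the cohort directory so identical
        # cohorts written anywhere produce identical tables
        bold_paths.append(bp.name)
        motion_paths.append(mp.name)
    table["bold_path"] = bold_paths
    table["motion_path"] = motion_paths
    save_volume(cohort.gm_probability, cohort.affine, outdir / "gm_probability.nii.gz")
    save_volume(cohort.parcel_labels, cohort.affine, outdir / "parcels.nii.gz")
    for name in ("wm", "csf", "brain"):
        save_volume(cohort.masks[name].astype(np.int16), cohort.affine, outdir / f"{name}_mask.nii.gz")
    lookup = pd.DataFrame(
        {
            "id": np.arange(1, cohort.spec.n_parcels + 1),
            "name": [
                f"parcel_{p:02d}" + ("_hub" if p in cohort.spec.hub_parcels else "")
                for p in range(1, cohort.spec.n_parcels + 1)
            ],
        }
    )
    lookup.to_csv(outdir / "parcels.tsv", sep="\t", index=False)
    table.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    logger.info("wrote cohort of %d subjects to %s", len(table), outdir)
    return table
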