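"""Voxelwise functional connectivity density (FCD) mapping.

A functional connection is a voxel pair whose Pearson correlation across the
preprocessed BOLD series strictly exceeds a threshold (default 0.6; negative
correlations never count). Two densities are mapped for every gray-matter
voxel x0:

* global FCD (gFCD): the number of suprathreshold connections between x0 and
  all other gray-matter voxels, i.e. the voxel's whole-brain degree;
* local FCD (lFCD): a "growing" cluster size — starting from x0, neighbours
  (26-adjacency by default) whose correlation *with the seed* exceeds the
  threshold join the cluster, then their neighbours are examined, until no
  voxel can be added. lFCD(x0) is the cluster size excluding the seed itself.

Raw integer maps are then normalized by their gray-matter mean and smoothed
with a Gaussian kernel (8 mm FWHM by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .bold import BoldSeries

__all__ = [
    "FcdParams",
    "FcdMap",
    "standardized_series",
    "seed_correlation_map",
    "compute_gfcd",
    "compute_lfcd",
    "normalize_fcd",
    "smooth_fcd",
    "fwhm_to_sigma_voxels",
]

logger = logging.getLogger(__name__)

_ADJACENCY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class FcdParams:
    """FCD computation parameters."""

    r_threshold: float = 0.6
    adjacency: int = 26
    fwhm_mm: float = 8.0

    def __post_init__(self) -> None:
        if not (-1.0 < self.r_threshold < 1.0):
            raise ValueError(f"r_threshold must be in (-1, 1), got {self.r_threshold}")
        if self.adjacency not in _ADJACENCY_RANK:
            raise ValueError(f"adjacency must be one of 6, 18, 26; got {self.adjacency}")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")

    @property
    def structure(self) -> np.ndarray:
        """3x3x3 binary adjacency structuring element."""
        return ndimage.generate_binary_structure(3, _ADJACENCY_RANK[self.adjacency])


@dataclass
class FcdMap:
    """A 3D connectivity-density map with provenance."""

    data: np.ndarray
    kind: str  # "global" | "local"
    state: str  # "raw" | "normalized" | "smoothed"
    mask: np.ndarray
    affine: np.ndarray
    params: FcdParams

    def __post_init__(self) -> None:
        if self.kind not in ("global", "local"):
            raise ValueError(f"kind must be 'global' or 'local', got {self.kind!r}")
        if self.state not in ("raw", "normalized", "smoothed"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.data.shape != self.mask.shape:
            raise ValueError("map and mask grids differ")


def standardized_series(
    series: BoldSeries, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mask the series and z-score each voxel's time course to unit norm.

    Returns ``(Z, mask)`` where ``Z`` has one unit-norm demeaned row per
    masked voxel so that ``Z @ Z.T`` is the Pearson correlation matrix.
    Zero-variance voxels cannot enter correlations and are removed from the
    mask with a logged count.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != series.grid_shape:
        raise ValueError("mask grid does not match series grid")
    if not mask.any():
        raise ValueError("empty mask")
    ts = series.data[mask]  # n_voxels x t
    ts = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ts, axis=1)
    ok = norms > 0
    if not ok.all():
        n_bad = int((~ok).sum())
        logger.warning("excluding %d zero-variance voxels from the mask", n_bad)
        mask = mask.copy()
        mask[tuple(np.argwhere(mask)[~ok].T)] = False
        ts, norms = ts[ok], norms[ok]
    if ts.shape[0] == 0:
        raise ValueError("all masked voxels have zero variance")
    return ts / norms[:, None], mask


def seed_correlation_map(
    series: BoldSeries, mask: np.ndarray, seed_voxel: tuple[int, int, int]
) -> np.ndarray:
    """Pearson correlation between the seed voxel's series and every masked
    voxel's series; NaN outside the mask, 1.0 at the seed."""
    Z, mask = standardized_series(series, mask)
    seed_voxel = tuple(int(v) for v in seed_voxel)
    if not mask[seed_voxel]:
        raise ValueError(f"seed voxel {seed_voxel} outside the (nonzero-variance) mask")
    idx = np.flatnonzero(mask.ravel())
    seed_flat = np.ravel_multi_index(seed_voxel, mask.shape)
    seed_row = int(np.searchsorted(idx, seed_flat))
    r = Z @ Z[seed_row]
    out = np.full(mask.shape, np.nan)
    out[mask] = r
    return out


def compute_gfcd(
    series: BoldSeries, mask: np.ndarray, params: FcdParams = FcdParams(), block: int = 512
) -> FcdMap:
    """Global FCD: per masked voxel, the count of other masked voxels whose
    correlation with it strictly exceeds the threshold.

    Computed blockwise (seed block x all voxels) so memory stays bounded; the
    result is identical to the full O(N^2) pairwise count.
    """
    Z, mask = standardized_series(series, mask)
    n = Z.shape[0]
    counts = np.empty(n, dtype=np.int64)
    thr = params.r_threshold
    for start in range(0, n, block):
        stop = min(start + block, n)
        r = Z[start:stop] @ Z.T
        c = (r > thr).sum(axis=1)
        # remove self-correlation (exactly 1 > thr)
        counts[start:stop] = c - 1
    out = np.zeros(mask.shape, dtype=np.float64)
    out[mask] = counts
    return FcdMap(out, "global", "raw", mask, series.affine, params)


def compute_lfcd(
    series: BoldSeries, mask: np.ndarray, params: FcdParams = FcdParams(), block: int = 512
) -> FcdMap:
    """Local FCD by the growing algorithm.

    For each seed, the suprathreshold set {x in mask : r(x, seed) > thr} plus
    the seed itself is formed, and the cluster is its adjacency-connected
    component containing the seed (all correlations are against the seed,
    never between members). lFCD is the component size minus one.
    """
    Z, mask = standardized_series(series, mask)
    n = Z.shape[0]
    coords = np.argwhere(mask)
    structure = params.structure
    thr = params.r_threshold
    counts = np.empty(n, dtype=np.int64)
    supra = np.zeros(mask.shape, dtype=bool)
    flat_index = np.flatnonzero(mask.ravel())
    for start in range(0, n, block):
        stop = min(start + block, n)
        r = Z[start:stop] @ Z.T
        for k in range(stop - start):
            i = start + k
            supra.ravel()[flat_index] = r[k] > thr
            supra[tuple(coords[i])] = True
            labeled, _ = ndimage.label(supra, structure=structure)
            comp = labeled[tuple(coords[i])]
            counts[i] = int((labeled == comp).sum()) - 1
    out = np.zeros(mask.shape, dtype=np.float64)
    out[mask] = counts
    return FcdMap(out, "local", "raw", mask, series.affine, params)


def normalize_fcd(fcd: FcdMap) -> FcdMap:
    """Divide by the gray-matter mean so the masked map has mean 1."""
    mean = fcd.data[fcd.mask].mean()
    if mean <= 0:
        raise ValueError("cannot normalize: mask-wide mean FCD is zero")
    out = np.zeros_like(fcd.data)
    out[fcd.mask] = fcd.data[fcd.mask] / mean
    return replace(fcd, data=out, state="normalized")


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm: np.ndarray | float) -> np.ndarray:
    """Gaussian sigma per axis in voxel units: FWHM / sqrt(8 ln 2) / voxel."""
    voxel = np.atleast_1d(np.asarray(voxel_size_mm, float))
    return fwhm_mm / np.sqrt(8.0 * np.log(2.0)) / voxel


def smooth_fcd(fcd: FcdMap, fwhm_mm: float | None = None) -> FcdMap:
    """Gaussian smoothing of the (masked, zero-embedded) map.

    Smoothing operates on the map embedded in zeros, then values outside the
    mask are re-zeroed; fwhm 0 is the identity.
    """
    if fwhm_mm is None:
        fwhm_mm = fcd.params.fwhm_mm
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return replace(fcd, data=fcd.data.copy(), state="smoothed")
    voxel = np.sqrt((np.asarray(fcd.affine)[:3, :3] ** 2).sum(axis=0))
    sigma = fwhm_to_sigma_voxels(fwhm_mm, voxel)
    smoothed = ndimage.gaussian_filter(fcd.data, sigma=sigma, mode="constant", cval=0.0)
    smoothed[~fcd.mask] = 0.0
    return replace(fcd, data=smoothed, state="smoothed")
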