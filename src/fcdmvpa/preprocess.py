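"""Temporal-domain BOLD preprocessing.

Fixed stage order: initial-volume trimming, nuisance regression (Friston-24
motion expansion + global/white-matter/CSF mean signals + intercept), then
0.01-0.08 Hz bandpass filtering. Spatial registration steps are out of scope;
inputs are assumed to share a common grid already.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .bold import BoldSeries
from .cohort import MOTION_COLUMNS

__all__ = [
    "trim_initial_volumes",
    "build_friston24",
    "extract_nuisance_signals",
    "regress_nuisance",
    "bandpass",
    "threshold_gm_mask",
    "motion_qc",
    "preprocess_series",
]

logger = logging.getLogger(__name__)


def trim_initial_volumes(series: BoldSeries, n_drop: int = 10) -> BoldSeries:
    """Drop the first ``n_drop`` volumes (magnetization-equilibration period)."""
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    if n_drop >= series.n_timepoints:
        raise ValueError(
            f"cannot drop {n_drop} of {series.n_timepoints} volumes: nothing would remain"
        )
    if n_drop == 0:
        return series
    return series.with_data(series.data[..., n_drop:])


def build_friston24(motion: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Friston 24-parameter motion expansion.

    For each of the 6 rigid-body parameters R the design holds
    ``[R(t), R(t-1), R(t)^2, R(t-1)^2]``; the backward lag is zero-filled at
    the first sample. Columns are grouped as 6 raw, 6 lagged, 6 squared,
    6 lagged-squared.
    """
    arr = motion.to_numpy() if isinstance(motion, pd.DataFrame) else np.asarray(motion, float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"motion trace must have exactly 6 columns, got shape {arr.shape}")
    lag = np.zeros_like(arr)
    lag[1:] = arr[:-1]
    names = (
        MOTION_COLUMNS
        + [f"{c}_lag" for c in MOTION_COLUMNS]
        + [f"{c}_sq" for c in MOTION_COLUMNS]
        + [f"{c}_lag_sq" for c in MOTION_COLUMNS]
    )
    return pd.DataFrame(np.hstack([arr, lag, arr**2, lag**2]), columns=names)


def extract_nuisance_signals(
    series: BoldSeries, masks: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Spatial-mean time series per named mask (e.g. global, wm, csf)."""
    out = {}
    flat = series.data.reshape(-1, series.n_timepoints)
    for name, mask in masks.items():
        mask = np.asarray(mask, bool)
        if mask.shape != series.grid_shape:
            raise ValueError(f"mask {name!r} grid {mask.shape} != series grid {series.grid_shape}")
        if not mask.any():
            raise ValueError(f"mask {name!r} is empty")
        out[name] = flat[mask.ravel()].mean(axis=0)
    return pd.DataFrame(out)


def _prune_rank_deficient(design: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop columns that add no rank (pivoted-QR based), keeping earlier ones."""
    keep: list[int] = []
    rank = 0
    for j in range(design.shape[1]):
        cand = design[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
    if len(keep) < design.shape[1]:
        dropped = [names[j] for j in range(design.shape[1]) if j not in keep]
        warnings.warn(f"pruned collinear nuisance columns: {dropped}", stacklevel=3)
    return design[:, keep], [names[j] for j in keep]


def regress_nuisance(
    series: BoldSeries, design: pd.DataFrame | np.ndarray
) -> BoldSeries:
    """Replace every voxel series by its OLS residual against the design.

    An intercept is always included, so residuals are demeaned and orthogonal
    to every design column. A rank-deficient design is pruned with a warning.
    """
    X = design.to_numpy() if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    names = list(design.columns) if isinstance(design, pd.DataFrame) else [
        f"c{j}" for j in range(X.shape[1])
    ]
    if X.ndim != 2 or X.shape[0] != series.n_timepoints:
        raise ValueError(
            f"design has {X.shape[0] if X.ndim == 2 else '?'} rows for "
            f"{series.n_timepoints} timepoints"
        )
    X = np.column_stack([np.ones(X.shape[0]), X])
    names = ["intercept"] + names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X, names = _prune_rank_deficient(X, names)
    flat = series.data.reshape(-1, series.n_timepoints).T  # t x voxels
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    return series.with_data(resid.T.reshape(series.data.shape))


def bandpass(
    series: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> BoldSeries:
    """Zero-phase (forward-backward) order-4 Butterworth bandpass.

    Removes DC and slow drift below ``low_hz`` and high-frequency noise above
    ``high_hz``. The upper cutoff must stay below Nyquist = 1/(2 TR).
    """
    nyq = 1.0 / (2.0 * series.tr)
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz {high_hz} must be below Nyquist {nyq:.4f} Hz at TR {series.tr}")
    b, a = signal.butter(4, [low_hz / nyq, high_hz / nyq], btype="bandpass")
    filtered = signal.filtfilt(b, a, series.data, axis=-1)
    return series.with_data(filtered)


def threshold_gm_mask(prob_map: np.ndarray, threshold: float = 0.20) -> np.ndarray:
    """Boolean gray-matter mask: probability strictly greater than threshold."""
    prob = np.asarray(prob_map, float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    mask = prob > threshold
    if not mask.any():
        raise ValueError(f"gray-matter mask empty at threshold {threshold}")
    return mask


def motion_qc(
    motion: dict[str, pd.DataFrame],
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
) -> pd.DataFrame:
    """Cohort-level head-motion screen.

    Flags (does not drop) subjects whose peak absolute translation or rotation
    exceeds the limits.
    """
    rows = []
    for sid, trace in motion.items():
        arr = trace[MOTION_COLUMNS].to_numpy()
        t_max = float(np.abs(arr[:, :3]).max())
        r_max = float(np.abs(arr[:, 3:]).max())
        rows.append(
            {
                "subject_id": sid,
                "max_translation_mm": t_max,
                "max_rotation_deg": r_max,
                "excluded": bool(t_max >= max_translation_mm or r_max >= max_rotation_deg),
            }
        )
    return pd.DataFrame(rows)


def preprocess_series(
    series: BoldSeries,
    motion: pd.DataFrame,
    masks: dict[str, np.ndarray],
    n_drop: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> BoldSeries:
    """Standard temporal pipeline: trim, regress nuisance, bandpass.

    ``masks`` must provide ``wm`` and ``csf``; the global signal is averaged
    over ``brain`` when present, else over the union of all provided masks.
    """
    trimmed = trim_initial_volumes(series, n_drop)
    motion_t = motion.iloc[n_drop:].reset_index(drop=True)
    design = build_friston24(motion_t)
    if "brain" in masks:
        global_mask = masks["brain"]
    else:
        global_mask = np.zeros(trimmed.grid_shape, bool)
        for m in masks.values():
            global_mask |= np.asarray(m, bool)
    sig_masks = {"global": global_mask}
    for name in ("wm", "csf"):
        if name in masks:
            sig_masks[name] = masks[name]
    signals = extract_nuisance_signals(trimmed, sig_masks)
    design = pd.concat([design, signals], axis=1)
    residual = regress_nuisance(trimmed, design)
    return bandpass(residual, low_hz=low_hz, high_hz=high_hz)
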