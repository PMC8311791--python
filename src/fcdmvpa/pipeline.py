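"""Pipeline orchestration: synth -> preprocess -> fcd -> groupstats -> mvpa.

Stages execute sequentially in fixed order; each stage writes its outputs
(NIfTI volumes with JSON parameter sidecars, TSV tables, a JSON report)
before the next starts, and a run manifest with content hashes is written
last so identical config + seed reruns are verifiable bit-for-bit for the
deterministic stages. A failing stage leaves a ``<stage>.partial`` marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bold import load_bold, load_volume, save_volume
from .cohort import Cohort, CohortSpec, DemographicsModel, generate_cohort, write_cohort
from .config import RunConfig
from .fcd import FcdParams, compute_gfcd, compute_lfcd, normalize_fcd, smooth_fcd
from .groupstats import significance_mask, table1_report, voxelwise_group_glm
from .mvpa import (
    build_weight_map,
    classification_report,
    loocv_classify,
    permutation_test,
    rank_region_weights,
)
from .preprocess import motion_qc, preprocess_series, threshold_gm_mask

__all__ = ["RunManifest", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGE_ORDER = ["synth", "preprocess", "fcd", "groupstats", "mvpa"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "stages": self.stages,
            "warnings": self.warnings,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sidecar(path: Path, params: dict) -> Path:
    side = path.with_name(path.name.split(".")[0] + ".json")
    side.write_text(json.dumps(params, indent=2, sort_keys=True))
    return side


def _spec_from_config(config: RunConfig) -> CohortSpec:
    s = config.synth
    return CohortSpec(
        n_group_a=s["n_group_a"],
        n_group_b=s["n_group_b"],
        grid_shape=tuple(s["grid_shape"]),
        voxel_size_mm=s["voxel_size_mm"],
        n_timepoints=s["n_timepoints"],
        tr_seconds=s["tr_seconds"],
        n_parcels=s["n_parcels"],
        hub_parcels=frozenset(s["hub_parcels"]),
        coupling_a=s["coupling_a"],
        coupling_b=s["coupling_b"],
        parcel_loading=s["parcel_loading"],
        noise_sd=s["noise_sd"],
        ar_coeff=s["ar_coeff"],
        demographics=DemographicsModel(),
        seed=config.seed,
    )


class _RunState:
    """In-memory carry-over between stages (falls back to disk on reruns)."""

    def __init__(self, config: RunConfig, out: Path):
        self.config = config
        self.out = out
        self.cohort: Cohort | None = None
        self.table: pd.DataFrame | None = None
        self.preproc: dict[str, object] = {}
        self.maps: dict[str, dict[str, np.ndarray]] = {}

    # -- loading fallbacks -------------------------------------------------
    def load_table(self) -> pd.DataFrame:
        if self.table is None:
            self.table = pd.read_csv(self.out / "cohort" / "cohort.tsv", sep="\t")
        return self.table

    def gm_mask(self) -> np.ndarray:
        prob, _ = load_volume(self.out / "cohort" / "gm_probability.nii.gz")
        return threshold_gm_mask(prob, self.config.preprocess["gm_threshold"])


def _stage_synth(state: _RunState) -> list[Path]:
    cohort_dir = state.out / "cohort"
    spec = _spec_from_config(state.config)
    state.cohort = generate_cohort(spec)
    state.table = write_cohort(state.cohort, cohort_dir)
    return sorted(cohort_dir.iterdir())


def _stage_preprocess(state: _RunState) -> list[Path]:
    cfg = state.config.preprocess
    out = state.out / "preproc"
    out.mkdir(parents=True, exist_ok=True)
    table = state.load_table()
    cohort = state.cohort
    cohort_dir = state.out / "cohort"
    if cohort is not None:
        series_of = lambda sid: cohort.series[sid]
        motion = dict(cohort.motion)
        masks = cohort.masks
        tr = cohort.spec.tr_seconds
    else:  # rerun from on-disk synth outputs
        tr = state.config.synth["tr_seconds"]
        paths = {sid: cohort_dir / p for sid, p in zip(table["subject_id"], table["bold_path"])}
        series_of = lambda sid: load_bold(paths[sid], tr=tr)
        motion = {
            sid: pd.read_csv(cohort_dir / mp, sep="\t")
            for sid, mp in zip(table["subject_id"], table["motion_path"])
        }
        masks = {
            name: load_volume(cohort_dir / f"{name}_mask.nii.gz")[0] > 0
            for name in ("wm", "csf", "brain")
        }
    qc = motion_qc(motion)
    qc.to_csv(out / "motion_qc.tsv", sep="\t", index=False)
    outputs = [out / "motion_qc.tsv"]
    from .bold import save_bold

    for sid in table["subject_id"]:
        series = preprocess_series(
            series_of(sid),
            motion[sid],
            masks,
            n_drop=cfg["drop_initial"],
            low_hz=cfg["low_hz"],
            high_hz=cfg["high_hz"],
        )
        state.preproc[sid] = series
        path = out / f"{sid}_preproc.nii.gz"
        save_bold(series, path)
        outputs.append(path)
    return outputs


def _stage_fcd(state: _RunState) -> list[Path]:
    cfg = state.config.fcd
    out = state.out / "fcd"
    out.mkdir(parents=True, exist_ok=True)
    table = state.load_table()
    params = FcdParams(
        r_threshold=cfg["r_threshold"], adjacency=cfg["adjacency"], fwhm_mm=cfg["fwhm_mm"]
    )
    if state.cohort is not None:
        mask = threshold_gm_mask(
            state.cohort.gm_probability, state.config.preprocess["gm_threshold"]
        )
    else:
        mask = state.gm_mask()
    kinds = {"global": ["global"], "local": ["local"], "both": ["global", "local"]}[cfg["kind"]]
    outputs: list[Path] = []
    mask_hash = hashlib.sha256(np.packbits(mask).tobytes()).hexdigest()[:16]
    for sid in table["subject_id"]:
        series = state.preproc.get(sid)
        if series is None:
            series = load_bold(state.out / "preproc" / f"{sid}_preproc.nii.gz")
        per_subject = {}
        for kind in kinds:
            compute = compute_gfcd if kind == "global" else compute_lfcd
            fmap = smooth_fcd(normalize_fcd(compute(series, mask, params)))
            suffix = "gfcd" if kind == "global" else "lfcd"
            path = out / f"{sid}_{suffix}_norm_s{cfg['fwhm_mm']:g}.nii.gz"
            save_volume(fmap.data, fmap.affine, path)
            outputs.append(path)
            outputs.append(
                _sidecar(
                    path,
                    {
                        "r_threshold": cfg["r_threshold"],
                        "adjacency": cfg["adjacency"],
                        "fwhm_mm": cfg["fwhm_mm"],
                        "kind": kind,
                        "state": "smoothed",
                        "mask_hash": mask_hash,
                    },
                )
            )
            per_subject[kind] = fmap.data
        state.maps[sid] = per_subject
    save_volume(mask.astype(np.int16), state.cohort.affine if state.cohort else np.eye(4), out / "gm_mask.nii.gz")
    outputs.append(out / "gm_mask.nii.gz")
    return outputs


def _collect_maps(state: _RunState, kind: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    table = state.load_table()
    mask = state.gm_mask() if state.cohort is None else threshold_gm_mask(
        state.cohort.gm_probability, state.config.preprocess["gm_threshold"]
    )
    suffix = "gfcd" if kind == "global" else "lfcd"
    rows = []
    for sid in table["subject_id"]:
        if sid in state.maps and kind in state.maps[sid]:
            data = state.maps[sid][kind]
        else:
            pattern = f"{sid}_{suffix}_norm_s*.nii.gz"
            matches = sorted((state.out / "fcd").glob(pattern))
            if not matches:
                raise FileNotFoundError(f"no FCD map for {sid} ({pattern})")
            data, _ = load_volume(matches[0])
        rows.append(data[mask])
    return np.asarray(rows), mask, table["group"].to_numpy()


def _stage_groupstats(state: _RunState) -> list[Path]:
    cfg = state.config.groupstats
    out = state.out / "groupstats"
    out.mkdir(parents=True, exist_ok=True)
    table = state.load_table()
    X, mask, labels = _collect_maps(state, state.config.mvpa["feature"])
    covs = table[cfg["covariates"]] if cfg["covariates"] else None
    stat = voxelwise_group_glm(X, labels, covariates=covs, mask=mask)
    sig = significance_mask(stat, alpha=cfg["alpha"], correction=cfg["correction"])
    affine = state.cohort.affine if state.cohort else np.eye(4)
    outputs = [
        save_volume(np.nan_to_num(stat.t), affine, out / "group_tmap.nii.gz"),
        save_volume(np.nan_to_num(stat.p, nan=1.0), affine, out / "group_pmap.nii.gz"),
        save_volume(sig.astype(np.int16), affine, out / "group_sigmask.nii.gz"),
    ]
    # demographics table: continuous age/education (pooled t), gender 2x2 (Fisher)
    cont = {}
    for var in ("age", "education"):
        a = table[table["group"] == "A"][var]
        b = table[table["group"] == "B"][var]
        cont[var] = ((len(a), a.mean(), a.std(ddof=1)), (len(b), b.mean(), b.std(ddof=1)))
    counts = pd.crosstab(table["group"], table["gender"]).reindex(
        index=["A", "B"], columns=["male", "female"], fill_value=0
    )
    tables = {}
    if (counts.to_numpy().sum(axis=0) > 0).all() and (counts.to_numpy().sum(axis=1) > 0).all():
        tables["gender"] = (counts.to_numpy(), "fisher")
    report = table1_report(continuous=cont, tables=tables)
    report_path = out / "table1.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    outputs.append(report_path)
    return outputs


def _stage_mvpa(state: _RunState) -> list[Path]:
    cfg = state.config.mvpa
    out = state.out / "mvpa"
    out.mkdir(parents=True, exist_ok=True)
    X, mask, labels = _collect_maps(state, cfg["feature"])
    folds = loocv_classify(X, labels, alpha=cfg["alpha"], C=cfg["C"], positive_label="A")
    report = classification_report(folds)
    p, _ = permutation_test(
        X,
        labels,
        n_perm=cfg["n_perm"],
        seed=np.random.default_rng(np.random.SeedSequence((state.config.seed, 97))),
        alpha=cfg["alpha"],
        C=cfg["C"],
        positive_label="A",
        stat=cfg["stat"],
        observed=report.accuracy if cfg["stat"] == "accuracy" else report.auc,
    )
    report.permutation_p = p
    weight_map = build_weight_map(folds, mask)
    affine = state.cohort.affine if state.cohort else np.eye(4)
    outputs = [save_volume(weight_map, affine, out / "weight_map.nii.gz")]
    roc = pd.DataFrame(report.roc_points, columns=["fpr", "tpr"])
    roc.to_csv(out / "roc_points.tsv", sep="\t", index=False)
    outputs.append(out / "roc_points.tsv")
    atlas_path = state.out / "cohort" / "parcels.nii.gz"
    if atlas_path.exists():
        atlas, _ = load_volume(atlas_path)
        lookup = pd.read_csv(state.out / "cohort" / "parcels.tsv", sep="\t")
        names = dict(zip(lookup["id"], lookup["name"]))
        region_table, top_cum = rank_region_weights(
            weight_map, atlas.astype(int), names=names, top_k=cfg["top_k"]
        )
        region_table.to_csv(out / "region_weights.tsv", sep="\t", index=False)
        outputs.append(out / "region_weights.tsv")
    else:
        top_cum = None
    payload = report.as_dict()
    payload["top_k"] = cfg["top_k"]
    payload["top_k_cumulative_percent"] = top_cum
    report_path = out / "report.json"
    report_path.write_text(json.dumps(payload, indent=2))
    outputs.append(report_path)
    return outputs


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "fcd": _stage_fcd,
    "groupstats": _stage_groupstats,
    "mvpa": _stage_mvpa,
}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order and write ``manifest.json``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_text = json.dumps(config.as_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_text.encode()).hexdigest(),
        version=__version__,
    )
    state = _RunState(config, out)
    for stage in STAGE_ORDER:
        if not config.stages.get(stage, False):
            continue
        t0 = time.time()
        logger.info("stage %s: starting", stage)
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                outputs = _STAGE_FUNCS[stage](state)
        except Exception as exc:
            (out / f"{stage}.partial").write_text(str(exc))
            raise PipelineError(stage, exc) from exc
        manifest.warnings.extend(f"{stage}: {w.message}" for w in caught)
        manifest.stages[stage] = {
            "elapsed_seconds": round(time.time() - t0, 3),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs if p.is_file()},
        }
        logger.info("stage %s: done (%.1fs)", stage, time.time() - t0)
    (out / "manifest.json").write_text(json.dumps(manifest.as_dict(), indent=2))
    return manifest
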