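"""Run configuration: schema, defaults, validation.

A run config is a YAML/JSON document mirroring the pipeline stages. Unknown
keys are rejected (with their path), defaults are filled, and cross-field
constraints (e.g. the bandpass upper cutoff against the Nyquist frequency
implied by the TR) are enforced before any stage executes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["RunConfig", "ConfigError", "validate_config", "DEFAULT_CONFIG"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key path."""


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "out_dir": "fcdmvpa_run",
    "log_level": "INFO",
    "stages": {
        "synth": True,
        "preprocess": True,
        "fcd": True,
        "groupstats": True,
        "mvpa": True,
    },
    "synth": {
        "n_group_a": 20,
        "n_group_b": 26,
        "grid_shape": [24, 24, 24],
        "voxel_size_mm": 3.0,
        "n_timepoints": 240,
        "tr_seconds": 2.4,
        "n_parcels": 64,
        "hub_parcels": [1, 16, 52, 61],
        "coupling_a": 3.0,
        "coupling_b": 1.0,
        "parcel_loading": 1.0,
        "noise_sd": 0.5,
        "ar_coeff": 0.0,
    },
    "preprocess": {
        "drop_initial": 10,
        "low_hz": 0.01,
        "high_hz": 0.08,
        "gm_threshold": 0.20,
    },
    "fcd": {
        "kind": "global",
        "r_threshold": 0.6,
        "adjacency": 26,
        "fwhm_mm": 8.0,
    },
    "groupstats": {
        "alpha": 0.05,
        "correction": "none",
        "covariates": ["age", "gender", "education"],
    },
    "mvpa": {
        "alpha": 0.05,
        "C": 1.0,
        "n_perm": 5000,
        "stat": "accuracy",
        "top_k": 20,
        "feature": "global",
    },
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults filled)."""

    seed: int
    out_dir: str
    log_level: str
    stages: dict[str, bool]
    synth: dict[str, Any]
    preprocess: dict[str, Any]
    fcd: dict[str, Any]
    groupstats: dict[str, Any]
    mvpa: dict[str, Any]
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "stages": self.stages,
            "synth": self.synth,
            "preprocess": self.preprocess,
            "fcd": self.fcd,
            "groupstats": self.groupstats,
            "mvpa": self.mvpa,
        }


def _merge(defaults: dict, user: dict, path: str) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{here}: expected a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ConfigError(message)


def _check_number(cfg: dict, section: str, key: str, lo=None, hi=None, strict_lo=False):
    value = cfg[section][key]
    _require(isinstance(value, (int, float)) and not isinstance(value, bool),
             f"{section}.{key}: expected a number, got {value!r}")
    if lo is not None:
        ok = value > lo if strict_lo else value >= lo
        _require(ok, f"{section}.{key}: must be {'>' if strict_lo else '>='} {lo}, got {value}")
    if hi is not None:
        _require(value <= hi, f"{section}.{key}: must be <= {hi}, got {value}")


def validate_config(raw: str | dict | None) -> RunConfig:
    """Parse and validate a raw YAML/JSON text or mapping into a RunConfig.

    An empty config yields the full default configuration.
    """
    if raw is None:
        user: dict = {}
    elif isinstance(raw, str):
        parsed = yaml.safe_load(raw)
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, dict):
            raise ConfigError("config document must be a mapping")
        user = parsed
    elif isinstance(raw, dict):
        user = raw
    else:
        raise ConfigError(f"unsupported config type {type(raw).__name__}")
    cfg = _merge(DEFAULT_CONFIG, user, "")

    _require(isinstance(cfg["seed"], int) and not isinstance(cfg["seed"], bool),
             f"seed: expected an integer, got {cfg['seed']!r}")
    for stage, enabled in cfg["stages"].items():
        _require(isinstance(enabled, bool), f"stages.{stage}: expected true/false")
    for key in ("n_group_a", "n_group_b", "n_timepoints", "n_parcels"):
        _check_number(cfg, "synth", key, lo=1)
    _require(
        isinstance(cfg["synth"]["grid_shape"], (list, tuple))
        and len(cfg["synth"]["grid_shape"]) == 3
        and all(isinstance(g, int) and g >= 1 for g in cfg["synth"]["grid_shape"]),
        "synth.grid_shape: expected 3 positive integers",
    )
    for key in ("voxel_size_mm", "tr_seconds"):
        _check_number(cfg, "synth", key, lo=0, strict_lo=True)
    for key in ("coupling_a", "coupling_b", "parcel_loading", "noise_sd"):
        _check_number(cfg, "synth", key, lo=0)
    _check_number(cfg, "preprocess", "drop_initial", lo=0)
    _require(cfg["preprocess"]["drop_initial"] < cfg["synth"]["n_timepoints"],
             "preprocess.drop_initial: must be below synth.n_timepoints")
    _check_number(cfg, "preprocess", "low_hz", lo=0, strict_lo=True)
    _check_number(cfg, "preprocess", "high_hz", lo=0, strict_lo=True)
    _require(cfg["preprocess"]["low_hz"] < cfg["preprocess"]["high_hz"],
             "preprocess.low_hz must be below preprocess.high_hz")
    nyquist = 1.0 / (2.0 * cfg["synth"]["tr_seconds"])
    _require(
        cfg["preprocess"]["high_hz"] < nyquist,
        f"preprocess.high_hz: {cfg['preprocess']['high_hz']} exceeds the Nyquist "
        f"frequency {nyquist:.4f} Hz implied by tr_seconds={cfg['synth']['tr_seconds']}",
    )
    _check_number(cfg, "preprocess", "gm_threshold", lo=0, hi=1)
    _require(cfg["fcd"]["kind"] in ("global", "local", "both"),
             f"fcd.kind: expected global|local|both, got {cfg['fcd']['kind']!r}")
    r = cfg["fcd"]["r_threshold"]
    _require(isinstance(r, (int, float)) and -1 < r < 1,
             f"fcd.r_threshold: must lie in (-1, 1), got {r!r}")
    _require(cfg["fcd"]["adjacency"] in (6, 18, 26),
             f"fcd.adjacency: expected 6, 18 or 26, got {cfg['fcd']['adjacency']!r}")
    _check_number(cfg, "fcd", "fwhm_mm", lo=0)
    _check_number(cfg, "groupstats", "alpha", lo=0, hi=1, strict_lo=True)
    _require(cfg["groupstats"]["correction"] in ("none", "fdr", "bonferroni"),
             f"groupstats.correction: expected none|fdr|bonferroni")
    _check_number(cfg, "mvpa", "alpha", lo=0, hi=1, strict_lo=True)
    _check_number(cfg, "mvpa", "C", lo=0, strict_lo=True)
    _check_number(cfg, "mvpa", "n_perm", lo=1)
    _require(cfg["mvpa"]["stat"] in ("accuracy", "auc"),
             f"mvpa.stat: expected accuracy|auc, got {cfg['mvpa']['stat']!r}")
    _check_number(cfg, "mvpa", "top_k", lo=1)
    _require(cfg["mvpa"]["feature"] in ("global", "local"),
             "mvpa.feature: expected global|local")

    return RunConfig(
        seed=cfg["seed"],
        out_dir=cfg["out_dir"],
        log_level=cfg["log_level"],
        stages=cfg["stages"],
        synth=cfg["synth"],
        preprocess=cfg["preprocess"],
        fcd=cfg["fcd"],
        groupstats=cfg["groupstats"],
        mvpa=cfg["mvpa"],
    )
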