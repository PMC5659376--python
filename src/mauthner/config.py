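"""Run configuration, overrides and reproducibility manifests.

A run configuration is a flat mapping whose numeric keys carry unit
suffixes (`_nS`, `_mV`, `_ms`, `_pA`, `_C`).  Values are resolved with the
precedence CLI > file > defaults; unknown keys are rejected by name.
Every CLI run writes a manifest (resolved configuration + package version
+ SHA-256 checksums of the outputs) from which the result files can be
regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import __version__ as _pkg_version
from .mcell import DEFAULT_CALIBRATION, MCellModel

__all__ = ["DEFAULTS", "resolve_config", "model_from_config", "write_manifest",
           "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


DEFAULTS: dict = {
    # model conductances (nS); gKv11 and gKv11_kvb2 are mutually exclusive
    "gKv74_nS": 0.0,
    "gKv11_nS": 0.0,
    "gKv11_kvb2_nS": 0.0,
    # integration
    "dt_ms": 0.025,
    "settle_ms": 100.0,
    "temperature_C": 25.0,
    "v_init_mV": -85.0,
    # stimulus
    "amplitude_pA": 0.0,
    "duration_ms": 100.0,
    # voltage-clamp protocol
    "holding_mV": -80.0,
    "step_min_mV": -80.0,
    "step_max_mV": 50.0,
    "step_increment_mV": 10.0,
    "step_duration_ms": 200.0,
    "sample_interval_ms": 0.1,
    # fixtures
    "seed": 0,
    "noise_sd": 0.02,
    "leak_uS": 2.0,
}

_UNIT_SUFFIXES = ("_nS", "_mV", "_ms", "_pA", "_C", "_uS", "_Hz")


def _check_keys(layer: dict, name: str) -> None:
    for key, value in layer.items():
        if key not in DEFAULTS:
            raise ConfigError(f"unknown configuration key {key!r} in {name}")
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            if key not in ("seed", "noise_sd") and not key.endswith(_UNIT_SUFFIXES):
                raise ConfigError(
                    f"numeric key {key!r} in {name} lacks a unit suffix"
                )


def resolve_config(
    file_overrides: dict | None = None,
    cli_overrides: dict | None = None,
    defaults: dict | None = None,
) -> dict:
    """Merge defaults < file < CLI; validate keys and consistency."""
    resolved = dict(DEFAULTS if defaults is None else defaults)
    for layer, name in ((file_overrides, "config file"), (cli_overrides, "command line")):
        if layer:
            _check_keys(layer, name)
            resolved.update(layer)
    if resolved["gKv11_nS"] > 0 and resolved["gKv11_kvb2_nS"] > 0:
        raise ConfigError(
            "gKv11_nS and gKv11_kvb2_nS are both nonzero: the model carries "
            "either Kv1.1 alone or Kv1.1 coexpressed with Kvb2, not both"
        )
    return resolved


def load_config_file(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return data


def model_from_config(cfg: dict) -> MCellModel:
    kvb2 = cfg["gKv11_kvb2_nS"] > 0
    return MCellModel(
        g_kv74_nS=cfg["gKv74_nS"],
        g_kv1_nS=cfg["gKv11_kvb2_nS"] if kvb2 else cfg["gKv11_nS"],
        kvb2=kvb2,
        v_init_mV=cfg["v_init_mV"],
        temperature_C=cfg["temperature_C"],
        settle_ms=cfg["settle_ms"],
        calibration=DEFAULT_CALIBRATION,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir, resolved_cfg: dict, outputs) -> Path:
    """Write manifest.json next to the outputs; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "mauthner",
        "version": _pkg_version,
        "config": resolved_cfg,
        "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
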