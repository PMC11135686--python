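"""Configuration, table schemas, and reproducibility plumbing.

Tables are comma-separated UTF-8 text with a header row and '.' decimals;
floats are written with 17 significant digits so write-then-read round-trips
bit-identically.  Every CLI command writes a JSON manifest (config hash,
seed, package version) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, SchemaError
from .pathway_model import PathwayParams, default_params

__all__ = ["RunConfig", "load_config", "save_config", "read_table",
           "write_table", "write_manifest", "TABLE_SCHEMAS", "params_from_config"]

TABLE_SCHEMAS = {
    "timecourse": ["dose", "time", "observable", "value", "sd"],
    "dose_response": ["receptor_fc", "response_fc", "replicate"],
    "per_cell": ["cell_id", "R1_0", "R2_0", "S2_0", "k_NFR"],
    "scan": ["r1_mult", "r2_mult", "s2_mult", "rel_psmad2", "n2c_fc"],
    "minimal_scan": ["R1tot", "R2tot", "Sa"],
    "profile": ["param", "value", "objective"],
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with defaults filled."""

    preset: str = "hacat_like"
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"
    param_overrides: dict = field(default_factory=dict)
    command_options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw)
    # validate overrides against PathwayParams by constructing the preset
    params_from_config(cfg)
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def params_from_config(cfg: RunConfig) -> PathwayParams:
    """Build the preset with overrides applied; bad keys/values raise ConfigError."""
    from dataclasses import replace

    try:
        p = default_params(cfg.preset)
    except Exception as exc:
        raise ConfigError(f"preset: {exc}") from exc
    valid = {f.name for f in fields(PathwayParams)}
    for key, value in cfg.param_overrides.items():
        if key not in valid:
            raise ConfigError(f"param_overrides.{key}: unknown parameter")
        try:
            p = replace(p, **{key: float(value)})
        except Exception as exc:
            raise ConfigError(f"param_overrides.{key}: {exc}") from exc
    return p


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> None:
    """Write a CSV table, optionally enforcing a named schema."""
    if schema is not None:
        _check_schema(df, schema)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path, schema: str | None = None) -> pd.DataFrame:
    """Read a CSV table, optionally validating against a named schema."""
    df = pd.read_csv(path, float_precision="round_trip")
    if schema is not None:
        _check_schema(df, schema)
    return df


def _check_schema(df: pd.DataFrame, schema: str) -> None:
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    missing = [c for c in TABLE_SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"schema {schema!r}: missing column(s) {missing}")


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(out_dir, command: str, cfg_dict: dict, seed: int) -> Path:
    """Record what produced the outputs in <out_dir>/manifest.json."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": cfg_dict,
        "config_hash": config_hash(cfg_dict),
        "seed": seed,
        "version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
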