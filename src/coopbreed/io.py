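"""Configuration files, result writers, and run manifests.

Configs are YAML with three optional sections::

    ranges:            # lo/hi pairs, keys = ModelParams field names
      s0: [0.5, 0.75]
    params:            # fixed parameter values for single-point evaluation
      r_kin: 0.2
    experiment:        # driver settings (n_draws, grid, ...)
      n_draws: 200

Sweep results are written as long-format CSV (one statistic per row, stable
schema across experiment types); NaN statistics are written as empty fields
(pandas convention) and read back as NaN.  Every experiment run writes a
``manifest.json`` recording the config snapshot, root seed, package
version, timestamps and a sha256 checksum per output file, which is enough
to reproduce the run exactly.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .params import PARAM_FIELDS, ModelParams, ParamError, ParamRanges

__all__ = [
    "read_config",
    "write_config",
    "ranges_from_config",
    "params_from_config",
    "sha256_file",
    "write_manifest",
    "read_manifest",
    "write_results_csv",
    "read_results_csv",
]


def read_config(path) -> dict:
    """Load a YAML config; malformed files raise with file/line context."""
    path = Path(path)
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ParamError(f"malformed config {path}: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ParamError(f"config {path} must be a mapping at top level")
    return cfg


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def ranges_from_config(cfg: dict) -> ParamRanges:
    """Build ParamRanges from the ``ranges`` section (defaults elsewhere)."""
    section = cfg.get("ranges", {}) or {}
    unknown = set(section) - set(PARAM_FIELDS)
    if unknown:
        raise ParamError(f"unknown range field(s): {sorted(unknown)}")
    kw = {}
    for name, bounds in section.items():
        if isinstance(bounds, (int, float)):
            bounds = [bounds, bounds]
        if len(bounds) != 2:
            raise ParamError(f"range for {name!r} must be [lo, hi]")
        kw[name] = (float(bounds[0]), float(bounds[1]))
    return ParamRanges(**kw).validate()


def params_from_config(cfg: dict) -> ModelParams:
    """Build a parameter point from the ``params`` section (defaults elsewhere)."""
    section = cfg.get("params", {}) or {}
    unknown = set(section) - set(PARAM_FIELDS)
    if unknown:
        raise ParamError(f"unknown parameter field(s): {sorted(unknown)}")
    return ModelParams(**{k: float(v) for k, v in section.items()}).validate()


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed: int, outputs,
                   started: str | None = None) -> Path:
    """Write ``manifest.json`` listing every output with its checksum."""
    out_dir = Path(out_dir)
    entries = []
    for f in outputs:
        f = Path(f)
        entries.append({"path": f.name, "sha256": sha256_file(f)})
    manifest = {
        "package": "coopbreed",
        "version": __version__,
        "seed": int(seed),
        "config": config,
        "started": started or datetime.now(timezone.utc).isoformat(),
        "finished": datetime.now(timezone.utc).isoformat(),
        "outputs": entries,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def read_manifest(out_dir) -> dict:
    with open(Path(out_dir) / "manifest.json") as fh:
        manifest = json.load(fh)
    for entry in manifest["outputs"]:
        f = Path(out_dir) / entry["path"]
        if not f.exists():
            raise FileNotFoundError(f"manifest lists missing file {f}")
    return manifest


RESULT_DTYPES = {"grid_value": float, "value": float}


def write_results_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_results_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col, dtype in RESULT_DTYPES.items():
        if col in df.columns:
            df[col] = df[col].astype(dtype)
    return df
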