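"""File I/O: clinical-curve CSVs with JSON sidecars, time-series CSVs,
parameter/config files, and run manifests."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bcpm import BCPMParams
from .calibration import CURVE_KINDS, KIND_UNIT, ClinicalDataset
from .coupling import PDParams
from .pk import PKParams

logger = logging.getLogger("bonepkpd")


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


def write_clinical_csv(ds: ClinicalDataset, path: str | Path) -> None:
    """Write a curve as CSV (columns t_d, value, unit) plus a JSON sidecar
    carrying the metadata (kind, regimen, site f_bm)."""
    path = Path(path)
    df = pd.DataFrame({"t_d": ds.t, "value": ds.values,
                       "unit": [ds.unit] * len(ds.t)})
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = {"name": ds.name, "kind": ds.kind, "regimen": ds.regimen,
               "fbm": ds.fbm}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_clinical_csv(path: str | Path) -> ClinicalDataset:
    """Read a curve CSV + sidecar back; schema violations name the column
    or row at fault."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("t_d", "value", "unit"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for i, v in enumerate(df["value"], start=2):  # header is line 1
        if not np.isfinite(v):
            raise ValueError(f"{path}: non-finite value at row {i}")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    kind = meta.get("kind")
    if kind not in CURVE_KINDS:
        raise ValueError(f"{sidecar_path}: invalid kind {kind!r}")
    fbm = meta.get("fbm")
    if fbm is not None and not 0 < fbm < 100:
        raise ValueError(f"{sidecar_path}: fbm must lie in (0, 100)")
    units = df["unit"].unique()
    if len(units) != 1:
        raise ValueError(f"{path}: inconsistent units {list(units)}")
    if units[0] != KIND_UNIT[kind]:
        raise ValueError(f"{path}: unit {units[0]!r} does not match "
                         f"kind {kind!r} (expected {KIND_UNIT[kind]!r})")
    return ClinicalDataset(name=meta.get("name", path.stem), kind=kind,
                           regimen=meta.get("regimen", ""),
                           t=df["t_d"].to_numpy(),
                           values=df["value"].to_numpy(),
                           unit=str(units[0]), fbm=fbm)


def read_clinical_dir(path: str | Path) -> list[ClinicalDataset]:
    return [read_clinical_csv(p) for p in sorted(Path(path).glob("*.csv"))]


def write_timeseries_csv(ts, path: str | Path) -> None:
    """Write any object exposing ``to_frame()`` as CSV."""
    ts.to_frame().to_csv(path, index=False, float_format="%.10g")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration/parameter file."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(path.read_text())
    if path.suffix == ".json":
        return json.loads(path.read_text())
    raise ValueError(f"unsupported config format: {path.suffix}")


def pk_params_from_config(cfg: dict) -> PKParams:
    return PKParams(**cfg)


def bcpm_params_from_config(cfg: dict) -> BCPMParams:
    return BCPMParams.from_dict(cfg)


def pd_params_from_config(cfg: dict) -> PDParams:
    return PDParams(**cfg)


def write_manifest(out_dir: str | Path, config: dict, seed: int | None
                   ) -> Path:
    """Record what produced a run: config hash, seed, package versions."""
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {"bonepkpd": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


__all__ = [
    "setup_logging", "write_clinical_csv", "read_clinical_csv",
    "read_clinical_dir", "write_timeseries_csv", "load_config",
    "pk_params_from_config", "bcpm_params_from_config",
    "pd_params_from_config", "write_manifest", "logger",
]
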