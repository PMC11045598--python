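"""Raster, tabular and configuration I/O.

Rasters are written as TIFF via :mod:`tifffile` with a JSON sidecar
(``<name>.tif.json``) carrying the georeferencing-adjacent metadata the
package needs to round-trip losslessly: pixel size, nodata code, class codes.
Categorical maps are 8-bit with explicit integer nodata (default 255);
continuous layers are 32-bit float with NaN nodata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import DEFAULT_NODATA, DEFAULT_PIXEL_SIZE, LulcMap
from .errors import ConfigurationError

CONFIG_SCHEMA_VERSION = 1


def write_lulc(path: str | Path, lulc: LulcMap) -> Path:
    path = Path(path)
    tifffile.imwrite(path, lulc.data.astype(np.uint8))
    meta = {
        "kind": "categorical",
        "class_codes": list(lulc.class_codes),
        "nodata": int(lulc.nodata),
        "pixel_size": float(lulc.pixel_size),
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    return path


def read_lulc(path: str | Path) -> LulcMap:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return LulcMap(
        data,
        tuple(meta["class_codes"]),
        nodata=meta.get("nodata", DEFAULT_NODATA),
        pixel_size=meta.get("pixel_size", DEFAULT_PIXEL_SIZE),
    )


def write_continuous(path: str | Path, raster: np.ndarray, pixel_size: float = DEFAULT_PIXEL_SIZE,
                     units: str = "") -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(raster, dtype=np.float32))
    meta = {"kind": "continuous", "pixel_size": float(pixel_size), "units": units,
            "nodata": "nan"}
    Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    return path


def read_continuous(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float64)


def write_json(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class RunConfig:
    """Validated run configuration for the CLI stages."""

    out_dir: str = "outputs"
    seed: int = 0
    grid_rows: int = 120
    grid_cols: int = 120
    class_codes: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    class_names: dict[int, str] = field(default_factory=dict)
    forest_code: int = 1
    epochs: tuple[int, ...] = (1985, 2000, 2010, 2020)
    projection_target_year: int = 2050
    n_scenes: int = 5
    n_reference_samples: int = 800
    train_fraction: float = 0.7
    n_trees: int = 500
    rms_target: float = 0.01
    max_iterations: int = 1000
    emission_factor: float = 10.0
    effectiveness: float = 0.8
    displacement: float = 0.1
    horizon_years: int = 30
    reporting_period_years: int = 5
    leakage_belt_width_pixels: int = 6
    c_baseline: float | None = None
    c_actual: float | None = None
    c_leakage: float | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["class_codes"] = list(self.class_codes)
        d["epochs"] = list(self.epochs)
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return d


_CONFIG_FIELDS = set(RunConfig.__dataclass_fields__)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; unknown keys and missing files are errors."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")
    version = raw.pop("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ConfigurationError(
            f"unsupported schema_version {version}; expected {CONFIG_SCHEMA_VERSION}"
        )
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "class_codes" in raw:
        raw["class_codes"] = tuple(raw["class_codes"])
    if "epochs" in raw:
        raw["epochs"] = tuple(raw["epochs"])
    if "class_names" in raw:
        raw["class_names"] = {int(k): v for k, v in raw["class_names"].items()}
    return RunConfig(**raw)


def write_config(path: str | Path, config: RunConfig) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


class RunLog:
    """Structured JSON-lines run log: one record per logged event."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def record(self, stage: str, **payload) -> None:
        import landcarbon

        entry = {"stage": stage, "package_version": landcarbon.__version__}
        entry.update(payload)
        with self.path.open("a") as fh:
            fh.write(json.dumps(entry, sort_keys=True, default=_json_default) + "\n")
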