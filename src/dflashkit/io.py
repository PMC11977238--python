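"""Readers and writers for the pipeline's standard artifacts.

Images travel as single-channel 16-bit TIFF pairs (``*_egfp.tif`` /
``*_tom.tif``) with label masks alongside; everything tabular is CSV
with fixed column schemas so each stage's output round-trips into the
next stage's input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import GroundTruth, ImageField, LAYOUT_COLUMNS

__all__ = [
    "write_field",
    "read_field",
    "write_label_mask",
    "read_label_mask",
    "write_table",
    "read_table",
    "read_plate_map",
    "write_plate_map",
    "save_config_yaml",
    "load_config_yaml",
]

WELL_COLUMNS = ["plate", "well", "n_included", "egfp_mean", "tom_mean",
                "ratio", "sufficient_n"]


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)


def write_field(field: ImageField, prefix: str | Path) -> tuple[Path, Path]:
    """Write one field as ``<prefix>_egfp.tif`` and ``<prefix>_tom.tif``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    egfp_path = prefix.with_name(prefix.name + "_egfp.tif")
    tom_path = prefix.with_name(prefix.name + "_tom.tif")
    tifffile.imwrite(egfp_path, _to_uint16(field.egfp))
    tifffile.imwrite(tom_path, _to_uint16(field.tom))
    return egfp_path, tom_path


def read_field(prefix: str | Path) -> ImageField:
    """Read a TIFF pair written by :func:`write_field`."""
    prefix = Path(prefix)
    egfp_path = prefix.with_name(prefix.name + "_egfp.tif")
    tom_path = prefix.with_name(prefix.name + "_tom.tif")
    for p in (egfp_path, tom_path):
        if not p.exists():
            raise FileNotFoundError(f"missing channel image: {p}")
    return ImageField(tifffile.imread(egfp_path).astype(float),
                      tifffile.imread(tom_path).astype(float))


def write_label_mask(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, _to_uint16(truth.label_mask))
    return path


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path, required: list[str] | None = None
               ) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input table: {path}")
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path} missing column(s): {missing}")
    return df


def write_plate_map(layout: pd.DataFrame, path: str | Path) -> Path:
    return write_table(layout[LAYOUT_COLUMNS], path)


def read_plate_map(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=["plate", "well", "role"])


def save_config_yaml(data: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path


def load_config_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing config file: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path} must contain a mapping at top level")
    return data
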