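"""File I/O: TIFF frames and masks, manifest and table CSVs, configs.

CSV dialect is fixed: UTF-8, comma separator, '.' decimal, mandatory header
row. Frames are written as 16-bit single-channel TIFFs (one file per frame),
masks as 16-bit label TIFFs (0 = background), with acquisition metadata in a
manifest CSV rather than TIFF tags.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .shape_metrics import SHAPE_COLUMNS
from .synthetic import FrameImage, SimulationResult

__all__ = ["write_experiment", "read_manifest", "read_frame", "read_mask",
           "write_shapes", "read_shapes", "load_config", "SchemaError",
           "file_sha256", "MANIFEST_COLUMNS"]

MANIFEST_COLUMNS = ["path", "mask_path", "condition", "replicate", "fov",
                    "timestamp_h", "pixel_size_um"]


class SchemaError(ValueError):
    """A table or config failed schema validation."""


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def write_experiment(result: SimulationResult, out_dir) -> Path:
    """Write frames, truth masks, manifest.csv and truth_shapes.csv.

    Returns the manifest path. Frame files are named
    ``<condition>_rep<r>_<fov>_t<hours>.tif`` with masks alongside.
    """
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for frame, mask in zip(result.frames, result.masks):
        stem = (f"{frame.condition}_rep{frame.replicate}_{frame.fov_id}"
                f"_t{frame.timestamp_h:09.3f}".replace(".", "p"))
        fpath = out / "frames" / f"{stem}.tif"
        mpath = out / "masks" / f"{stem}_mask.tif"
        tifffile.imwrite(fpath, np.clip(frame.pixels, 0, 65535).astype(np.uint16))
        tifffile.imwrite(mpath, mask.astype(np.uint16))
        rows.append({"path": str(fpath.relative_to(out)),
                     "mask_path": str(mpath.relative_to(out)),
                     "condition": frame.condition, "replicate": frame.replicate,
                     "fov": frame.fov_id, "timestamp_h": frame.timestamp_h,
                     "pixel_size_um": frame.pixel_size_um})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    mpath = out / "manifest.csv"
    manifest.to_csv(mpath, index=False)
    result.truth.to_csv(out / "truth_shapes.csv", index=False)
    return mpath


def read_manifest(path, check_files: bool = True) -> pd.DataFrame:
    """Read and validate a manifest CSV; paths are resolved relative to it."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, ["path", "condition", "replicate", "fov", "timestamp_h"],
                   f"manifest {path}")
    if not np.issubdtype(df["timestamp_h"].dtype, np.number):
        raise SchemaError(f"manifest {path}: timestamp_h must be numeric "
                          "(C-locale CSV with '.' decimal separator required)")
    root = path.parent
    df["path"] = [str(root / p) for p in df["path"]]
    if "mask_path" in df.columns:
        df["mask_path"] = [str(root / p) if isinstance(p, str) else p
                           for p in df["mask_path"]]
    if check_files:
        for i, p in enumerate(df["path"]):
            if not Path(p).exists():
                raise SchemaError(f"manifest {path} row {i}: frame file "
                                  f"{p} does not exist")
    for cond, sub in df.groupby(["condition", "replicate", "fov"]):
        if not sub["timestamp_h"].is_monotonic_increasing:
            raise SchemaError(f"manifest {path}: timestamps not sorted for "
                              f"series {cond}")
    return df


def read_frame(row) -> FrameImage:
    """Load one manifest row into a :class:`FrameImage`."""
    pixels = tifffile.imread(row["path"]).astype(float)
    return FrameImage(pixels=pixels, timestamp_h=float(row["timestamp_h"]),
                      condition=str(row["condition"]), fov_id=str(row["fov"]),
                      pixel_size_um=float(row.get("pixel_size_um", 1.0)),
                      replicate=int(row["replicate"]))


def read_mask(row) -> np.ndarray:
    return tifffile.imread(row["mask_path"]).astype(np.int32)


def write_shapes(df: pd.DataFrame, path) -> None:
    _check_columns(df, SHAPE_COLUMNS, "shape table")
    df.to_csv(path, index=False, columns=SHAPE_COLUMNS)


def read_shapes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, SHAPE_COLUMNS, f"shape table {path}")
    for col in ("area_um2", "perimeter_um", "circularity", "timestamp_h"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise SchemaError(f"shape table {path}: column {col} is not numeric "
                              "(C-locale CSV with '.' decimal separator required)")
    return df


def load_config(path) -> dict:
    """Load a YAML or JSON pipeline config."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    elif path.suffix == ".json":
        cfg = json.loads(text)
    else:
        raise SchemaError(f"unsupported config format: {path.suffix}")
    if not isinstance(cfg, dict):
        raise SchemaError("config root must be a mapping")
    return cfg


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
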