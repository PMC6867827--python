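"""Plain-text and TIFF interchange helpers.

Spot tables, Ct tables, per-cell counts and sweep sets travel as CSV;
image stacks and masks as unsigned 16-bit multi-page TIFF; results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ephys import SweepSet

SPOT_TABLE_COLUMNS = ("cell_id", "channel", "x_nm", "y_nm", "intensity")


def write_spot_table(spots: pd.DataFrame, path) -> None:
    spots.to_csv(path, index=False)


def read_spot_table(path, pixel_size_nm: float | None = None) -> pd.DataFrame:
    spots = pd.read_csv(path)
    missing = [c for c in SPOT_TABLE_COLUMNS if c not in spots.columns]
    if missing:
        raise ValueError(f"spot table {path} is missing columns: {missing}")
    if "spot_id" not in spots.columns:
        spots.insert(0, "spot_id", np.arange(len(spots)))
    if pixel_size_nm is not None:
        spots.attrs["pixel_size_nm"] = float(pixel_size_nm)
    return spots


def write_image_stack(image, path) -> None:
    arr = np.asarray(image)
    if arr.dtype.kind == "f":
        arr = np.clip(np.rint(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_image_stack(path) -> np.ndarray:
    return tifffile.imread(path)


def write_mask(mask, path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def write_sweepset(sweeps: SweepSet, path) -> None:
    sweeps.to_frame().to_csv(path, index=False)


def read_sweepset(path, epochs: dict | None = None) -> SweepSet:
    return SweepSet.from_frame(pd.read_csv(path), epochs=epochs)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")
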