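"""Readers and writers for the pipeline's on-disk artifacts.

Backscatter stacks are stored as multi-page float32 TIFFs (one page per
acquisition, nodata -9999) with the calendar, pixel spacing and nodata
value embedded as JSON in the image description, plus a sidecar CSV of
acquisition dates for spreadsheet users.  Truth and decision rasters are
single-page TIFFs; tables and ground truth travel as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stack import NODATA_DB, AcquisitionCalendar, SigmaStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_raster",
    "read_raster",
    "write_ground_truth",
    "read_ground_truth",
    "dates_sidecar_path",
]


def dates_sidecar_path(stack_path: str | Path) -> Path:
    p = Path(stack_path)
    return p.with_name(p.stem + "_dates.csv")


def write_stack(stack: SigmaStack, path: str | Path) -> Path:
    """Write a sigma-naught stack as a multi-page float32 TIFF + date CSV."""
    path = Path(path)
    values = stack.values_db.astype(np.float32)
    values = np.where(stack.nodata_mask, np.float32(NODATA_DB), values)
    meta = {
        "dates": stack.calendar.isoformat(),
        "cadence_days": stack.calendar.cadence_days,
        "pixel_spacing_m": list(stack.pixel_spacing_m),
        "nodata": NODATA_DB,
        "units": "dB",
    }
    tifffile.imwrite(path, values, description=json.dumps(meta))
    pd.DataFrame({"band": range(1, stack.n_dates + 1), "date": meta["dates"]}).to_csv(
        dates_sidecar_path(path), index=False
    )
    return path


def read_stack(path: str | Path) -> SigmaStack:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray().astype(np.float64)
        desc = tif.pages[0].description
    meta = json.loads(desc)
    calendar = AcquisitionCalendar.from_isoformat(meta["dates"], int(meta["cadence_days"]))
    nodata = float(meta.get("nodata", NODATA_DB))
    mask = values == nodata
    values = np.where(mask, 0.0, values)
    return SigmaStack(
        values_db=values,
        calendar=calendar,
        nodata_mask=mask,
        pixel_spacing_m=tuple(meta.get("pixel_spacing_m", (10.0, 10.0))),
    )


def write_raster(arr: np.ndarray, path: str | Path, description: str = "") -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(arr), description=description)
    return path


def read_raster(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_ground_truth(points: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    points.to_csv(path, index=False)
    return path


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
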