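"""Pixel counting and district/date area tables.

Areas use the pixel spacing (10 m x 10 m = 0.01 ha per pixel by default),
which tiles the map without overlap, rather than the larger resolution
cell.  Tables carry explicit Total rows/columns whose conservation is
exact; hectares are kept at full precision internally and rounded only
when tables are written out.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phenology import SoSMap
from .rules import RICE, RiceMap
from .stack import SOS_SENTINEL

__all__ = ["pixels_to_hectares", "district_area_table", "sos_area_table", "add_totals"]

TOTAL_LABEL = "Total"


def pixels_to_hectares(n_pixels: int | np.ndarray, pixel_spacing_m: tuple[float, float] = (10.0, 10.0)) -> float | np.ndarray:
    """Hectares covered by ``n_pixels`` pixels of the given spacing."""
    sx, sy = pixel_spacing_m
    if sx <= 0 or sy <= 0:
        raise ValueError("pixel spacing must be positive")
    if np.any(np.asarray(n_pixels) < 0):
        raise ValueError("pixel counts must be non-negative")
    area = np.asarray(n_pixels, dtype=np.float64) * (sx * sy) / 10_000.0
    return float(area) if np.isscalar(n_pixels) or np.ndim(n_pixels) == 0 else area


def add_totals(df: pd.DataFrame, row: bool = True, col: bool = True) -> pd.DataFrame:
    """Append exact Total row and/or column to an area table."""
    out = df.copy()
    if col and df.shape[1] > 1:
        out[TOTAL_LABEL] = out.sum(axis=1)
    if row:
        out.loc[TOTAL_LABEL] = out.sum(axis=0)
    return out


def _district_labels(
    district_raster: np.ndarray, district_names: Mapping[int, str] | None
) -> tuple[np.ndarray, list]:
    ids = np.unique(district_raster)
    if district_names is None:
        labels = [int(i) for i in ids]
    else:
        labels = [district_names.get(int(i), str(int(i))) for i in ids]
    return ids, labels


def district_area_table(
    rice_map: RiceMap | np.ndarray,
    district_raster: np.ndarray,
    pixel_spacing_m: tuple[float, float] = (10.0, 10.0),
    district_names: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Rice hectares per district, with an exact Total row.

    Unclassifiable pixels never contribute area.
    """
    rice = rice_map.rice if isinstance(rice_map, RiceMap) else np.asarray(rice_map)
    if isinstance(rice_map, RiceMap):
        pixel_spacing_m = rice_map.pixel_spacing_m
    district_raster = np.asarray(district_raster)
    if rice.shape != district_raster.shape:
        raise ValueError(
            f"rice map {rice.shape} and district raster {district_raster.shape} differ"
        )
    ids, labels = _district_labels(district_raster, district_names)
    is_rice = rice == RICE
    counts = [int(is_rice[district_raster == i].sum()) for i in ids]
    df = pd.DataFrame(
        {"area_ha": [pixels_to_hectares(c, pixel_spacing_m) for c in counts]},
        index=pd.Index(labels, name="district"),
    )
    return add_totals(df, col=False)


def sos_area_table(
    sos_map: SoSMap | np.ndarray,
    district_raster: np.ndarray,
    calendar=None,
    pixel_spacing_m: tuple[float, float] = (10.0, 10.0),
    district_names: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """District x SoS-date hectares with exact Total row and column."""
    if isinstance(sos_map, SoSMap):
        sos = sos_map.sos_index
        calendar = sos_map.calendar
        pixel_spacing_m = sos_map.pixel_spacing_m
    else:
        sos = np.asarray(sos_map)
        if calendar is None:
            raise ValueError("a calendar is required when passing a bare SoS raster")
    district_raster = np.asarray(district_raster)
    if sos.shape != district_raster.shape:
        raise ValueError(
            f"SoS raster {sos.shape} and district raster {district_raster.shape} differ"
        )
    ids, labels = _district_labels(district_raster, district_names)
    t = len(calendar)
    table = np.zeros((len(ids), t), dtype=np.int64)
    defined = sos != SOS_SENTINEL
    for k, i in enumerate(ids):
        sel = defined & (district_raster == i)
        if sel.any():
            table[k] = np.bincount(sos[sel].astype(np.int64), minlength=t)
    df = pd.DataFrame(
        pixels_to_hectares(table, pixel_spacing_m),
        index=pd.Index(labels, name="district"),
        columns=calendar.isoformat(),
    )
    return add_totals(df)
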