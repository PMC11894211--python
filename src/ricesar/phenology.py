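"""Start-of-Season retrieval and seasonal binning.

The start of season (SoS) of a rice pixel is the acquisition date of the
minimum dB value of its temporal signature — the agronomic flooding event.
SoS is reported at acquisition dates only (12-day quantisation); season
bins (early / major / late sown windows) are per-year inputs, not computed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .rules import RiceMap
from .stack import AcquisitionCalendar, SOS_SENTINEL

__all__ = ["SoSMap", "SeasonBins", "detect_sos", "bin_sos_areas"]


@dataclass
class SoSMap:
    """Per-pixel SoS acquisition index with its calendar legend."""

    sos_index: np.ndarray  # int16; SOS_SENTINEL outside rice
    calendar: AcquisitionCalendar
    pixel_spacing_m: tuple[float, float] = (10.0, 10.0)

    def __post_init__(self) -> None:
        self.sos_index = np.asarray(self.sos_index, dtype=np.int16)
        defined = self.sos_index != SOS_SENTINEL
        if defined.any():
            vals = self.sos_index[defined]
            if vals.min() < 0 or vals.max() >= len(self.calendar):
                raise ValueError("SoS indices must be valid calendar positions")

    @classmethod
    def from_rice_map(cls, rice_map: RiceMap) -> "SoSMap":
        return cls(
            sos_index=rice_map.sos_index.copy(),
            calendar=rice_map.calendar,
            pixel_spacing_m=rice_map.pixel_spacing_m,
        )

    def legend(self) -> dict[int, dt.date]:
        return dict(enumerate(self.calendar.dates))

    def date_of(self, index: int) -> dt.date:
        return self.calendar.dates[index]


def detect_sos(
    series_db: np.ndarray,
    calendar: AcquisitionCalendar,
    window: tuple[dt.date, dt.date] | None = None,
    valid_mask: np.ndarray | None = None,
) -> dt.date | None:
    """Date of the minimum dB value within ``window`` (ties: earliest date).

    Returns None when no valid acquisition falls inside the window.
    """
    series_db = np.asarray(series_db, dtype=np.float64)
    if series_db.shape[0] != len(calendar):
        raise ValueError("series length must match the calendar")
    valid = np.isfinite(series_db)
    if valid_mask is not None:
        valid &= np.asarray(valid_mask, dtype=bool)
    if window is not None:
        w0, w1 = window
        if w0 > w1:
            raise ValueError("window must be ordered")
        in_win = np.array([w0 <= d <= w1 for d in calendar.dates])
        valid &= in_win
    idx = np.nonzero(valid)[0]
    if idx.size == 0:
        return None
    return calendar.dates[int(idx[np.argmin(series_db[idx])])]


@dataclass(frozen=True)
class SeasonBins:
    """Inclusive early / major / late sowing windows for one season."""

    early: tuple[dt.date, dt.date]
    major: tuple[dt.date, dt.date]
    late: tuple[dt.date, dt.date]

    def __post_init__(self) -> None:
        for name in ("early", "major", "late"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} bin must be ordered")
        if not (self.early[1] < self.major[0] and self.major[1] < self.late[0]):
            raise ValueError("bins must be ordered and non-overlapping")

    def bin_of(self, when: dt.date) -> str | None:
        for name in ("early", "major", "late"):
            lo, hi = getattr(self, name)
            if lo <= when <= hi:
                return name
        return None


def bin_sos_areas(
    sos_area_by_date: Mapping[dt.date, float],
    bins: SeasonBins,
) -> dict[str, float]:
    """Sum per-SoS-date areas into the early/major/late sowing windows.

    Every SoS date must fall in exactly one bin; dates outside all bins
    raise, listing the offenders.  The three bins conserve the total area.
    """
    totals = {"early": 0.0, "major": 0.0, "late": 0.0}
    orphans = []
    for when, area in sos_area_by_date.items():
        name = bins.bin_of(when)
        if name is None:
            orphans.append(when)
        else:
            totals[name] += float(area)
    if orphans:
        listing = ", ".join(d.isoformat() for d in sorted(orphans))
        raise ValueError(f"SoS dates outside every season bin: {listing}")
    return totals
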