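"""Core containers for multi-temporal SAR backscatter scenes.

A scene is a stack of co-registered acquisitions of the radar backscattering
coefficient sigma-naught (dB) on a regular pixel grid, together with the
acquisition calendar.  Everything downstream (filtering, rule classification,
phenology) consumes these containers.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

#: Sentinel written to rasters where no backscatter value is available.
NODATA_DB = -9999.0

#: Integer codes for the land-cover classes of the synthetic truth.
CLASS_CODES = {"rice": 1, "nonrice_veg": 2, "water": 3, "urban": 4}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}

#: Sentinel for "no start of season" in SoS index rasters.
SOS_SENTINEL = -1


@dataclass(frozen=True)
class AcquisitionCalendar:
    """Ordered satellite acquisition dates at a nominal repeat cadence.

    Dates must be strictly increasing and every gap must be an integer
    multiple of ``cadence_days`` (missing passes are allowed).  Rule-based
    classification needs at least 10 acquisitions to be meaningful; that
    depth requirement is enforced where calendars are generated and where
    pixels are classified, so short calendars remain constructible for
    signal-conditioning utilities.
    """

    dates: tuple[dt.date, ...]
    cadence_days: int = 12

    def __post_init__(self) -> None:
        if len(self.dates) < 2:
            raise ValueError("calendar needs at least two acquisition dates")
        if self.cadence_days <= 0:
            raise ValueError("cadence_days must be positive")
        object.__setattr__(self, "dates", tuple(self.dates))
        diffs = np.diff([d.toordinal() for d in self.dates])
        if np.any(diffs <= 0):
            raise ValueError("acquisition dates must be strictly increasing")
        if np.any(diffs % self.cadence_days != 0):
            raise ValueError(
                "gaps between acquisitions must be integer multiples of "
                f"the {self.cadence_days}-day cadence"
            )

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def start(self) -> dt.date:
        return self.dates[0]

    @property
    def end(self) -> dt.date:
        return self.dates[-1]

    @property
    def day_offsets(self) -> np.ndarray:
        """Days of each acquisition since the first one."""
        first = self.dates[0].toordinal()
        return np.array([d.toordinal() - first for d in self.dates], dtype=np.int64)

    def offset_of(self, when: dt.date) -> int:
        """Days from the first acquisition to ``when`` (may be negative)."""
        return when.toordinal() - self.dates[0].toordinal()

    def nearest_index(self, when: dt.date) -> int:
        """Index of the acquisition closest in time to ``when`` (ties: earlier)."""
        offs = np.abs(self.day_offsets - self.offset_of(when))
        return int(np.argmin(offs))

    def index_of(self, when: dt.date) -> int:
        try:
            return self.dates.index(when)
        except ValueError:
            raise KeyError(f"{when.isoformat()} is not an acquisition date") from None

    def isoformat(self) -> list[str]:
        return [d.isoformat() for d in self.dates]

    @classmethod
    def from_isoformat(cls, dates: list[str], cadence_days: int = 12) -> "AcquisitionCalendar":
        return cls(tuple(dt.date.fromisoformat(d) for d in dates), cadence_days)


@dataclass
class SigmaStack:
    """T x H x W stack of sigma-naught values in dB with its calendar.

    ``nodata_mask`` is True where no observation exists; values there are
    ignored by every operation and re-written as :data:`NODATA_DB` on export.
    """

    values_db: np.ndarray
    calendar: AcquisitionCalendar
    nodata_mask: np.ndarray | None = None
    pixel_spacing_m: tuple[float, float] = (10.0, 10.0)

    def __post_init__(self) -> None:
        self.values_db = np.asarray(self.values_db, dtype=np.float64)
        if self.values_db.ndim != 3:
            raise ValueError("values_db must be a T x H x W array")
        if self.values_db.shape[0] != len(self.calendar):
            raise ValueError(
                f"stack has {self.values_db.shape[0]} bands but the calendar "
                f"lists {len(self.calendar)} acquisitions"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values_db.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values_db.shape:
                raise ValueError("nodata_mask shape must match values_db")
        if not np.all(np.isfinite(self.values_db[~self.nodata_mask])):
            raise ValueError("non-finite backscatter outside the nodata mask")

    @property
    def n_dates(self) -> int:
        return self.values_db.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values_db.shape[1], self.values_db.shape[2]

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def series(self, row: int, col: int) -> np.ndarray:
        """Temporal signature of one pixel (dB, NaN where nodata)."""
        s = self.values_db[:, row, col].astype(np.float64).copy()
        s[self.nodata_mask[:, row, col]] = np.nan
        return s

    def with_values(self, values_db: np.ndarray) -> "SigmaStack":
        """Copy of this stack with replaced values, same calendar and masks."""
        return SigmaStack(
            values_db=np.asarray(values_db, dtype=np.float64),
            calendar=self.calendar,
            nodata_mask=self.nodata_mask.copy(),
            pixel_spacing_m=self.pixel_spacing_m,
        )


@dataclass
class SceneTruth:
    """Ground truth of a synthetic scene.

    ``class_raster`` holds :data:`CLASS_CODES`; ``sos_raster`` the acquisition
    index of the flooding minimum for rice pixels (:data:`SOS_SENTINEL`
    elsewhere); ``district_raster`` an administrative label for every pixel.
    """

    class_raster: np.ndarray
    sos_raster: np.ndarray
    district_raster: np.ndarray
    pixel_spacing_m: tuple[float, float] = (10.0, 10.0)

    def __post_init__(self) -> None:
        self.class_raster = np.asarray(self.class_raster, dtype=np.uint8)
        self.sos_raster = np.asarray(self.sos_raster, dtype=np.int16)
        self.district_raster = np.asarray(self.district_raster, dtype=np.int16)
        if not (self.class_raster.shape == self.sos_raster.shape == self.district_raster.shape):
            raise ValueError("truth rasters must share one grid")
        rice = self.class_raster == CLASS_CODES["rice"]
        if np.any(self.sos_raster[rice] == SOS_SENTINEL):
            raise ValueError("rice pixels must carry a start-of-season index")
        if np.any(self.sos_raster[~rice] != SOS_SENTINEL):
            raise ValueError("non-rice pixels must carry the SoS sentinel")

    @property
    def rice_mask(self) -> np.ndarray:
        return self.class_raster == CLASS_CODES["rice"]
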