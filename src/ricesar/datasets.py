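"""Published rice-area statistics for the Cauvery Delta Zone (Tamil Nadu).

Two reference tables for the samba seasons 2017-18 through 2022-23 are
bundled as plain CSV:

* district-wise rice area (ha) per season, and
* district x SoS-date rice area (ha) at the 12-day acquisition cadence,
  including the published per-date zone totals ('Total' rows).

They serve as worked inputs for the area-accounting and season-binning
operations (district aggregation, early/major/late sowing windows).  The
source statistics carry occasional +/-1-2 ha internal rounding slips
between cells and their printed totals; cells are stored as published.

Seasons are keyed "2017-18" ... "2022-23".
"""

from __future__ import annotations

import datetime as dt
from importlib import resources

import pandas as pd

from .phenology import SeasonBins

__all__ = [
    "YEARS",
    "DISTRICTS",
    "SEASON_BINS",
    "load_rice_area",
    "load_sos_area",
    "sos_totals_by_date",
]

YEARS = ("2017-18", "2018-19", "2019-20", "2020-21", "2021-22", "2022-23")

DISTRICTS = ("Thanjavur", "Thiruvarur", "Nagapattinam", "Cuddalore", "Tiruchirappalli")

_D = dt.date

#: Early / major / late sowing windows per season (inclusive SoS dates).
#: The 2022-23 late window opens 5 December: the published narrative says
#: "5th November" but that date is inside the stated major window and is
#: not an acquisition date; the acquisition list and totals fix it.
SEASON_BINS: dict[str, SeasonBins] = {
    "2017-18": SeasonBins(
        early=(_D(2017, 8, 21), _D(2017, 9, 14)),
        major=(_D(2017, 9, 26), _D(2017, 11, 13)),
        late=(_D(2017, 11, 25), _D(2018, 1, 12)),
    ),
    "2018-19": SeasonBins(
        early=(_D(2018, 8, 16), _D(2018, 8, 28)),
        major=(_D(2018, 9, 9), _D(2018, 11, 8)),
        late=(_D(2018, 11, 20), _D(2018, 12, 14)),
    ),
    "2019-20": SeasonBins(
        early=(_D(2019, 8, 23), _D(2019, 9, 16)),
        major=(_D(2019, 9, 28), _D(2019, 11, 15)),
        late=(_D(2019, 11, 27), _D(2020, 1, 2)),
    ),
    "2020-21": SeasonBins(
        early=(_D(2020, 8, 5), _D(2020, 9, 10)),
        major=(_D(2020, 9, 22), _D(2020, 11, 9)),
        late=(_D(2020, 11, 21), _D(2020, 12, 15)),
    ),
    "2021-22": SeasonBins(
        early=(_D(2021, 8, 12), _D(2021, 9, 17)),
        major=(_D(2021, 9, 29), _D(2021, 11, 4)),
        late=(_D(2021, 11, 16), _D(2021, 11, 28)),
    ),
    "2022-23": SeasonBins(
        early=(_D(2022, 8, 19), _D(2022, 9, 12)),
        major=(_D(2022, 9, 24), _D(2022, 11, 23)),
        late=(_D(2022, 12, 5), _D(2022, 12, 17)),
    ),
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("ricesar").joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh)


def load_rice_area(year: str | None = None) -> pd.DataFrame:
    """District-wise rice area (ha); tidy columns year, district, area_ha."""
    df = _read("cauvery_delta_rice_area.csv")
    if year is not None:
        _check_year(year)
        df = df[df["year"] == year].reset_index(drop=True)
    return df


def load_sos_area(year: str, include_totals: bool = False) -> pd.DataFrame:
    """District x SoS-date rice area (ha) for one season, wide layout.

    Rows are districts (plus the published 'Total' row when requested),
    columns ISO SoS dates.
    """
    _check_year(year)
    df = _read("cauvery_delta_sos_area.csv")
    df = df[df["year"] == year]
    if not include_totals:
        df = df[df["district"] != "Total"]
    wide = df.pivot(index="district", columns="sos_date", values="area_ha")
    order = [d for d in (*DISTRICTS, "Total") if d in wide.index]
    return wide.loc[order, sorted(wide.columns)]


def sos_totals_by_date(year: str) -> dict[dt.date, float]:
    """Published per-SoS-date zone totals (ha), keyed by date."""
    _check_year(year)
    df = _read("cauvery_delta_sos_area.csv")
    sel = df[(df["year"] == year) & (df["district"] == "Total")]
    return {
        dt.date.fromisoformat(r.sos_date): float(r.area_ha)
        for r in sel.itertuples()
    }


def _check_year(year: str) -> None:
    if year not in YEARS:
        raise KeyError(f"unknown season {year!r}; available: {', '.join(YEARS)}")
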