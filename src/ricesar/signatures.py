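"""Derivation of rice-detection rule parameters from training signatures.

dB curves extracted at monitored rice fields are summarised into the
threshold set the classifier consumes: the envelope of temporal means
(lowest mean ``a``, highest mean ``b``), of seasonal variation (minimum
``f``, maximum ``c``), the flooding threshold (maximum value at SoS ``d``),
the minimum flowering-peak value ``e``, the admissible SoS window, the
growth-phase duration bounds and the maximum time a pixel may stay below
the flooding threshold.  An explicit min/max-envelope +/- margin policy is
used throughout: it is reproducible, and widening the margin relaxes every
bound monotonically.

All statistics are computed on the dB signatures directly, matching how the
thresholds are quoted and used.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stack import AcquisitionCalendar

__all__ = [
    "RuleParameters",
    "TrainingSignatureSet",
    "extract_field_signatures",
    "extract_rule_parameters",
]

#: Season-length bounds (days) used when the stack does not span the full
#: season, from the regional samba crop calendar.
DEFAULT_SEASON_LENGTH_DAYS = (90, 160)


@dataclass(frozen=True)
class RuleParameters:
    """Thresholds of the rule-based rice classifier.

    All dB values refer to the VH temporal signature of a pixel.  The growth
    bounds constrain the days from the flooding minimum to the post-minimum
    peak; the season-length bounds describe the full crop duration and are
    kept for post-hoc filtering when a stack spans the whole season.
    """

    a_lowest_mean_db: float
    b_highest_mean_db: float
    c_max_variation_db: float
    d_max_value_at_sos_db: float
    e_min_value_at_peak_db: float
    f_min_variation_db: float
    t_underwater_max_days: int
    sos_window: tuple[dt.date, dt.date]
    t_min_growth_days: int
    t_max_growth_days: int
    t_last: dt.date
    t_minlength_days: int = DEFAULT_SEASON_LENGTH_DAYS[0]
    t_maxlength_days: int = DEFAULT_SEASON_LENGTH_DAYS[1]

    def __post_init__(self) -> None:
        if self.a_lowest_mean_db > self.b_highest_mean_db:
            raise ValueError("lowest mean a must not exceed highest mean b")
        if self.f_min_variation_db > self.c_max_variation_db:
            raise ValueError("minimum variation f must not exceed maximum variation c")
        if self.d_max_value_at_sos_db >= self.e_min_value_at_peak_db:
            raise ValueError("flooding threshold d must lie below peak threshold e")
        if self.sos_window[0] > self.sos_window[1]:
            raise ValueError("sos_window must be ordered")
        if self.t_min_growth_days > self.t_max_growth_days:
            raise ValueError("growth-duration bounds must be ordered")
        if self.t_minlength_days > self.t_maxlength_days:
            raise ValueError("season-length bounds must be ordered")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sos_window"] = [self.sos_window[0].isoformat(), self.sos_window[1].isoformat()]
        d["t_last"] = self.t_last.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RuleParameters":
        d = dict(d)
        w0, w1 = d["sos_window"]
        d["sos_window"] = (dt.date.fromisoformat(w0), dt.date.fromisoformat(w1))
        d["t_last"] = dt.date.fromisoformat(d["t_last"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TrainingSignatureSet:
    """dB signatures of monitored rice fields on a common calendar."""

    ids: list
    values_db: np.ndarray  # (n_signatures, T); NaN marks missing readings
    calendar: AcquisitionCalendar

    def __post_init__(self) -> None:
        self.values_db = np.atleast_2d(np.asarray(self.values_db, dtype=np.float64))
        if self.values_db.shape[1] != len(self.calendar):
            raise ValueError("signature length must match the calendar")
        if len(self.ids) != self.values_db.shape[0]:
            raise ValueError("one id per signature required")

    def __len__(self) -> int:
        return self.values_db.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values_db, columns=self.calendar.isoformat())
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, cadence_days: int = 12) -> "TrainingSignatureSet":
        df = pd.read_csv(path)
        calendar = AcquisitionCalendar.from_isoformat(list(df.columns[1:]), cadence_days)
        return cls(df["id"].tolist(), df.iloc[:, 1:].to_numpy(dtype=np.float64), calendar)


def extract_field_signatures(
    stack,
    points: pd.DataFrame,
    window_px: int = 3,
) -> TrainingSignatureSet:
    """Monitoring-field dB curves at surveyed training locations.

    A monitoring field spans many 10 m pixels, so its temporal signature is
    the linear-power mean of a ``window_px`` square around the GPS point
    (clipped at scene edges), converted back to dB.  Field averaging also
    suppresses residual speckle and isolated atmospheric cells that survive
    stack preprocessing, which single-pixel curves would propagate into the
    threshold envelope.
    """
    if window_px < 1 or window_px % 2 == 0:
        raise ValueError("window_px must be an odd integer >= 1")
    half = window_px // 2
    t, h, w = stack.values_db.shape
    lin = np.power(10.0, stack.values_db / 10.0)
    lin = np.where(stack.valid_mask, lin, np.nan)
    sigs = np.empty((len(points), t), dtype=np.float64)
    rows = np.floor(points["y"].to_numpy(dtype=np.float64)).astype(int)
    cols = np.floor(points["x"].to_numpy(dtype=np.float64)).astype(int)
    for k, (r, c) in enumerate(zip(rows, cols)):
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"training point {points.index[k]} outside the scene")
        block = lin[:, max(0, r - half) : r + half + 1, max(0, c - half) : c + half + 1]
        with np.errstate(invalid="ignore"):
            m = np.nanmean(block.reshape(t, -1), axis=1)
        sigs[k] = np.where(m > 0, 10.0 * np.log10(np.where(m > 0, m, 1.0)), np.nan)
    return TrainingSignatureSet(points.index.tolist(), sigs, stack.calendar)


def _signature_stats(series: np.ndarray, calendar: AcquisitionCalendar) -> dict:
    """Per-signature summary; argmin/argmax ties resolved to the earliest date."""
    valid = np.isfinite(series)
    idx = np.nonzero(valid)[0]
    vals = series[idx]
    offs = calendar.day_offsets[idx]
    i_min = int(np.argmin(vals))
    post = np.nonzero(np.arange(len(vals)) > i_min)[0]
    if post.size:
        i_peak = int(post[np.argmax(vals[post])])
        peak_db = float(vals[i_peak])
        growth_days = int(offs[i_peak] - offs[i_min])
    else:
        i_peak, peak_db, growth_days = None, None, None
    return {
        "mean_db": float(vals.mean()),
        "min_db": float(vals.min()),
        "max_db": float(vals.max()),
        "variation_db": float(vals.max() - vals.min()),
        "argmin_date": calendar.dates[int(idx[i_min])],
        "argmin_offset": int(offs[i_min]),
        "peak_db": peak_db,
        "growth_days": growth_days,
        "_valid_vals": vals,
        "_valid_offs": offs,
        "_i_min": i_min,
    }


def _run_below_days(stats: dict, threshold_db: float) -> int:
    """Day span of the consecutive below-threshold run starting at the minimum."""
    vals, offs, i_min = stats["_valid_vals"], stats["_valid_offs"], stats["_i_min"]
    last = i_min
    for j in range(i_min + 1, len(vals)):
        if vals[j] > threshold_db:
            break
        last = j
    return int(offs[last] - offs[i_min])


def extract_rule_parameters(
    training: TrainingSignatureSet,
    margin_db: float = 0.5,
) -> RuleParameters:
    """Summarise training-field signatures into classifier thresholds.

    The envelope over signatures of each statistic is widened by
    ``margin_db`` (time bounds by one cadence step), so every training
    signature itself satisfies the extracted parameters and widening the
    margin never reclassifies a rice pixel as non-rice.

    The margins applied to the flooding threshold ``d`` and the peak
    threshold ``e`` are capped so that ``d`` stays strictly below ``e``:
    their raw envelopes can sit less than ``2 * margin_db`` apart (worst
    flooding minima around -17.7 dB vs worst flowering peaks around
    -16.1 dB), and unlike the mean bounds these two need little widening —
    observation noise biases a pixel's minimum down and its peak up, which
    relaxes both tests by itself.
    """
    if len(training) < 3:
        raise ValueError("insufficient training fields (need at least 3 signatures)")
    if margin_db < 0:
        raise ValueError("margin_db must be non-negative")

    cal = training.calendar
    stats = [_signature_stats(s, cal) for s in training.values_db]
    if any(not np.isfinite(s["mean_db"]) for s in stats):
        raise ValueError("training signatures must contain valid readings")
    if any(s["peak_db"] is None for s in stats):
        raise ValueError("every training signature needs a post-minimum peak")

    means = np.array([s["mean_db"] for s in stats])
    variations = np.array([s["variation_db"] for s in stats])
    mins = np.array([s["min_db"] for s in stats])
    peaks = np.array([s["peak_db"] for s in stats])
    growth = np.array([s["growth_days"] for s in stats])
    argmin_dates = [s["argmin_date"] for s in stats]

    d_raw, e_raw = float(mins.max()), float(peaks.min())
    if d_raw >= e_raw:
        raise ValueError(
            "training envelope inconsistent: highest flooding minimum "
            f"({d_raw:.2f} dB) reaches the lowest peak ({e_raw:.2f} dB)"
        )
    margin_de = min(margin_db, 0.45 * (e_raw - d_raw))
    d = d_raw + margin_de
    cadence = cal.cadence_days
    underwater = max(_run_below_days(s, d) for s in stats) + cadence

    return RuleParameters(
        a_lowest_mean_db=float(means.min() - margin_db),
        b_highest_mean_db=float(means.max() + margin_db),
        c_max_variation_db=float(variations.max() + margin_db),
        f_min_variation_db=float(max(0.0, variations.min() - margin_db)),
        d_max_value_at_sos_db=d,
        e_min_value_at_peak_db=float(e_raw - margin_de),
        sos_window=(
            min(argmin_dates) - dt.timedelta(days=cadence),
            max(argmin_dates) + dt.timedelta(days=cadence),
        ),
        t_min_growth_days=int(max(0, growth.min() - cadence)),
        t_max_growth_days=int(growth.max() + cadence),
        t_underwater_max_days=int(underwater),
        t_last=cal.end,
    )
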