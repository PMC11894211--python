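"""Per-pixel rule-based rice detection from multi-temporal VH signatures.

A pixel is rice when its dB signature satisfies ALL of:

* R1 — temporal mean within the training envelope [a, b];
* R2 — seasonal variation (max - min) within [f, c];
* R3 — minimum at or below the flooding threshold d, dated inside the
  admissible SoS window (the minimum IS the start of season);
* R4 — a post-minimum peak at or above e (tillering-flowering rise);
* R5 — growth-phase duration (minimum to post-minimum peak) within bounds;
* R6 — the consecutive below-d run starting at the minimum no longer than
  the maximum time underwater;
* R7 — the peak observed no later than the last acquisition.

Each threshold is a bound, so the conjunction is the only combination under
which every parameter stays meaningful.  Argmin/argmax ties are broken to
the earliest date (SoS is an onset event).  Pixels with fewer than
``min_valid`` usable acquisitions are flagged unclassifiable: they enter
neither the rice map nor area sums and are counted separately.

:func:`classify_pixel` is the scalar reference implementation;
:func:`classify_stack` is an independent vectorised version of the same
decision applied to a whole stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signatures import RuleParameters
from .stack import AcquisitionCalendar, SOS_SENTINEL, SigmaStack

__all__ = ["RULE_IDS", "RiceDecision", "RiceMap", "classify_pixel", "classify_stack"]

RULE_IDS = ("R1", "R2", "R3", "R4", "R5", "R6", "R7")

RULE_DESCRIPTIONS = {
    "R1": "temporal mean within [a, b]",
    "R2": "seasonal variation within [f, c]",
    "R3": "minimum <= d and dated inside the SoS window",
    "R4": "post-minimum peak >= e",
    "R5": "growth-phase duration within bounds",
    "R6": "below-d run from the minimum <= max time underwater",
    "R7": "peak no later than the last acquisition",
}

#: Raster codes of the rice map.
RICE, NONRICE, UNCLASSIFIABLE = 1, 0, 255


@dataclass(frozen=True)
class RiceDecision:
    """Outcome of the rule conjunction for one pixel."""

    is_rice: bool
    sos_index: int | None
    peak_index: int | None
    fail_reasons: frozenset
    unclassifiable: bool = False

    def __post_init__(self) -> None:
        if self.is_rice and self.fail_reasons:
            raise ValueError("a rice decision cannot carry fail reasons")
        if self.is_rice and not (self.sos_index < self.peak_index):
            raise ValueError("rice requires the minimum to precede the peak")


def classify_pixel(
    series_db: np.ndarray,
    calendar: AcquisitionCalendar,
    params: RuleParameters,
    valid_mask: np.ndarray | None = None,
    min_valid: int = 10,
) -> RiceDecision:
    """Classify one temporal signature.  NaNs (or masked dates) are ignored."""
    series_db = np.asarray(series_db, dtype=np.float64)
    if series_db.shape[0] != len(calendar):
        raise ValueError("series length must match the calendar")
    valid = np.isfinite(series_db)
    if valid_mask is not None:
        valid &= np.asarray(valid_mask, dtype=bool)
    if int(valid.sum()) < min_valid:
        return RiceDecision(False, None, None, frozenset(), unclassifiable=True)

    offs = calendar.day_offsets
    t_idx = np.nonzero(valid)[0]
    vals = series_db[t_idx]

    mean = vals.mean()
    mn, mx = vals.min(), vals.max()
    argmin = int(t_idx[np.argmin(vals)])  # first occurrence = earliest date
    argmin_date = calendar.dates[argmin]

    fails = set()
    if not params.a_lowest_mean_db <= mean <= params.b_highest_mean_db:
        fails.add("R1")
    if not params.f_min_variation_db <= mx - mn <= params.c_max_variation_db:
        fails.add("R2")
    w0, w1 = params.sos_window
    if not (mn <= params.d_max_value_at_sos_db and w0 <= argmin_date <= w1):
        fails.add("R3")

    post = t_idx[t_idx > argmin]
    if post.size == 0:
        fails.update({"R4", "R5"})
        peak_idx = None
    else:
        post_vals = series_db[post]
        peak_idx = int(post[np.argmax(post_vals)])
        if post_vals.max() < params.e_min_value_at_peak_db:
            fails.add("R4")
        growth_days = int(offs[peak_idx] - offs[argmin])
        if not params.t_min_growth_days <= growth_days <= params.t_max_growth_days:
            fails.add("R5")
        if calendar.dates[peak_idx] > params.t_last:
            fails.add("R7")

    d = params.d_max_value_at_sos_db
    run_days = 0
    if series_db[argmin] <= d:
        last = argmin
        for t in post:
            if series_db[t] > d:
                break
            last = int(t)
        run_days = int(offs[last] - offs[argmin])
    if run_days > params.t_underwater_max_days:
        fails.add("R6")

    is_rice = not fails
    return RiceDecision(
        is_rice=is_rice,
        sos_index=argmin if is_rice else None,
        peak_index=peak_idx if is_rice else None,
        fail_reasons=frozenset(fails),
    )


@dataclass
class RiceMap:
    """Per-pixel rice decision rasters for a classified stack."""

    rice: np.ndarray  # uint8: 1 rice, 0 non-rice, 255 unclassifiable
    sos_index: np.ndarray  # int16 acquisition index, -1 outside rice
    peak_index: np.ndarray  # int16 acquisition index, -1 outside rice
    calendar: AcquisitionCalendar
    pixel_spacing_m: tuple[float, float] = (10.0, 10.0)
    fail_counts: dict = field(default_factory=dict)

    @property
    def rice_mask(self) -> np.ndarray:
        return self.rice == RICE

    @property
    def n_unclassifiable(self) -> int:
        return int((self.rice == UNCLASSIFIABLE).sum())


def classify_stack(
    stack: SigmaStack,
    params: RuleParameters,
    min_valid: int = 10,
) -> RiceMap:
    """Vectorised rule classification; pixelwise identical to
    :func:`classify_pixel` applied independently."""
    t, h, w = stack.values_db.shape
    n = h * w
    v = stack.values_db.reshape(t, n)
    valid = (stack.valid_mask & np.isfinite(stack.values_db)).reshape(t, n)
    x = np.where(valid, v, np.nan)

    nvalid = valid.sum(axis=0)
    unclass = nvalid < min_valid
    ok = ~unclass
    # Dummy value keeps nan-reductions defined for unclassifiable pixels;
    # their statistics are gated out of every rule below.
    x = _nanfill(x, unclass)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(x, axis=0)
        mn = np.nanmin(x, axis=0)
        mx = np.nanmax(x, axis=0)
        argmin = np.nanargmin(x, axis=0)

    offs = stack.calendar.day_offsets
    tgrid = np.arange(t)[:, None]

    w0, w1 = params.sos_window
    w0_off = stack.calendar.offset_of(w0)
    w1_off = stack.calendar.offset_of(w1)
    argmin_off = offs[argmin]

    r1 = (params.a_lowest_mean_db <= mean) & (mean <= params.b_highest_mean_db)
    r2 = (params.f_min_variation_db <= mx - mn) & (mx - mn <= params.c_max_variation_db)
    r3 = (mn <= params.d_max_value_at_sos_db) & (w0_off <= argmin_off) & (argmin_off <= w1_off)

    post = valid & (tgrid > argmin[None, :])
    has_post = post.any(axis=0)
    xpost = np.where(post, v, np.nan)
    xpost[0, ~has_post] = 0.0  # keep reductions defined; gated by has_post
    with np.errstate(invalid="ignore"):
        peak = np.nanmax(xpost, axis=0)
        peak_idx = np.nanargmax(xpost, axis=0)

    r4 = has_post & (peak >= params.e_min_value_at_peak_db)
    growth_days = offs[peak_idx] - argmin_off
    r5 = (
        has_post
        & (params.t_min_growth_days <= growth_days)
        & (growth_days <= params.t_max_growth_days)
    )
    t_last_off = stack.calendar.offset_of(params.t_last)
    r7 = ~has_post | (offs[peak_idx] <= t_last_off)

    # R6: day span of the consecutive below-d run starting at the minimum.
    d_thr = params.d_max_value_at_sos_db
    below = valid & (v <= d_thr)
    min_below = np.take_along_axis(below, argmin[None, :], axis=0)[0]
    breaks = valid & (v > d_thr) & (tgrid > argmin[None, :])
    any_break = breaks.any(axis=0)
    first_break = np.where(any_break, breaks.argmax(axis=0), t)
    in_run = below & (tgrid >= argmin[None, :]) & (tgrid < first_break[None, :])
    run_last = (t - 1) - in_run[::-1].argmax(axis=0)
    run_last = np.where(in_run.any(axis=0), run_last, argmin)
    run_days = np.where(min_below, offs[run_last] - argmin_off, 0)
    r6 = run_days <= params.t_underwater_max_days

    is_rice = ok & r1 & r2 & r3 & r4 & r5 & r6 & r7

    rice = np.full(n, NONRICE, dtype=np.uint8)
    rice[is_rice] = RICE
    rice[unclass] = UNCLASSIFIABLE
    sos = np.where(is_rice, argmin, SOS_SENTINEL).astype(np.int16)
    peak_r = np.where(is_rice, peak_idx, SOS_SENTINEL).astype(np.int16)

    fail_counts = {
        "R1": int((ok & ~r1).sum()),
        "R2": int((ok & ~r2).sum()),
        "R3": int((ok & ~r3).sum()),
        "R4": int((ok & ~r4).sum()),
        "R5": int((ok & ~r5).sum()),
        "R6": int((ok & ~r6).sum()),
        "R7": int((ok & ~r7).sum()),
        "unclassifiable": int(unclass.sum()),
    }
    return RiceMap(
        rice=rice.reshape(h, w),
        sos_index=sos.reshape(h, w),
        peak_index=peak_r.reshape(h, w),
        calendar=stack.calendar,
        pixel_spacing_m=stack.pixel_spacing_m,
        fail_counts=fail_counts,
    )


def _nanfill(x: np.ndarray, unclass: np.ndarray) -> np.ndarray:
    """Give unclassifiable pixels a dummy value so nan-reductions stay defined."""
    if not unclass.any():
        return x
    out = x.copy()
    out[0, unclass] = 0.0
    return out
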