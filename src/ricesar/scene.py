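"""Synthetic C-band VH backscatter scenes with known per-pixel truth.

The generator emulates what a 12-day C-band SAR revisit sees over a
rice-dominated delta during the main (samba) season:

* rice pixels follow the canonical dB curve — a pre-season level, a sharp
  minimum at agronomic flooding (the start of season, SoS), a monotone rise
  through tillering to a peak at flowering, then a slow decline;
* non-rice vegetation keeps a moderate level with seasonal variation smaller
  than any rice growth rise;
* permanent water stays low for the whole season; urban/bare stays high;
* multiplicative gamma speckle (configurable equivalent number of looks) and
  additive dB noise sit on top of every signature, and sporadic isolated
  single-acquisition spikes/troughs emulate atmospheric attenuation events.

The default dB envelope is the one observed for transplanted rice in VH
polarization: flooding minima in [-22.03, -17.69] dB, flowering peaks in
[-16.10, -14.20] dB and a seedling-to-flowering rise of 2.69-6.74 dB with a
mean of 5.07 dB.  The generator and the rule classifier deliberately share
this envelope so that noiseless scenes are classified perfectly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .stack import CLASS_CODES, SOS_SENTINEL, AcquisitionCalendar, SceneTruth, SigmaStack

__all__ = [
    "RicePriors",
    "NonRicePriors",
    "SignatureModel",
    "SceneConfig",
    "generate_calendar",
    "sample_rice_model",
    "simulate_rice_signature",
    "simulate_nonrice_signature",
    "build_scene",
    "add_atmospheric_anomalies",
]

#: Printed VH dB envelope for transplanted rice (flooding minima, flowering
#: peaks, seedling-to-flowering rise and its mean).
RICE_MIN_DB_RANGE = (-22.03, -17.69)
RICE_PEAK_DB_RANGE = (-16.10, -14.20)
RICE_RISE_DB_RANGE = (2.69, 6.74)
RICE_RISE_MEAN_DB = 5.07


def generate_calendar(
    start_date: dt.date,
    n_acq: int,
    cadence_days: int = 12,
    drop_prob: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> AcquisitionCalendar:
    """Nominal acquisition calendar with optional randomly missing passes.

    ``n_acq`` nominal slots are laid out every ``cadence_days`` from
    ``start_date``; interior slots are then dropped independently with
    probability ``drop_prob``.  The first and last passes are always kept so
    the season span is preserved.
    """
    if n_acq < 10:
        raise ValueError("insufficient temporal depth for rule classification (n_acq < 10)")
    if n_acq > 20:
        raise ValueError("n_acq must be <= 20")
    if not 0.0 <= drop_prob < 0.3:
        raise ValueError("drop_prob must be in [0, 0.3)")
    rng = np.random.default_rng(seed)
    keep = np.ones(n_acq, dtype=bool)
    if drop_prob > 0:
        keep[1:-1] = rng.random(n_acq - 2) >= drop_prob
    dates = tuple(
        start_date + dt.timedelta(days=int(i) * cadence_days)
        for i in np.nonzero(keep)[0]
    )
    if len(dates) < 10:
        raise ValueError("insufficient temporal depth for rule classification (after drops)")
    return AcquisitionCalendar(dates, cadence_days)


@dataclass(frozen=True)
class RicePriors:
    """Population the per-pixel rice signature parameters are drawn from.

    ``rise_db`` is drawn uniformly on a sub-interval of the observed
    2.69-6.74 dB range chosen symmetric about the observed 5.07 dB mean,
    and the flowering peak is then drawn uniformly on the sub-interval that
    keeps both the peak and the flooding minimum (peak - rise) inside their
    printed ranges.  Independent uniforms on the two printed ranges would
    centre the rise at 4.71 dB instead of the observed mean.
    """

    min_db_range: tuple[float, float] = RICE_MIN_DB_RANGE
    peak_db_range: tuple[float, float] = RICE_PEAK_DB_RANGE
    rise_db_range: tuple[float, float] = RICE_RISE_DB_RANGE
    rise_mean_db: float = RICE_RISE_MEAN_DB
    pre_season_db_range: tuple[float, float] = (-17.0, -15.5)
    rise_days_choices: tuple[int, ...] = (36, 48, 60)
    decline_rate_db_per_step: float = 0.5
    noise_sd_db: float = 0.3
    speckle_looks: float | None = 4.4

    def rise_sampling_range(self) -> tuple[float, float]:
        lo, hi = self.rise_db_range
        lo_sym = max(lo, 2.0 * self.rise_mean_db - hi)
        return lo_sym, hi


@dataclass(frozen=True)
class NonRicePriors:
    """Stand-in parameters for the negative classes.

    These levels are not observed quantities; they exist to exercise the
    classifier and are all configurable.
    """

    urban_db: float = -8.0
    water_db: float = -22.0
    veg_db_range: tuple[float, float] = (-15.5, -14.5)
    veg_amplitude_db_range: tuple[float, float] = (0.5, 1.0)
    veg_period_days: float = 180.0


@dataclass(frozen=True)
class SignatureModel:
    """Parameters of one rice pixel's noiseless dB curve plus its noise."""

    pre_season_db: float
    flood_min_db: float
    peak_db: float
    sos_date: dt.date
    rise_days: int
    decline_rate_db_per_step: float = 0.5
    noise_sd_db: float = 0.0
    speckle_looks: float | None = None

    def __post_init__(self) -> None:
        if not self.flood_min_db < self.peak_db:
            raise ValueError("flood_min_db must lie below peak_db")
        if self.rise_days <= 0:
            raise ValueError("rise_days must be positive")


def sample_rice_model(
    rng: np.random.Generator,
    sos_date: dt.date,
    priors: RicePriors = RicePriors(),
) -> SignatureModel:
    """Draw one rice signature model from the priors."""
    rise, peak, flood, pre, rise_days = _sample_rice_params(rng, 1, priors)
    return SignatureModel(
        pre_season_db=float(pre[0]),
        flood_min_db=float(flood[0]),
        peak_db=float(peak[0]),
        sos_date=sos_date,
        rise_days=int(rise_days[0]),
        decline_rate_db_per_step=priors.decline_rate_db_per_step,
        noise_sd_db=priors.noise_sd_db,
        speckle_looks=priors.speckle_looks,
    )


def _sample_rice_params(rng: np.random.Generator, n: int, priors: RicePriors):
    rlo, rhi = priors.rise_sampling_range()
    rise = rng.uniform(rlo, rhi, size=n)
    mlo, mhi = priors.min_db_range
    plo, phi = priors.peak_db_range
    peak_lo = np.maximum(plo, rise + mlo)
    peak_hi = np.minimum(phi, rise + mhi)
    if np.any(peak_lo > peak_hi):
        raise ValueError("rice priors leave no feasible flowering peak")
    peak = rng.uniform(peak_lo, peak_hi)
    flood = peak - rise
    pre = rng.uniform(*priors.pre_season_db_range, size=n)
    rise_days = rng.choice(np.asarray(priors.rise_days_choices), size=n)
    return rise, peak, flood, pre, rise_days


def _rice_backbone_db(
    days_from_sos: np.ndarray,
    pre: np.ndarray,
    flood: np.ndarray,
    peak: np.ndarray,
    rise_days: np.ndarray,
    decline_rate: float,
    cadence_days: int,
) -> np.ndarray:
    """Piecewise noiseless rice dB curve, broadcast over pixels x dates.

    Level before a one-cadence flooding dip, linear descent into the flooding
    minimum at day 0, linear rise to the peak after ``rise_days``, then a
    linear decline of ``decline_rate`` dB per nominal acquisition step that
    saturates at the pre-season baseline (ripening dries the canopy back
    towards its unflooded level; it does not undercut the flooding minimum).
    """
    d = np.asarray(days_from_sos, dtype=np.float64)
    pre = np.asarray(pre, dtype=np.float64)
    flood = np.asarray(flood, dtype=np.float64)
    peak = np.asarray(peak, dtype=np.float64)
    rise_days = np.asarray(rise_days, dtype=np.float64)
    dip = float(cadence_days)

    out = np.where(d <= -dip, pre, 0.0)
    on_dip = (d > -dip) & (d < 0)
    out = np.where(on_dip, pre + (flood - pre) * (1.0 + d / dip), out)
    on_rise = (d >= 0) & (d <= rise_days)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(on_rise, flood + (peak - flood) * d / rise_days, out)
    after = d > rise_days
    floor = np.minimum(pre, peak)
    declined = np.maximum(peak - decline_rate * (d - rise_days) / dip, floor)
    out = np.where(after, declined, out)
    return out


def simulate_rice_signature(
    model: SignatureModel,
    calendar: AcquisitionCalendar,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one rice pixel's dB series on the given calendar.

    The flooding date is snapped to the nearest acquisition so that the
    argmin of the noiseless backbone is exactly the acquisition closest to
    ``model.sos_date``.  Additive Gaussian dB noise and multiplicative gamma
    speckle (``speckle_looks`` equivalent looks, applied in linear power)
    are layered on the backbone.
    """
    first, last = calendar.start, calendar.end
    latest = last - dt.timedelta(days=int(model.rise_days))
    if not first <= model.sos_date <= latest:
        raise ValueError(
            f"sos_date {model.sos_date} outside calendar span "
            f"[{first}, {last}] minus rise_days={model.rise_days}"
        )
    sos_idx = calendar.nearest_index(model.sos_date)
    offs = calendar.day_offsets - calendar.day_offsets[sos_idx]
    backbone = _rice_backbone_db(
        offs,
        model.pre_season_db,
        model.flood_min_db,
        model.peak_db,
        model.rise_days,
        model.decline_rate_db_per_step,
        calendar.cadence_days,
    )
    rng = np.random.default_rng(seed)
    return _apply_noise(backbone, model.noise_sd_db, model.speckle_looks, rng)


def simulate_nonrice_signature(
    kind: str,
    calendar: AcquisitionCalendar,
    seed: int | np.random.Generator | None = None,
    noise_sd_db: float = 0.0,
    speckle_looks: float | None = None,
    priors: NonRicePriors = NonRicePriors(),
) -> np.ndarray:
    """Simulate a non-rice temporal signature.

    ``urban`` is a high constant, ``water`` a low constant for the whole
    season, and ``nonrice_veg`` a moderate level with a slow seasonal
    oscillation whose total range stays below the smallest rice rise.
    """
    rng = np.random.default_rng(seed)
    offs = calendar.day_offsets.astype(np.float64)
    if kind == "urban":
        backbone = np.full(len(calendar), priors.urban_db)
    elif kind == "water":
        backbone = np.full(len(calendar), priors.water_db)
    elif kind == "nonrice_veg":
        level = rng.uniform(*priors.veg_db_range)
        amp = rng.uniform(*priors.veg_amplitude_db_range)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        backbone = level + amp * np.sin(2.0 * np.pi * offs / priors.veg_period_days + phase)
    else:
        raise ValueError(f"unknown non-rice class {kind!r}")
    return _apply_noise(backbone, noise_sd_db, speckle_looks, rng)


def _apply_noise(
    backbone_db: np.ndarray,
    noise_sd_db: float,
    speckle_looks: float | None,
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.asarray(backbone_db, dtype=np.float64)
    if noise_sd_db > 0:
        out = out + rng.normal(0.0, noise_sd_db, size=out.shape)
    if speckle_looks is not None and np.isfinite(speckle_looks):
        looks = float(speckle_looks)
        if looks <= 0:
            raise ValueError("speckle_looks must be positive")
        mult = rng.gamma(shape=looks, scale=1.0 / looks, size=out.shape)
        out = out + 10.0 * np.log10(mult)
    return out


@dataclass(frozen=True)
class SceneConfig:
    """Everything needed to synthesise one scene.

    Class fractions must sum to one; they are realised exactly (quantile
    thresholding of a smooth random field), which also gives spatially
    contiguous land-cover patches — the situation the multi-temporal filter
    is designed for.  The SoS window is quantised to acquisition dates and
    chosen so the flowering peak is observed before the last acquisition.
    """

    grid_shape: tuple[int, int] = (100, 100)
    class_fractions: dict = field(
        default_factory=lambda: {"rice": 0.6, "nonrice_veg": 0.2, "water": 0.1, "urban": 0.1}
    )
    start_date: dt.date = dt.date(2017, 8, 9)
    n_acquisitions: int = 14
    cadence_days: int = 12
    drop_prob: float = 0.0
    sos_start: dt.date = dt.date(2017, 9, 14)
    sos_end: dt.date = dt.date(2017, 11, 1)
    sos_weights: tuple[float, ...] | None = None
    class_blob_px: float = 12.0
    sos_blob_px: float = 16.0
    # Correlation length of the crop-parameter fields: flooding depth, peak
    # level and growth duration vary by field (variety, management), not by
    # 10 m pixel, so neighbouring rice pixels share similar curve parameters
    # while speckle stays independent per pixel.
    param_blob_px: float = 6.0
    n_districts: int = 5
    noise_sd_db: float = 0.3
    speckle_looks: float | None = 4.4
    rice_priors: RicePriors = field(default_factory=RicePriors)
    nonrice_priors: NonRicePriors = field(default_factory=NonRicePriors)
    pixel_spacing_m: tuple[float, float] = (10.0, 10.0)

    def __post_init__(self) -> None:
        total = float(sum(self.class_fractions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1 (got {total})")
        unknown = set(self.class_fractions) - set(CLASS_CODES)
        if unknown:
            raise ValueError(f"unknown classes in fractions: {sorted(unknown)}")
        if self.sos_start > self.sos_end:
            raise ValueError("sos_start must not be after sos_end")

    def noiseless(self) -> "SceneConfig":
        """Copy of this config with all noise sources switched off."""
        priors = replace(self.rice_priors, noise_sd_db=0.0, speckle_looks=None)
        return replace(self, noise_sd_db=0.0, speckle_looks=None, rice_priors=priors)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    field_ = rng.standard_normal(shape)
    if sigma_px > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=sigma_px, mode="wrap")
    # Infinitesimal jitter breaks rank ties so quantile splits are exact.
    field_ = field_ + rng.uniform(0.0, 1e-9, size=shape)
    return field_


def _uniform_field(
    rng: np.random.Generator, shape: tuple[int, int], sigma_px: float
) -> np.ndarray:
    """Spatially correlated field with exactly uniform (0, 1) marginals."""
    f = _smooth_field(rng, shape, sigma_px).ravel()
    ranks = np.empty(f.size, dtype=np.int64)
    ranks[np.argsort(f, kind="stable")] = np.arange(f.size)
    return ((ranks + 0.5) / f.size).reshape(shape)


def _quantile_classes(field_: np.ndarray, counts: list[int]) -> np.ndarray:
    """Assign class slots by rank of a smooth field; counts are exact."""
    order = np.argsort(field_.ravel(), kind="stable")
    labels = np.empty(field_.size, dtype=np.int64)
    start = 0
    for k, c in enumerate(counts):
        labels[order[start : start + c]] = k
        start += c
    return labels.reshape(field_.shape)


def build_scene(
    config: SceneConfig, seed: int | np.random.Generator | None = None
) -> tuple[SigmaStack, SceneTruth]:
    """Synthesise a backscatter stack and its pixel-level truth."""
    rng = np.random.default_rng(seed)
    calendar = generate_calendar(
        config.start_date,
        config.n_acquisitions,
        config.cadence_days,
        config.drop_prob,
        rng,
    )
    h, w = config.grid_shape
    n_px = h * w

    # --- land cover: ranked smooth field -> exact class counts -------------
    class_order = [c for c in CLASS_CODES if c in config.class_fractions]
    fracs = np.array([config.class_fractions[c] for c in class_order])
    bounds = np.round(np.cumsum(fracs) * n_px).astype(int)
    counts = np.diff(np.concatenate([[0], bounds])).tolist()
    label_idx = _quantile_classes(_smooth_field(rng, (h, w), config.class_blob_px), counts)
    class_raster = np.zeros((h, w), dtype=np.uint8)
    for k, cname in enumerate(class_order):
        class_raster[label_idx == k] = CLASS_CODES[cname]

    # --- districts: vertical strips ----------------------------------------
    cols = np.arange(w)
    district_raster = np.broadcast_to(
        (cols * config.n_districts // w + 1).astype(np.int16), (h, w)
    ).copy()

    # --- start of season: smooth field quantile-mapped onto the window -----
    sos_candidates = [
        i
        for i, d in enumerate(calendar.dates)
        if config.sos_start <= d <= config.sos_end
    ]
    if not sos_candidates:
        raise ValueError("no acquisitions fall inside the SoS window")
    if config.sos_weights is not None:
        weights = np.asarray(config.sos_weights, dtype=np.float64)
        if len(weights) != len(sos_candidates):
            raise ValueError(
                f"sos_weights needs {len(sos_candidates)} entries "
                f"(acquisitions inside the SoS window)"
            )
    else:
        weights = np.ones(len(sos_candidates))
    weights = weights / weights.sum()

    rice_mask = class_raster == CLASS_CODES["rice"]
    n_rice = int(rice_mask.sum())
    sos_raster = np.full((h, w), SOS_SENTINEL, dtype=np.int16)
    if n_rice:
        sos_field = _smooth_field(rng, (h, w), config.sos_blob_px)[rice_mask]
        ranks = np.empty(n_rice, dtype=np.int64)
        ranks[np.argsort(sos_field, kind="stable")] = np.arange(n_rice)
        cum = np.round(np.cumsum(weights) * n_rice).astype(int)
        sos_per_rank = np.empty(n_rice, dtype=np.int16)
        start = 0
        for cand, stop in zip(sos_candidates, cum):
            sos_per_rank[start:stop] = cand
            start = stop
        sos_raster[rice_mask] = sos_per_rank[ranks]

    # --- signatures ---------------------------------------------------------
    values = np.empty((len(calendar), h, w), dtype=np.float64)
    day_offs = calendar.day_offsets.astype(np.float64)

    if n_rice:
        pr = config.rice_priors
        rlo, rhi = pr.rise_sampling_range()
        u_rise = _uniform_field(rng, (h, w), config.param_blob_px)[rice_mask]
        u_peak = _uniform_field(rng, (h, w), config.param_blob_px)[rice_mask]
        u_pre = _uniform_field(rng, (h, w), config.param_blob_px)[rice_mask]
        u_rd = _uniform_field(rng, (h, w), config.param_blob_px)[rice_mask]
        rise = rlo + (rhi - rlo) * u_rise
        mlo, mhi = pr.min_db_range
        plo, phi = pr.peak_db_range
        peak_lo = np.maximum(plo, rise + mlo)
        peak_hi = np.minimum(phi, rise + mhi)
        peak = peak_lo + (peak_hi - peak_lo) * u_peak
        flood = peak - rise
        pre = pr.pre_season_db_range[0] + np.diff(pr.pre_season_db_range)[0] * u_pre
        choices = np.asarray(pr.rise_days_choices)
        rise_days = choices[np.minimum((u_rd * len(choices)).astype(int), len(choices) - 1)]
        sos_days = day_offs[sos_raster[rice_mask]]
        rel = day_offs[None, :] - sos_days[:, None]  # (n_rice, T)
        backbone = _rice_backbone_db(
            rel,
            pre[:, None],
            flood[:, None],
            peak[:, None],
            rise_days[:, None],
            config.rice_priors.decline_rate_db_per_step,
            calendar.cadence_days,
        )
        values[:, rice_mask] = backbone.T

    veg_mask = class_raster == CLASS_CODES["nonrice_veg"]
    n_veg = int(veg_mask.sum())
    if n_veg:
        pr = config.nonrice_priors
        level = rng.uniform(*pr.veg_db_range, size=n_veg)
        amp = rng.uniform(*pr.veg_amplitude_db_range, size=n_veg)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=n_veg)
        veg = level[:, None] + amp[:, None] * np.sin(
            2.0 * np.pi * day_offs[None, :] / pr.veg_period_days + phase[:, None]
        )
        values[:, veg_mask] = veg.T

    values[:, class_raster == CLASS_CODES["water"]] = config.nonrice_priors.water_db
    values[:, class_raster == CLASS_CODES["urban"]] = config.nonrice_priors.urban_db

    values = _apply_noise(values, config.noise_sd_db, config.speckle_looks, rng)

    stack = SigmaStack(
        values_db=values,
        calendar=calendar,
        pixel_spacing_m=config.pixel_spacing_m,
    )
    truth = SceneTruth(
        class_raster=class_raster,
        sos_raster=sos_raster,
        district_raster=district_raster,
        pixel_spacing_m=config.pixel_spacing_m,
    )
    return stack, truth


def add_atmospheric_anomalies(
    stack: SigmaStack,
    rate: float = 0.05,
    magnitude_db: float = 4.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[SigmaStack, np.ndarray]:
    """Perturb isolated interior (pixel, date) cells by +/- ``magnitude_db``.

    Each interior-date cell is flagged independently with probability
    ``rate``; flags adjacent in time at the same pixel are thinned (earlier
    one kept) so every anomaly is an isolated single-acquisition spike or
    trough, as the interpolator expects.  Returns the perturbed stack and
    the boolean anomaly mask for oracle testing.
    """
    if not 0.0 <= rate <= 0.2:
        raise ValueError("rate must be in [0, 0.2]")
    if magnitude_db <= 0:
        raise ValueError("magnitude_db must be positive")
    rng = np.random.default_rng(seed)
    t = stack.n_dates
    mask = np.zeros(stack.values_db.shape, dtype=bool)
    if rate > 0 and t >= 3:
        cand = rng.random(stack.values_db.shape) < rate
        cand[0] = cand[-1] = False
        cand &= stack.valid_mask
        for ti in range(1, t - 1):
            cand[ti] &= ~cand[ti - 1]
        mask = cand
    sign = np.where(rng.random(stack.values_db.shape) < 0.5, -1.0, 1.0)
    values = stack.values_db + np.where(mask, sign * magnitude_db, 0.0)
    return stack.with_values(values), mask
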