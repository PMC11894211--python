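"""Temporal-signal conditioning for sigma-naught stacks.

Two preprocessing steps are applied to a backscatter stack before rule-based
classification:

* a mean-preserving multi-temporal speckle filter that borrows spatial
  averaging at each date while keeping every pixel's temporal mean (in linear
  power) untouched, and
* an interpolator that repairs isolated single-acquisition spikes and troughs
  caused by heavy atmospheric water vapour or rainfall during a pass.

Averaging for speckle filtering is done in linear power, because intensity
adds linearly; the anomaly interpolator operates on the dB signature, where
attenuation anomalies and the detection threshold are naturally expressed.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .stack import SigmaStack

__all__ = [
    "db_to_linear",
    "linear_to_db",
    "temporal_speckle_filter",
    "interpolate_anomalies",
]


def db_to_linear(x_db):
    """Convert sigma-naught from dB to linear power."""
    return np.power(10.0, np.asarray(x_db, dtype=np.float64) / 10.0)


def linear_to_db(x):
    """Convert linear power to dB. Raises on non-positive input."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x <= 0):
        raise ValueError("linear power must be positive to convert to dB")
    return 10.0 * np.log10(x)


def temporal_speckle_filter(stack: SigmaStack, window_px: int = 5) -> SigmaStack:
    """Multi-temporal speckle filter with per-pixel mean preservation.

    For each date the local spatial mean (``window_px`` square, linear power)
    is computed, and each pixel's output is that spatial mean rescaled by the
    ratio of the pixel's temporal mean to the spatial mean's temporal mean:

        out[t, p] = S_t(p) * m(p) / m_S(p)

    so the temporal mean of every pixel is preserved exactly in linear power
    while spatial speckle variance at each date is strongly reduced on
    homogeneous regions.  Nodata cells stay nodata and are excluded from all
    averages.
    """
    if window_px < 1 or window_px % 2 == 0:
        raise ValueError("window_px must be an odd integer >= 1")
    h, w = stack.grid_shape
    if window_px > min(h, w):
        raise ValueError(f"window of {window_px} px exceeds the {h}x{w} grid")

    valid = stack.valid_mask
    lin = db_to_linear(stack.values_db)
    lin = np.where(valid, lin, 0.0)

    # Local spatial mean over valid neighbours, one date at a time.
    size = (1, window_px, window_px)
    num = ndimage.uniform_filter(lin, size=size, mode="nearest")
    den = ndimage.uniform_filter(valid.astype(np.float64), size=size, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        spatial_mean = np.where(den > 0, num / den, 0.0)

    # Temporal means over each pixel's own valid dates, for the pixel and
    # for its spatial-mean series alike, so the ratio cancels exactly.
    nvalid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m_pixel = np.where(nvalid > 0, lin.sum(axis=0) / nvalid, 0.0)
        m_spatial = np.where(
            nvalid > 0, np.where(valid, spatial_mean, 0.0).sum(axis=0) / nvalid, 0.0
        )
        ratio = np.where(m_spatial > 0, m_pixel / m_spatial, 1.0)

    out_lin = spatial_mean * ratio[None, :, :]
    # Degenerate pixels (no positive neighbourhood power) keep their input.
    degenerate = (out_lin <= 0) & valid
    out_lin = np.where(degenerate, db_to_linear(stack.values_db), out_lin)

    out_db = np.where(valid, 10.0 * np.log10(np.where(out_lin > 0, out_lin, 1.0)), 0.0)
    out_db = np.where(valid, out_db, stack.values_db)
    return stack.with_values(out_db)


def interpolate_anomalies(stack: SigmaStack, spike_threshold_db: float = 3.0) -> SigmaStack:
    """Repair isolated single-date spikes/troughs in each temporal signature.

    An interior acquisition ``t`` is an anomaly when its value departs from
    the average of its temporal neighbours by more than ``spike_threshold_db``
    *and* is a local extremum (the signature turns around at ``t``).  Such
    values are replaced by the neighbour average.  Endpoints are never
    altered and a single simultaneous pass is made, so the repair is
    idempotent for isolated anomalies.
    """
    if spike_threshold_db <= 0:
        raise ValueError("spike_threshold_db must be positive")
    if stack.n_dates < 3:
        warnings.warn(
            "stack has fewer than 3 acquisitions; anomaly interpolation skipped",
            stacklevel=2,
        )
        return stack.with_values(stack.values_db.copy())

    x = np.where(stack.valid_mask, stack.values_db, np.nan)
    prev, cur, nxt = x[:-2], x[1:-1], x[2:]
    mid = 0.5 * (prev + nxt)
    with np.errstate(invalid="ignore"):
        spike = (
            np.isfinite(prev)
            & np.isfinite(cur)
            & np.isfinite(nxt)
            & (np.abs(cur - mid) > spike_threshold_db)
            & ((cur - prev) * (nxt - cur) < 0)
        )
    out = stack.values_db.copy()
    out[1:-1][spike] = mid[spike]
    return stack.with_values(out)
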