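# Methods

## Scope and data model

The package operates on a `SigmaStack`: a T×H×W array of terrain-geocoded
sigma-naught (σ°) values in dB on a 10 m pixel grid, with an
`AcquisitionCalendar` of strictly increasing dates whose gaps are integer
multiples of a nominal cadence (12 days by default; missing passes are
allowed). Geocoding, radiometric calibration, incidence-angle
normalisation and mosaicking are out of scope: inputs are assumed already
normalised, as produced by a standard SAR preprocessing chain. Only the VH
polarisation is modelled and classified; the rule thresholds are VH
quantities.

## The rice signature model

A rice pixel's noiseless VH curve is piecewise linear in time:

* a pre-season level (drained/stubble fields) until one cadence step before
  flooding;
* a linear descent into the flooding minimum at the start of season (SoS);
* a linear rise over `rise_days` to the flowering peak;
* a linear decline of `decline_rate` dB per 12-day step that saturates at
  the pre-season baseline — ripening dries the canopy back towards its
  unflooded level and must not undercut the flooding minimum, otherwise
  the seasonal minimum of an early-sown pixel would drift to the last
  acquisition.

The SoS is snapped to the nearest acquisition, so the argmin of the
noiseless series is exactly the acquisition closest to the flooding date.
SoS is likewise reported only at acquisition dates (12-day quantisation);
no sub-cadence interpolation is attempted.

Defaults for the stochastic parameters (all configurable via
`RicePriors`):

| parameter | default | why |
|---|---|---|
| flooding minimum | within [−22.03, −17.69] dB | observed envelope of VH flooding minima for transplanted rice |
| flowering peak | within [−16.10, −14.20] dB | observed envelope of VH flowering peaks |
| rise (peak − min) | U[3.40, 6.74] dB | inside the observed 2.69–6.74 dB range and symmetric about the observed 5.07 dB mean; independent uniforms on the two envelopes would centre the rise at 4.71 dB |
| pre-season level | U[−17.0, −15.5] dB | between flood and peak levels; keeps the flooding dip the unique minimum |
| rise duration | {36, 48, 60} days | 3–5 acquisition intervals from transplanting to flowering |
| post-peak decline | 0.5 dB / 12 d | gentle ripening decline |
| additive noise | 0.3 dB (1 σ) | residual calibration/environmental variability |
| speckle | gamma, 4.4 equivalent looks | the sensor's stated ENL; multiplicative in linear power |

The peak is drawn conditionally on the rise so that `(min, peak)` always
lies inside both printed rectangles. Within a scene, the four stochastic
curve parameters are drawn from spatially correlated fields
(rank-uniformised smoothed Gaussian fields, correlation length
`param_blob_px` = 6 px): crop variety, flooding depth and management vary
by field, not by 10 m pixel, while speckle remains independent per pixel.
The rank transform keeps every marginal exactly equal to the prior, so
scene statistics match the single-signature sampler.

Negative classes are stand-ins (none is quantified by observation, all are
configurable): urban/bare a −8 dB constant; permanent water a −22 dB
constant for the whole season (under water longer than any admissible
flooding period, and without a rise); non-rice vegetation a moderate level
(U[−15.5, −14.5] dB) with a slow seasonal oscillation of total range
≤ 2 dB, below the smallest rice rise.

## Scene synthesis

Land cover is assigned by ranking a smoothed Gaussian field and cutting at
the cumulative class fractions — counts are exact and patches are
contiguous, the situation a spatial filter is designed for. SoS dates are
assigned to rice pixels by quantile-mapping a second smooth field onto the
configured planting-window distribution (default: uniform over the
acquisitions in the window), giving spatially coherent planting blocks.
Districts are vertical strips of the grid: area accounting needs labels,
not real geometry. Atmospheric events are simulated as isolated
single-acquisition perturbations of ±`magnitude_db` (default 4 dB) at a
configurable cell rate (default 5%), never at the first or last
acquisition and never at adjacent acquisitions of one pixel.

Ground-truth survey points are sampled at patch-interior pixels (class
masks eroded by 2 px; for rice, interior of the SoS-homogeneous region):
handheld-GPS survey points are taken mid-field, not on 10 m parcel
boundaries, and a monitoring field has a single transplanting date. The
60/40 train/validation split is stratified by label and fixed before any
classification output is inspected.

## Preprocessing

**Multi-temporal speckle filter.** For each date the local spatial mean
S_t (window 5×5, linear power) is computed; the output is
`S_t · m / m_S`, where `m` is the pixel's temporal mean and `m_S` the
temporal mean of its spatial-mean series. Every pixel's temporal mean in
linear power is preserved exactly while per-date spatial speckle variance
drops roughly as the window size; all averaging is in linear power because
intensity adds linearly, whereas the classifier thresholds are quoted in
dB. This single mean-preserving temporal-ratio filter stands in for the
multi-filter chain of operational processors; spatial detail at class
boundaries is deliberately traded for temporal fidelity, so classification
errors concentrate at patch borders. Note the output is not formally
bounded by the input's space-time envelope (a pixel uniformly brighter
than its neighbourhood can exceed it); under speckle statistics it stays
inside with high probability, and the test suite checks exactly that.

**Atmospheric anomaly interpolation.** An interior acquisition is an
anomaly when it deviates from the average of its temporal neighbours by
more than a threshold *and* is a local extremum; it is then replaced by
the neighbour average in a single simultaneous pass (endpoints untouched,
so isolated repairs are idempotent). The operation's default threshold is
3 dB, appropriate for raw single-pixel series where anomalies of ±4 dB
are the dominant isolated excursions. Inside the pipeline, which runs the
filter first (filtering → anomaly removal → rules), the stage uses a 6 dB
threshold: spatial averaging has already diluted single-date anomalies
~25-fold, while a rice flooding trough remains a legitimate
single-acquisition excursion of up to ~4 dB — a 3 dB threshold after
filtering would "repair" the very feature the classifier keys on. The
residual anomaly effect that no 3-point test can remove — a small
whole-series shift of the pixel's preserved temporal mean (up to ~+0.5 dB
per spike in linear averaging) — is absorbed by the margins of the
threshold envelope and by field-level training curves (next section).

## Threshold extraction

Training curves are *field* signatures: the linear-power mean of a 3×3
window around each rice training point (a monitoring field spans many
10 m pixels). Field averaging suppresses residual speckle and anomaly
shifts that single-pixel curves would propagate into the envelope.

From ≥3 field curves the extractor takes, in dB: `a/b` = min/max temporal
mean ∓/± margin; `c/f` = max/min of (max − min) ± margin (f floored at 0);
`d` = max of the per-curve minima + margin; `e` = min of the post-minimum
peaks − margin; SoS window = [earliest, latest] argmin date ± one cadence;
growth bounds = observed min/max days from minimum to post-minimum peak
∓/± one cadence; maximum time underwater = longest observed below-`d` run
+ one cadence. The default margin is 0.5 dB. Two numerical guards:

* the margins on `d` and `e` are capped at 45% of the raw gap between
  them, keeping `d < e` always — the worst flooding minima (≈ −17.7 dB)
  and worst peaks (≈ −16.1 dB) can sit closer than twice the margin, and
  these two bounds need little widening anyway since noise biases a
  pixel's minimum down and its peak up;
* an extraction in which the highest per-curve minimum reaches the lowest
  peak is rejected as inconsistent rather than silently producing an
  unusable threshold set.

Temporal means are computed in dB, matching how the thresholds are quoted.
Season-length bounds (90/160 days, from the regional samba crop calendar)
are carried for post-hoc filtering when a stack spans the full season; the
in-season R5 test uses the growth-phase bounds instead, because
classification ends at the last acquisition, often before harvest.

## Classification and phenology

The seven rules are evaluated as a conjunction — each parameter is a
bound, and conjunction is the only combination under which every bound
stays meaningful. Argmin/argmax ties break to the earliest date (SoS is an
onset event). Pixels with fewer than 10 valid acquisitions are
unclassifiable: excluded from maps and area sums, counted in a QA layer.
Masked acquisitions are ignored identically in every rule, so decisions
are invariant to nodata padding. `classify_pixel` is the scalar reference;
`classify_stack` is an independent vectorised implementation tested for
pixelwise equality against it. Relaxing `a↓, b↑, c↑, f↓, e↓` or widening
the SoS window can only add rice pixels; `d` is deliberately excluded from
that monotonicity statement because raising it also lengthens below-`d`
runs against a fixed maximum time underwater.

SoS maps report the acquisition index of the minimum for rice pixels; the
standalone `detect_sos` (minimum within a search window) agrees with the
classifier's index on rice pixels by construction. Season bins
(early/major/late sowing windows) are per-year inputs; binning requires
every SoS date to fall in exactly one bin and conserves total area.

## Areas and validation

Hectares use the pixel spacing (10 m × 10 m = 0.01 ha/pixel), which tiles
the map without overlap, not the larger resolution cell. Tables carry
exact Total rows/columns; values are kept at full precision and rounded
only for display. Validation points resolve to the pixel containing their
coordinates (no neighbourhood majority); points on unclassifiable pixels
are excluded and logged. OA is reported to 1 decimal and kappa to 2, the
conventional table format.

## What the generator does and does not emulate

It emulates: the 12-day revisit with missing passes; the rice dB curve
and its printed envelopes; contiguous land-cover patches and per-field
parameter variation; ENL-4.4 gamma speckle; isolated atmospheric
spikes/troughs; mid-field ground truthing. It does not emulate: real field
geometry and mixed pixels at sub-field scale, topographic and
incidence-angle effects, spatially correlated rain cells (anomalies here
are independent across pixels), double-cropping within one stack,
non-rice classes with rice-like flooding (e.g. aquaculture), or any
real-scene co-registration error. Passing the recovery tests therefore
demonstrates the internal consistency of the chain under its own noise
model — envelope-based thresholds recover a known truth through speckle
and anomalies — not field performance on real scenes, whose accuracy
depends on survey quality and landscape fragmentation.

## Numerical choices

* Scene experiments in tests and the acceptance script use a 200×200 grid
  (40,000 pixels, ~24,000 rice) with a 14-acquisition season and a 300
  point survey, and 10,000 draws for prior statistics — sizes at which
  every statistic of interest is stable to well under its tolerance.
* Quantile assignment of classes/SoS breaks rank ties with infinitesimal
  jitter, so requested fractions are met exactly.
* All randomness flows from a single integer seed through named
  `SeedSequence` children (scene, anomalies, survey, split); reruns are
  byte-identical, and the manifest records the seed, every parameter,
  per-rule rejection counts and stage timings.
* Rasters are written as multi-page float32 TIFF (nodata −9999) with the
  calendar embedded as JSON and a sidecar CSV of dates; no CRS is
  attached since synthetic scenes have no geography.

## Known limitations

* The mean-preserving ratio filter replaces, at contract level, the
  proprietary multi-temporal and anisotropic-diffusion filters of
  operational processors; only its two downstream-relevant properties
  (temporal-mean preservation, spatial variance reduction) are claimed.
* A 3-point interpolator cannot distinguish a one-acquisition flooding
  trough from an atmospheric trough of similar depth on a single pixel;
  the pipeline resolves this by ordering (filter first) and threshold
  (6 dB), not by detection, and spatially correlated anomalies would
  defeat the dilution argument.
* Min/max envelope extraction is sensitive to contaminated training
  curves by design (it is the stated policy); field-level averaging and
  mid-field sampling are the mitigations, not robust statistics.
* The published Cauvery Delta tables carry occasional ±1–2 ha internal
  rounding slips between cells and their printed totals; cells are stored
  as published and only internally consistent sums are asserted.
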