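# ricesar

Rule-based rice area and start-of-season (SoS) mapping from multi-temporal
C-band SAR VH backscatter time series.

## The problem

Rice is transplanted into flooded fields. In C-band VH backscatter a rice
pixel therefore traces a characteristic dB curve over the season: a sharp
minimum at agronomic flooding (the start of season), a steep rise through
tillering to a peak at flowering, and a slow decline towards harvest. A
12-day SAR revisit (e.g. Sentinel-1 IW-GRD, 10 m pixel spacing) sees this
curve through clouds and monsoon rain, which defeats optical sensors exactly
when rice is growing. Operational area estimation exploits this: classify
each pixel's temporal signature with thresholds derived from monitored rice
fields, date its SoS at the backscatter minimum, and aggregate pixels into
district-level hectare statistics.

`ricesar` implements that chain at desk scale for researchers in
agricultural remote sensing: a synthetic-scene generator with known truth
(since real scene archives and field surveys are not shippable), temporal
preprocessing, the parameterised classifier, SoS retrieval, area
accounting, and error-matrix validation. It also bundles the published
district/date rice-area statistics of the Cauvery Delta Zone (Tamil Nadu,
samba seasons 2017-18 … 2022-23) as worked inputs for the accounting
layer.

## The classifier

Thresholds come from training-field dB curves (minimum/maximum envelope
± margin): lowest/highest temporal mean `a, b`; minimum/maximum seasonal
variation `f, c`; maximum value at SoS `d`; minimum value at the peak `e`;
an admissible SoS window; growth-duration bounds; and a maximum time
underwater `t₂−t₁`. A pixel is rice iff all of:

| rule | test |
|------|------|
| R1 | temporal mean ∈ [a, b] |
| R2 | max − min ∈ [f, c] |
| R3 | min ≤ d, dated inside the SoS window |
| R4 | post-minimum peak ≥ e |
| R5 | minimum→peak duration within growth bounds |
| R6 | consecutive run below d from the minimum ≤ t₂−t₁ |
| R7 | peak observed no later than the last acquisition t_last |

SoS is the acquisition date of the signature minimum (ties → earliest).
Map accuracy is assessed on reserved ground-truth points with an error
matrix: overall accuracy `OA = 100·A/N`, producer's/user's accuracies, and
the kappa coefficient `K̂ = (N·A − B)/(N² − B)` where `A` is the diagonal
sum and `B = Σ (row total × column total)`.

## Worked example

```python
import ricesar as rs
from ricesar.datasets import SEASON_BINS, sos_totals_by_date
from ricesar.phenology import bin_sos_areas

# Published per-SoS-date zone totals, summed into sowing windows
binned = bin_sos_areas(sos_totals_by_date("2017-18"), SEASON_BINS["2017-18"])

# End-to-end synthetic run: simulate -> preprocess -> fit -> classify ->
# SoS -> areas -> accuracy
cfg = rs.RunConfig(scene=rs.SceneConfig(grid_shape=(64, 64)), seed=5)
manifest = rs.run_pipeline(cfg, "demo_run")
```

prints (via the surrounding script):

```
samba 2017-18 rice area by sowing window (ha):
   early:    38,823
   major:   396,466
    late:    73,292
   total:   508,581

synthetic 64x64 scene, seed 5:
  validation points: 120
  overall accuracy:  94.2%
  kappa:             0.88
```

The early window (21 Aug – 14 Sep) is groundwater-irrigated early sowing;
the major window (26 Sep – 13 Nov) is the main canal-fed samba planting;
the late window (25 Nov – 12 Jan) flags double-cropped fields whose second
crop floods after the first harvest. On the synthetic scene, the
classifier recovers the generator's rice mask at 94% overall accuracy
(kappa 0.88) from speckled, anomaly-corrupted backscatter.

The same chain is available from the shell:

```bash
ricesar run-all --seed 5 --outdir demo_run      # full pipeline + report
ricesar areas --year 2017-18                    # published tables + bins
```

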