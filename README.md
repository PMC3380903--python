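# rainsure

Site-specific drought-index insurance design for smallholder rain-fed
agriculture.

Weather-index (parametric) insurance pays out on an observable rainfall
index instead of assessed crop loss, eliminating moral hazard and loss
adjustment costs — but only if the index actually tracks yield loss at
the insured site, on the insured soil, for the insured crop. `rainsure`
implements an end-to-end design pipeline for such contracts in data-poor
tropical regions, where long yield and rainfall records do not exist and
pseudo-historical data must be simulated instead:

1. **weathergen** — a seeded stochastic daily rainfall generator for
   tropical sites: wet/dry occurrence follows a Markov chain on the last
   1–3 days' history (third order by default — first-order chains
   reproduce temperate frontal weather but not tropical convective
   persistence), gamma-distributed wet-day amounts with monthly
   parameters, and an optional mid-season dry spell (the Central American
   *canícula*) splitting the rainy season into the *primera* and
   *postrera* cropping periods.
2. **cropmodel** — a water-limited drybean yield model: a soil-bucket
   water balance at the dekad (10-day) step over eight generic soils
   (four textures × deep/shallow profile), with runoff increasing with
   texture heaviness and slope, and yield falling with the
   sensitivity-weighted sum of stage water shortfalls.
3. **calibration** — the core algorithm. For each *run* (one soil within
   one site/pixel), estimate the per-dekad **minimum water requirement**
   (MWR, in mm of rainfall): the dekad deficit is `min(RAIN − MWR, 0)`
   (surpluses ignored), the season total deficit is the sum over dekads,
   and the MWR vector is optimized — subject to MWR ≥ 0 — to maximize the
   squared Pearson correlation R² between total deficit and simulated
   yield over the **lowest yield quartile** of the simulated years (the
   upper and middle quartiles should have essentially zero deficit and
   carry no information about where loss begins). The sum of the MWRs is
   the **rainfall index** (mm).
4. **contract** — the printed insurance sheet: MIN/RAIN/DEF rows, a
   trigger (e.g. −70 mm total deficit), a sowing window with a
   transparent onset rule ("first day after 5 consecutive rainy days over
   5 mm each"), and an indemnity of a fixed rate (e.g. US$5) per mm of
   deficit beyond the trigger.
5. **pricing** — empirical (burn-rate) trigger-exceedance probabilities,
   expected payouts, and actuarially fair premiums per pixel × soil, with
   an optional loading factor and soil-averaged summaries.

Everything is deterministic under a master seed, so a full design run is
reproducible bit for bit.

## Worked example

Settle a severe season against the packaged sample contract:

```
rainsure evaluate \
    --contract src/rainsure/data/contract_example.yaml \
    --rain src/rainsure/data/season_payout.csv
```

```
RAINFALL INSURANCE CONTRACT
Reference weather station: San Dionisio INETER weather station
Crop:                      Dry beans - drought tolerant type
Reference soil type:       deep_sand
Sowing window (day of yr): 135 to 166
Sowing date rule:          first day after 5 consecutive rainy days over 5 mm each
Trigger value:             -70 mm
Premium price:             US$3
Indemnity:                 US$5 for every mm of rainfall deficit after the trigger value

          d1-10   d11-20   d21-30   d31-40   d41-50   d51-60   d61-70   d71-80   d81-90
MIN           0       10       10       25       40       40       40       30        0
RAIN        5.8      3.6        0      9.5      4.1     23.5     12.6        2     96.1
DEF                 -6.4      -10    -15.5    -35.9    -16.5    -27.4      -28
TOTAL rainfall deficit: -139.7 mm
Triggered: yes
Indemnity payment: US$348.50
```

Reading the sheet: MIN is the crop's minimum rainfall requirement per
10-day window; DEF is the shortfall where observed RAIN fell below MIN
(surpluses never offset deficits). The season's total deficit of
−139.7 mm is beyond the −70 mm trigger, so the contract pays
US$5 × (139.7 − 70) = US$348.50. A milder packaged season
(`season_no_payout.csv`) totals −49.4 mm and pays nothing.

Calibrating an index from scratch on simulated droughty weather:

```python
import rainsure as rs

table = rs.run_grid(["BS"], [rs.get_soil("deep_loam")],
                    rs.droughty_wet_season(), rs.CropParams(), 99,
                    seed=1, sowing_day=None, onset_rule=rs.OnsetRule(),
                    sowing_window=(135, 166))
result = rs.calibrate_run(table, seed=1)
print(f"R2 (lowest quartile): {result.r2:.3f}")
print(f"rainfall index: {result.index_mm:.1f} mm")
```

```
R2 (lowest quartile): 0.897
rainfall index: 126.1 mm
```

The R² of 0.897 means the summed dekadal rainfall deficit explains ~90%
of the yield variation among the 24 worst of 99 simulated years on this
soil — an index a farmer and an insurer can both verify from a rain
gauge, yet tightly coupled to crop loss. The index (126 mm) is the sum of
the calibrated per-dekad MWRs, i.e. the season water requirement the
contract protects.

The full pipeline (simulate → calibrate per pixel × soil → write
contracts → price) runs from one YAML config:

```
rainsure pipeline --config my_region.yaml
```

producing a run table CSV, one calibration JSON and contract YAML per
(pixel, soil), and a risk grid CSV of exceedance probabilities and
premiums per trigger, including soil-averaged rows.

## Limitations

The weather generator and crop model are transparent, seeded stand-ins
with the structure the index method assumes, not calibrated models of any
real site: absolute yields and mapped probabilities for an actual region
require a fitted weather generator and a physiological crop model. Tail
behaviour beyond the simulated record (extreme-event extrapolation) and
ENSO conditioning are out of scope. See `docs/methods.md` for the model
equations, parameter choices, and known limitations.
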