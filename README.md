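# orchard-fbc

Per-tree carbon-balance modelling of apple **fruit-bearing capacity (FBC)**:
how many fruit of a chosen harvest diameter each tree in an orchard can
supply with carbon, given its LiDAR-measured leaf area, the season's
weather, fruit growth and respiration curves, and leaf photosynthesis
parameters. The package is aimed at precision-horticulture researchers and
crop-load modellers who want a tested, reproducible implementation of the
full chain — from point cloud or points-per-tree counts to per-tree FBC
maps, Getis–Ord hot/cold-spot classification, and regressions of fruit
quality on absorbed photosynthetic energy — together with a synthetic
orchard generator that replaces field data with known ground truth.

## The model

For each tree with total leaf area `LA` (m²) on ground area `G` (3.2 m² at
3.2 m × 1.0 m spacing):

- leaf area index `LAI = LA / G`, light interception
  `LI = LImax·(1 − exp(−k·LAI/LImax))` with `k = 0.5`, `LImax = 0.7`;
- daily canopy assimilation per unit ground area (big-leaf daily
  hyperbola), with `S` the daily solar radiation integral (MJ m⁻² d⁻¹),
  `DL` the day length (s), `maxα` the leaf quantum yield (mol CO₂ mol⁻¹
  photons, converted to g CO₂ MJ⁻¹ via the 0.4376 J µmol⁻¹ PAR energy
  content), `maxJ` the non-stomatal-limited light-saturated exchange rate
  (µmol m⁻² s⁻¹) and `PT(T)` a cubic temperature correction:

  `P_daily = (A·S·B)/(A·k·S + B) · LI · 0.27`,
  `A = maxα/0.4376·44`, `B = DL·maxJ·44·10⁻⁶·PT`  [g C m⁻² d⁻¹];

- a fruit's daily carbon requirement is `AGR_C + RC_daily`: the derivative
  of a logistic carbon growth curve scaled to the target harvest diameter
  (via a power-law diameter→mass conversion and `C_fruit = FM·DM_rel·C_rel`)
  plus dark respiration `RC_daily = Rd(DAFB, T)·FM·24·0.27`;
- the per-fruit **leaf-area demand** (cm²) is
  `LA_demand = 0.95·(AGR_C + RC_daily) / (P_daily·C_part/LAI) · 10⁴`
  with `C_part = 0.8`, Savitzky–Golay smoothed (order 1, window 9);
- `FBC = LA·10⁴ / mean(LA_demand)` over the 31-day window centred on the
  seasonal peak of the fruit carbon requirement, truncated to whole fruit;
- total absorbed photosynthetic energy from canopy closure (1,200 growing
  degree days after bud break, base 4 °C) to harvest:
  `TAPE = LI·ΣS·0.5·G` (MJ), divided by crop load for TAPE per fruit.

A bilinear surface `LA_demand ~ 1 + D + LA + D·LA` summarizes the full
daily model over a (diameter, leaf-area) grid; the published 2018/2019
season coefficients are included as constants.

## Worked example

The one-liner below reproduces the published capacity table for a tree of
the orchard-median 5.5 m² leaf area:

```python
>>> from orchard_fbc import PUBLISHED_DEMAND_REGRESSIONS
>>> [PUBLISHED_DEMAND_REGRESSIONS["2018"].fbc(d, 5.5) for d in (65, 70, 75, 80)]
[130, 98, 79, 66]
>>> [PUBLISHED_DEMAND_REGRESSIONS["2019"].fbc(d, 5.5) for d in (65, 70, 75, 80)]
[139, 105, 84, 71]
```

i.e. a median tree can carry 130 fruit of 65 mm in the 2018 season but only
66 if 80 mm fruit are targeted. A full synthetic season (5 rows × 200
trees) runs in a couple of seconds:

```
$ orchard-fbc run --seed 1 --outdir run1
done: 26 outputs in run1
```

`run1/summary.json` then reports (abridged):

```
"fbc_65_mean": 101.5,  "fbc_65_range": [64, 131],
"la_percentiles_5_50_95": [3.64, 5.38, 7.88],
"li_mean": 0.487,
"validation_ratio": {"ratio_mean": 1.002, "ratio_sd": 0.079, "n_trees": 1000},
"gas_exchange_summary": {"max_alpha": 0.0538, "max_j_nonstomatal": 19.92}
```

Read: the generated orchard hits the target leaf-area percentiles
(3.6/5.5/7.7 m²), mean light interception rounds to 0.5, the refitted leaf
parameters recover the generator truth (0.054 mol mol⁻¹, 19.8 µmol m⁻²
s⁻¹), the 65-mm capacity of individual trees spans 64–131 fruit, and the
simulated harvest count of marketable fruit per tree matches the modelled
capacity (ratio ≈ 1). Stage outputs include `fbc.csv` (per-tree capacities),
`demand_series.csv`, `hotspots.geojson` (Gi* classification), `tape.csv`
and `quality_regressions.csv`.

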