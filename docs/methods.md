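# Methods

This note documents the model the package implements, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the numerical details a user re-deriving results will
want.

## Carbon-balance model

The model treats each tree's canopy as one big leaf receiving the canopy's
average irradiance. Daily net canopy assimilation per unit ground area is
the daily-integral hyperbola

    P_daily = (A·S·B) / (A·k·S + B) · LI · 0.27      [g C m⁻² d⁻¹]

with `S` the daily solar radiation integral (MJ m⁻² d⁻¹) and `DL` the day
length (s). `A` is the leaf quantum yield on an energy basis: maxα
(mol CO₂ mol⁻¹ photons) divided by the PAR photon energy content in direct
sunlight (0.4376 J µmol⁻¹) and multiplied by the CO₂ molar mass (44),
giving g CO₂ MJ⁻¹. `B = DL·maxJ·44·10⁻⁶·PT(T)` is the daily
light-saturated capacity in g CO₂ m⁻² d⁻¹, where `PT` is a cubic in the
daytime mean temperature, clamped to [0, 1.05] (the fitted cubic peaks at
1.013 near 21 °C; clipping at 1 would truncate the fitted optimum). The
0.27 converts CO₂ mass to carbon mass. In the low-light limit
P → A·S·LI·0.27; at high S it saturates at B·LI·0.27/k.

Light interception is Beer–Lambert-type with a ceiling:
`LI = LImax·(1 − exp(−k·LAI/LImax))`, `k = 0.5`, `LImax = 0.7`, and
`LAI = LA/G` is a *per-tree* leaf-area index on the allotted ground area
`G = 3.2 m²`. At the orchard mean leaf areas of ~5.3–5.8 m² this gives
LI ≈ 0.49–0.51.

The fruit side: fresh mass and fruit carbon observations are fitted with
three-parameter logistics; curves are normalized to 1 at the harvest date
and rescaled to target harvest diameters D ∈ {65, 70, 75, 80} mm through a
power-law diameter→mass conversion FM = a·Dᵇ calibrated to the anchor
pairs (65, 102 g) … (80, 198 g) (fitted exponent ≈ 3.2). Carbon content is
FM·DM_rel·C_rel with DM_rel ≈ 0.15 and C_rel declining 0.51 → 0.48 over
the season (linear interpolants; their analytic derivative is included in
the carbon growth rate AGR_C). Dark respiration is log-linear in days
after full bloom (DAFB) and temperature — an exponential developmental
decline times a Q10 response — evaluated at the day's mean orchard
temperature (diurnal variation neglected), and converted to daily carbon
loss per fruit by RC_daily = Rd·FM·24·0.27.

The per-fruit leaf-area demand divides the (fruit-photosynthesis-corrected)
requirement by the per-leaf-area supply:

    LA_demand = 0.95·(AGR_C + RC_daily) / (P_daily·C_part/LAI) · 10⁴   [cm²]

with C_part = 0.8 once the canopy is fully developed. Daily fluctuations
are smoothed with a Savitzky–Golay filter, order 1 and window 9; at the
series edges the fit window shrinks to the available samples (interior
points coincide with `scipy.signal.savgol_filter`; order 1 on a symmetric
window is a centred moving average). FBC is the tree's leaf area in cm²
over the arithmetic mean of the smoothed demand across the 31-day window
centred on the seasonal maximum of the smoothed requirement
(AGR_C + RC_daily) of the smallest target diameter, truncated (floored) to
whole fruit. Because demand factors exactly into a tree-independent daily
series times LAI/LI, per-tree capacities are computed by rescaling one
reference series; `fbc_table` uses this identity, and tests assert it
matches the per-tree path.

TAPE (total absorbed photosynthetic energy) integrates LI·S·0.5·G from the
full-canopy date — the first day 1,200 growing degree days (base 4 °C)
accumulate from bud break — to harvest, in MJ; TAPE per fruit divides by
the tree's crop load.

### Demand-surface regression

A bilinear OLS surface `LA_demand ~ 1 + D + LA + D·LA` is fitted to the
full model's mean windowed demand over the grid D ∈ {65, 70, 75, 80} ×
LA ∈ {2.7, 3.6, 5.5, 7.7, 9.5} (the orchard's 5th/50th/95th leaf-area
percentiles plus the span ends). The published 2018/2019 coefficients are
shipped as constants and reproduce the published capacity table at
LA = 5.5 m² (130/98/79/66 and 139/105/85±1/71 fruit). A bilinear surface
cannot follow the cubic-like diameter→mass conversion exactly: mean
windowed demand is proportional to FM(D)·g(LA) with g = LAI/LI, so the
surface carries ±2–3.5% residuals at the grid corners, worth up to ~4
fruit where FBC exceeds 100. The shipped published coefficients show the
same pattern (demand/FM(D) = 4.14, 4.32, 4.30, 4.18 across the four
diameters). Users needing corner accuracy should evaluate the full model,
not the surface.

## Synthetic generator

The generator emulates a two-season trial in a 5 × 200-tree slender-spindle
orchard at 3.2 m × 1.0 m spacing. Its defaults are the study conditions:

- **Leaf area**: log-normal with (µ, σ) = (1.6756, 0.2311), solved by least
  squares on the log of the target percentiles 3.6/5.5/7.7 m², truncated
  to [2, 10] m²; optional rectangular patches offset LA to plant spatial
  clusters.
- **Weather**: clear-sky half-sine (base 16, amplitude 10 MJ m⁻² d⁻¹ over
  bud break → harvest) times a Beta(5, 2) cloudiness factor scaled to
  (0.2, 1.0]; season-mean S ≈ 17–18 MJ m⁻² d⁻¹. Photoperiod 14–16 h.
  Daily mean temperature tracks the season (8 + 12·phase °C), co-varies
  with cloudiness, and carries N(0, 1.5 °C) noise; daytime mean is 5 °C
  above the 24-h mean. The series starts at bud break (DAFB −38) so
  degree-day accumulation for the full-canopy date uses the same series;
  full canopy falls near 57–60 DAFB under the defaults.
- **Fruit growth**: logistic with midpoint at 0.8 of the 116-d season and
  rate 0.075 d⁻¹, reaching 145 g at harvest. This places the carbon-demand
  peak near 93 DAFB and makes carbon at 50 DAFB ≈ 4.5% of the harvest
  value, so the total seasonal requirement at a 65-mm target is ≈ 7.5 g —
  the printed-summary scale the generator is calibrated to. The implied
  early-season mass (~1.5 g at 30 DAFB) is smaller than real fruitlets; a
  logistic matching the late-season totals cannot also match early sizes.
  Per-fruit CV is 15% (a modelling choice, not a measured value), DM_rel ~
  N(0.15, 0.01), C_rel declines 0.51 → 0.48.
- **Respiration**: Rd = rd_ref·exp(−λ·DAFB)·Q10^((T−20)/10) with
  rd_ref = 0.11 g CO₂ kg⁻¹ h⁻¹ (at 20 °C, DAFB 0), λ = 0.008 d⁻¹,
  Q10 = 2, log-normal noise σ = 0.08. rd_ref is unobservable directly and
  was solved so the seasonal respiratory loss per fruit lands in the
  reported 0.6–1.2 g range (≈ 8% of the total requirement).
- **Leaf light response**: saturating exponential with quantum yield
  0.054 mol mol⁻¹ (3% leaf-to-leaf spread) sampled at PPFR 2000/250/100/
  50/20/0 µmol m⁻² s⁻¹; each curve's saturated rate sits on a rectangular
  hyperbola against its stomatal conductance with asymptote 19.8 µmol m⁻²
  s⁻¹, and ci/ca co-varies with gs, so the downstream gs-regression
  recovers the non-stomatal-limited value.
- **Point clouds**: expected canopy point count inverts the season
  calibration line (Poisson-dispersed), placed uniformly in an ellipsoidal
  canopy plus a dense trunk line; 5% of canopy points spill beyond the
  0.5 m segmentation cylinder. The default pipeline skips full clouds and
  draws points-per-tree from the same inverse line; the cloud →
  trunk-location → cylinder-segmentation → calibration round trip is
  exercised on single rows (median leaf-area recovery error < 5%).
- **Harvest**: crop load is set at the self-consistent fixed point where
  the count equals the capacity for the fruit size the tree's absorbed
  energy per fruit supports (Poisson-dispersed), mirroring the reported
  near-unity harvest/capacity validation ratio; individual fruit mass is
  Gaussian around a linear function of TAPE per fruit (slope 6 g per
  MJ fruit⁻¹, SD 18 g), soluble solids likewise (0.45% per MJ fruit⁻¹,
  SD 1%), diameters via the inverse mass conversion.

What the generator does **not** emulate: within-canopy light gradients and
shading (the big-leaf assumption is inherited, and tends to overestimate
canopy photosynthesis), real LiDAR beam geometry and occlusion,
year-to-year carry-over physiology, and branch-level source–sink
distances. Passing tests therefore demonstrate the pipeline's internal
correctness and its calibration to the published summary statistics, not
field validity.

## Numerical choices

- Logistic fits: `scipy.optimize.curve_fit` with bounded parameters; at
  least four distinct sampling dates spanning half the season; constant
  series rejected. Harvest normalization anchors on the *measured* mean at
  the harvest date, not the fitted asymptote.
- The light-response form is the saturating exponential
  J = Jmax(1 − exp(−αI/Jmax)) − Rd; it has no extra curvature parameter, and
  α is identified by the initial slope (invariant to adding saturated
  points). Curves with ci/ca < 0.5 are flagged stomatally limited (the
  midpoint between the observed limited, ≤ 0.22, and unlimited, ≥ 0.62,
  ranges).
- Respiration fitting is log-linear least squares; fits with Q10 outside
  [1, 4] are rejected; an optional mask drops the last sampling date (the
  climacteric respiration rise) — the model is for pre-climacteric fruit.
- Trunk location uses a 0.1 m bivariate density histogram restricted to a
  0.2–0.8 m height band (excludes canopy and ground returns); density
  peaks closer than 60% of the expected spacing merge into the stronger
  peak. Cylinder segmentation is a partition: points inside overlapping
  cylinders go to the nearest trunk; boundary points (distance exactly the
  radius) are included.
- Getis–Ord Gi* is self-inclusive with binary distance-band weights
  (default 3.5 m: within-row neighbours and adjacent rows), analytical
  mean/variance, two-sided thresholds ±1.96 (95%) with 90% optional, and
  no multiple-testing correction. Zero-variance fields classify as
  all-"none"; trees without neighbours are flagged `isolated` and excluded.
- FBC truncation is floor; all stage outputs are written at ≥ 6
  significant digits; every run writes a manifest of SHA-256 output hashes
  and is bit-reproducible from config + seed.

## Problem sizes

Defaults run 1,000 trees over a 116-day season in a few seconds. Cloud
round-trip tests use 10–12 tree rows (~40,000 canopy points per tree at
the 2018 calibration); the Gi* oracle cross-check uses ≤ 50-tree
instances, with the vectorized implementation applied unchanged to the
full orchard.

## Known limitations

- The demand surface is bilinear by construction; see the residual
  analysis above.
- The big-leaf model ignores within-canopy shading; reported capacities
  are upper-bound-flavoured.
- The temperature correction cubic is an empirical fit valid roughly for
  0–35 °C daytime means; it is clamped, not extrapolated.
- Leaf-count reporting (mean single-leaf area ≈ 21 cm² implies ~12–57
  leaves per fruit across demand extremes) is a derived convenience, not a
  modelled quantity.
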