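# Methods

## Model overview and assumptions

`heatstrain` computes a steady-state energy budget for a clothed human,
`S = M + R_abs − C − E` (W), and converts the storage flux `S` into an
hourly core-temperature change `ΔT = S·3600/(c_b·m·1000)` with
`c_b = 3.5 J·g⁻¹·K⁻¹`. An individual is *at risk* when `ΔT ≥ 2 °C·h⁻¹`
(inclusive; the threshold is configurable for sensitivity analysis).

Two strong simplifications define the regime of validity:

1. **Fixed skin temperature (36 °C), maximal sweating.** No
   thermoregulatory feedback loop is solved. This deliberately
   overstates the evaporative ceiling for comfortable conditions and is
   intended for screening *hot* conditions, where skin temperature does
   approach 36 °C and sweating is near-maximal. Consequences are
   visible in the outputs: sustained moderate exertion by a low-sweat
   individual can exceed the risk threshold even in mild air, because
   the fixed 36 °C skin bounds the dry-loss gradient. This is a
   property of the model class, not a bug; results for air temperatures
   far below ~25 °C should not be read as physiology.
2. **Steady state over one hour.** The storage flux at the 3 p.m.
   observation is extrapolated linearly for an hour; no transient or
   sub-hourly dynamics, and no behavioural adaptation (people do not
   seek shade, drink, or stop working). Outputs are therefore an upper
   envelope of risk for that hour.

## Flux formulations

The surface-balance correlations are standard heat-stress-engineering
choices; every coefficient is exposed in `HeatBalanceConfig` /
`ClothingParameters` so other dialects of the model can be configured.

* **Psychrometrics.** Tetens saturation pressure
  `p_sat(T) = 0.6108·exp(17.27·T/(T+237.3))` kPa, valid −20…60 °C.
* **Convection.** `h_c = max(8.3·v^0.6, 3.1)` W·m⁻²·K⁻¹. The floor
  represents natural convection; the power law is a whole-body forced
  correlation. Indoor air speed is 0.3 m·s⁻¹ (body movement), outdoor
  2.5 m·s⁻¹ (light breeze) — fixed exposure-level constants rather than
  station wind, which is measured above ground level.
* **Solar.** Absorbed shortwave `R_abs = R_sol·f_p·A·[p·r_cl·(1−α_cl) +
  (1−p)·(1−α_sk)]` with projected-area fraction `f_p = 0.25`, clothed
  proportion `p = 0.4`, area ratio `r_cl = 1.08`, albedos 0.3. Longwave
  exchange is omitted (mean radiant temperature taken equal to air
  temperature), which keeps the surface balance linear; it folds into
  the convection term.
* **Clothing.** A single resistive layer, `I_cl = 0.093 m²·K·W⁻¹`
  (0.6 clo). Its surface temperature solves the linear balance
  `(T_sk−T_cl)/I_cl = h_c·(T_cl−T_a) − (1−α_cl)·f_p·R_sol` in closed
  form; the conduction flux is implemented as
  `(h_c·(T_sk−T_a) − (1−α_cl)·f_p·R_sol)/(1 + h_c·I_cl)`, which is the
  same expression rearranged to stay finite as `I_cl → 0` (where
  `T_cl → T_sk`). A numeric root-finder cross-checks the closed form in
  the tests to 1e-6 °C.
* **Dry exchange.** Bare-segment convection `h_c·A·(1−p)·(T_sk−T_a)`
  plus clothed-segment conduction `A·p·(T_sk−T_cl)/I_cl`. Positive =
  loss; the sign flips as air crosses skin temperature (earlier under
  strong sun, because the clothing surface runs hot).
* **Evaporation.** Sweat-limited loss `m_sw·A·λ·η/60` with latent heat
  `λ = 2426 J·g⁻¹` (evaporation at skin temperature) and efficiency
  `η = 0.85`; environmental capacity `16.5·h_c·A·(p_sat(36) −
  φ·p_sat(T_a))`, floored at zero so supersaturated air cannot heat the
  body through this term. The realized loss is the minimum of the two.
* **Respiration.** Off by default for comparability with the basic
  model; when enabled it subtracts the standard empirical
  `0.0014·M·(34−T_a) + 0.0173·M·(5.87−φ·p_sat(T_a))` from `M`.

## Physiology

* Surface area `A = 0.007184·m^0.425·h^0.725` (kg, cm → m²).
* Maximal sweat rate `m_sw = 7.39 + 2.61·male + 1.16·acclimatized −
  0.07·age` g·min⁻¹·m⁻², with the male indicator forced to zero below
  age 14. Everyone is assumed acclimatized by default. The linear model
  goes non-physical for unacclimatized women above ~105 years, so the
  rate is clamped below at 0.5 g·min⁻¹·m⁻² (configurable); the clamp
  never binds for the default acclimatized population.
* Metabolic rate: exertion anchors 125/225/600/1280 W at the 70 kg
  reference mass, scaled by `(m/70)^0.75`. The source scaling law for
  mass is not uniquely pinned down; classic metabolic allometry (¾
  power) was chosen, with the exponent configurable (1.0 = linear).
  Mass-effect conclusions are sensitive to this choice.

## Population layer

Continuous variables are discretized — height into 10 cm blocks, mass
into 20 kg blocks, sweat rate into 2 g·min⁻¹·m⁻² blocks — and each
block is represented by its arithmetic midpoint (unbiased under
within-block uniformity). Age enters the sweat model as the band
midpoint (80 years for the open-ended 75+ band). Person-types are the
cross-product of body blocks with the stratum's exposure × exertion
distribution; weights multiply and are conserved per stratum to 1e-9.
Aggregation over person-types is *exactly* equivalent to enumerating
individuals whenever individuals sit on block midpoints, and the test
suite asserts this against a brute-force oracle.

Exposure categories: `not_exposed` (can fully modify their
environment; contributes zero risk by construction), `indoors`,
`outdoors`. Indoor air temperature equals the outdoor observation — no
building thermal model. For reporting, rest and minimal exertion are
merged, giving seven cells (not-exposed + {in,out} × {rest/minimal,
moderate, heavy}).

## Synthetic inputs

Real height-mass-by-age-sex tabulations and occupation breakdowns are
restricted custom products, so generators produce stand-ins with the
required *structure*; the anthropometric numbers are configuration, not
demographic claims.

* **Bodies.** Heights Gaussian per (age band, sex) — e.g. adult male
  mean 175–178 cm SD 7, female 162–164 cm SD 6.5, children scaled down;
  BMI log-normal (adult median 23–27.5, log-SD 0.18) coupled to height
  through a Gaussian copula (ρ = 0.2); mass = BMI·height². Samples
  (default 400 per stratum) are rounded to whole cm/kg and tabulated,
  so stratum proportions sum to exactly 1.
* **Occupations.** ~18 categories with a shipped YAML mapping to
  exposure × exertion. Shares are fixed per stratum and calibrated in
  closed form so the population-weighted male:female weight ratio in
  outdoor moderate/heavy cells is 4.0; the generator recomputes the
  implied ratio and refuses to emit a table more than 5 % off target.
  The 75+ strata get identical male and female activity distributions
  (retiree activity assumed sex-neutral); children have no
  heavy-exertion categories.
* **Weather.** A summer series: seasonal sinusoid + AR(1) noise around
  27 °C, humidity anticorrelated with temperature, solar anticorrelated
  with humidity, plus designated spike days that are forced strictly
  above the rest of the series. One seed fixes all three generators.

What passing tests on synthetic data show: the machinery (binning,
weighting, aggregation, monotone response, determinism) is correct
under the assumed structure. What they do not show: calibrated absolute
risk levels for any real population — those require the real
anthropometric and occupation tables dropped in via the documented CSV
schemas.

## Numerical choices

* Budget closure holds to < 1e-9 W by construction (storage is computed
  as the component sum) and is property-tested over random inputs.
* Stratum proportion sums are validated to 1e-6 (CSV round-off);
  internal weight conservation is asserted to 1e-9.
* The risk comparison is inclusive (`≥` threshold). Thresholds/gains
  round-trip through `storage_for_gain` to ≤ 1e-12 °C·h⁻¹ (float
  multiply/divide is not bit-exact).
* Zero insulation, zero solar, saturated air and band edges are all
  handled as exact limits, not special-cased failures.
* Problem sizes: the shipped configuration uses 400 sampled individuals
  per stratum (18 strata), collapsing to ≈300 body bins and ≈1700
  person-types; a four-day simulation runs in well under a second, the
  full test suite in seconds.

## Known limitations

No longwave radiation or building thermal model; one clothing layer;
no percent-body-fat, cardiovascular or hydration covariates; no
behavioural adaptation or acclimatization dynamics; occupation→exposure
mapping is an editable assumption table, not measured exposure; the
daily solar estimate is used directly as the 3 p.m. flux (a
configurable scale factor is provided). Rankings between strata are
more trustworthy than absolute proportions.
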