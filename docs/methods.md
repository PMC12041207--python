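# Methods

## Model and definitions

All efficiencies live on the percent scale. For a nutrient *Nu* with mature
and senesced community-level leaf concentrations `Nu_mat`, `Nu_sen`
(g kg⁻¹),

* resorption efficiency `NuRE = (Nu_mat − Nu_sen)/Nu_mat × 100 %`,
* absolute resorption `Nu_mat − Nu_sen` (g kg⁻¹),
* proficiency: resorption is *complete* when `Nu_sen` falls strictly below
  a boundary concentration — 0.4 g kg⁻¹ by default for P; no default is
  adopted for N, where published boundaries vary with growth form, so the
  caller must supply one.

Negative efficiencies (senesced above mature, possible under field noise)
are reported with a warning rather than clamped: clamping would bias
site means and hide data problems from the diagnostics.

Mass-based literature efficiencies (fractions) convert to the
concentration basis with growth-form mass loss correction factors
`NuRE = (1 − (1 − NuRE_m)·MLCF) × 100 %`, with MLCF 0.780 (evergreen
broadleaf), 0.784 (deciduous broadleaf), 0.745 (conifer), 0.640 (forb),
0.713 (graminoid); the table is overridable. Because senesced leaves have
lost mass, MLCF < 1 and the concentration-based value always exceeds the
raw mass-based percentage.

## Strategy diagnostics

The senesced–mature relation is modelled as `Nu_sen = a·Nu_mat^b` and
fitted as `log₁₀(Nu_sen) = log₁₀(a) + b·log₁₀(Nu_mat)`. Substituting into
the efficiency definition gives `NuRE = (1 − a·Nu_mat^(b−1)) × 100 %`, so
`b > 1` ⇔ efficiency rises as mature concentration falls (*concentration
control*). The resorbed-ratio relation is
`resorbed N:P = ε·(leaf N:P)^λ`, equivalently
`NRE:PRE = ε·(leaf N:P)^(λ−1)`; `λ < 1` ⇔ the scarcer nutrient is resorbed
preferentially (*limitation control*). *Stoichiometry control* is accepted
when NRE–PRE correlate positively and the resorbed N:P regresses on
mature-leaf N:P with a positive significant slope.

Estimation choices:

* **Default estimator** is OLS on site means (n = number of sites,
  df = n − 2). At the 30-site scale this is transparent and exactly
  testable. A **mixed mode** fits the same fixed-effect line on
  replicate-level data with a random site intercept (statsmodels MixedLM,
  REML); with singleton groups the random intercept is unidentified and the
  estimate reduces exactly to OLS, which the code short-circuits. Mixed-mode
  slope tests use a conservative df of (number of sites − 2).
* **Slope-vs-null test**: t = (slope − null)/SE with the fit's df, two-sided
  p reported; directional criteria (b > 1, λ < 1) use the one-sided tail.
  A perfect fit (zero residual, zero SE) is treated as the limiting case:
  p → 0 for a slope away from the null, p = 1 at it.
* **α = 0.05**, unadjusted, log base 10 throughout; no multiple-testing
  correction.
* Sites with non-positive resorbed P (undefined resorbed N:P on the log
  scale) are excluded from ratio fits with a logged count; fewer than three
  remaining sites is an error, not a silent verdict.
* No reduced/standardized major axis variants: the diagnostics are defined
  by the regression of y on x, and the slope test against 1 needs the OLS
  sampling theory.

## Mineralization

One resin-core tube contributes
`rate = (post_soil + resin − pre_soil) / (π(d/2)²·days)` in ng cm⁻² d⁻¹,
where `resin` is the capture summed over all monthly bag exchanges and
inorganic N is the NH₄⁺-N + NO₃⁻-N sum (both summed upstream of this
module). Negative rates (net immobilization) are retained. Site rates are
means over replicate tubes (not pooled budgets — the two agree only for
identical tube geometry, and the mean-of-replicates convention gives an SE).
The site N:P rate ratio uses site means and is flagged undefined when the
site P mean is non-positive.

## Inference

Paired t-tests use df = n − 1 and Cohen's d = mean(diff)/sd(diff) — the
conventional paired standardiser. Independent tests default to Welch;
Cohen's d always uses the pooled SD. Two-sample power comes from the
noncentral t distribution with noncentrality `d·√(n₁n₂/(n₁+n₂))`.
Zero-variance inputs are degenerate: t = 0/p = 1/d = 0 for identical
samples, infinite t reported as p = 0 otherwise, both flagged. The joint
significance rule (p < α **and** |d| > d_min, defaults 0.05/0.2) guards
against trivially small but precisely estimated differences. Normality
(Shapiro–Wilk) and homoscedasticity (Levene, mean-centred) checks are
advisory only and never gate the tests.

## Synthetic transect generator

The generator emulates a 30-site × 3-replicate cold-grassland transect.
Mature log₁₀ concentrations are Gaussian across sites (N: mean 1.30,
sd 0.08; P: mean 0.176, sd 0.10 — about 20 and 1.5 g kg⁻¹) with a small
replicate jitter (sd 0.02). Senesced P follows `a_p·mat^b_p` (defaults
0.221, 1.3) with multiplicative log₁₀-normal noise (sd 0.05 per
replicate). Senesced N is driven by the resorbed-ratio model
(`ε = 1.31, λ = 0.8` by default), from which senesced N is
back-calculated; setting `lambda_np=None` switches N to its own power law
(`a_n`, `b_n`), which is the configuration used for unit-slope calibration
studies. A floor of 1% of the mature concentration guards senesced values
against rare noise excursions past full depletion.

Defaults are calibrated so site summaries fall inside the observed ranges
for alpine permafrost grasslands — site NRE within 37.9–72.3% (mean near
58.7), PRE within 44.4–87.3% (mean near 75.1), senesced P 0.2–0.9 g kg⁻¹
(mean near 0.4), N mineralization mean near 232.5 and P near
0.8 ng cm⁻² d⁻¹. These are calibration targets of the generator, not
empirical claims.

Site N mineralization is constructed from the realised site NRE plus
Gaussian residuals, scaled so that the expected cross-site regression slope
of NRE on N mineralization equals `tradeoff_slope` (default −0.05
percentage points per ng cm⁻² d⁻¹) while the marginal spread stays at
`nmin_sd` (default 85, chosen to match the observed site-to-site spread).
Building the coupling into the mineralization side, rather than perturbing
the leaf chemistry, keeps the power-law and ratio relations exact so the
generator closes on its own parameters. P mineralization is independent
Gaussian (mean 0.8, sd 0.38): the N-only coupling reproduces the
qualitative asymmetry of interest (a trade-off for N, none for P).
Replicate tube rates scatter around the site mean (sd 15% of the mean,
re-centred so the replicate mean is exactly the site value) and are encoded
as pre/post/resin budgets that invert exactly to the intended rate, with
positive net change split 60:40 between resin capture and soil increase.

What the generator does **not** emulate: spatial autocorrelation, climate
or vegetation-type covariates, seasonal timing of resorption, resin
saturation, or a shared site-level "resorption intensity" driving NRE and
PRE jointly. The last point matters for interpretation: under the default
parameters the site NRE–PRE correlation is weak, so the stoichiometry
verdict is usually *not* supported on default synthetic data even though
the construction with λ = 1 demonstrates the supported case. Passing tests
therefore validate the estimators and their calibration, not the field
prevalence of any strategy.

## Validation design and problem sizes

* Closed-form consistency of the efficiency algebra: 1000 random
  (a, b, mature) triples, tolerance 1e-9.
* Mass-basis round trip: all five growth forms × 100 random efficiencies,
  tolerance 1e-9.
* Slope-test calibration: 1000 transects of 30 sites with a unit exponent
  and noise sd 0.05, single replicate per site (the clean iid design for a
  site-level test); the one-sided rejection rate at α = 0.05 must lie in
  [0.03, 0.07]. A 6000-simulation spot check puts the true rate at ≈0.050.
* Exponent recovery: 200 transects at b_p = 1.3, λ = 0.8; seed-averaged
  fitted slopes within ±0.05 of truth, limitation verdict supported in
  ≥90% of runs.
* Trade-off asymmetry: 200 default transects; the N-side coupling detected
  in ≥90% of runs, the uncoupled P side flagged at most α + 0.02.
* The worked single-tube rate (100 ng net gain, 5 cm tube, 90 d) is checked
  against independent hand arithmetic to 1e-6.

These sizes keep the whole validation battery under a minute on one CPU
while holding Monte-Carlo error on the reported rates to well under the
decision margins.

## Known limitations

* The mixed mode's df convention (sites − 2) is conservative;
  Satterthwaite/Kenward–Roger approximations are not implemented.
* No leaching-loss or retranslocation-timing corrections; efficiencies are
  snapshots of the two sampling periods.
* The deposited field measurements behind the published transect summaries
  are not redistributed here; the reproduction test runs only when the user
  places the converted CSVs under `data/deposited/`. The loader accepts a
  `column_map` so differently-headed archives can be read without editing
  files.
* Proficiency "close to the boundary" is not operationalized beyond the
  strict below-boundary count; published counts based on "close to" are
  not reproduced.
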