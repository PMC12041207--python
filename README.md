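# resorb

Analysis toolkit for **leaf nutrient resorption** and **soil nutrient
supply** along grassland transects, aimed at plant and ecosystem ecologists
working with paired mature/senesced leaf chemistry and resin-core soil
incubations — the standard design for asking whether plants in
nutrient-poor (e.g. alpine permafrost) ecosystems conserve nitrogen or
phosphorus more aggressively, and whether leaf resorption trades off
against soil mineralization.

## What it computes

**Resorption efficiency and proficiency.** For each site, community-level
resorption efficiency of nutrient *Nu* is

```
NuRE = (Nu_mat − Nu_sen) / Nu_mat × 100 %
```

from mature (`Nu_mat`) and senesced (`Nu_sen`) leaf concentrations
(g kg⁻¹), together with absolute resorption `Nu_mat − Nu_sen` and a
proficiency verdict against a complete-resorption boundary on the senesced
concentration (0.4 g kg⁻¹ for P, after Killingbeck). Mass-based literature
values convert to the concentration basis through growth-form mass loss
correction factors: `NuRE = (1 − (1 − NuRE_m) · MLCF) × 100 %`.

**Strategy diagnostics.** Three control strategies are tested with log₁₀
power-law regressions:

* *concentration control* — fit `Nu_sen = a · Nu_mat^b`; a slope `b`
  significantly above 1 means resorption is more efficient where mature
  leaves are nutrient-poor;
* *stoichiometry control* — NRE and PRE positively correlated, and resorbed
  N:P proportional to mature-leaf N:P;
* *limitation control* — fit `resorbed N:P = ε · (leaf N:P)^λ`; a slope `λ`
  significantly below 1 means the scarcer nutrient is resorbed
  preferentially.

Slopes are tested against an arbitrary null value by a t-test on
`(slope − null)/SE`; fits run on site means (OLS) or on replicates with a
random site intercept (mixed mode).

**Net mineralization.** Per incubation tube,
`rate = (post_soil + resin − pre_soil) / (π (d/2)² · days)` in
ng cm⁻² d⁻¹, aggregated to site means ± SE and an N:P rate ratio.

**Trade-off tests.** Linear fits of NRE, PRE, and NRE:PRE on the site
mineralization rates and their ratio; a relationship is flagged as a
trade-off when the slope is negative and significant.

**Inference utilities.** Paired/independent t-tests with Cohen's *d* and
95% CIs, noncentral-t power for two-sample designs, Levene/Shapiro
assumption checks, and the joint significance rule
(*P* < 0.05 **and** |*d*| > 0.2).

A seeded synthetic transect generator (`resorb.synthetic`) produces
leaf-chemistry and incubation tables with this exact statistical structure
(30 sites × 3 replicates by default) so the whole pipeline is testable
without field data.

## Worked example

```
resorb simulate --seed 42 --out-dir demo
resorb run-all --leaf demo/leaf.csv --incubation demo/incubation.csv --out-dir demo/out
cat demo/out/summary.txt
```

prints (abridged):

```
n_sites = 30
mean_nre_percent = 58.8962
mean_pre_percent = 74.4016
mean_senesced_p_g_kg = 0.403474
nre_vs_pre_p = 1.53341e-16
nre_vs_pre_cohen_d = -3.08228
nre_vs_pre_significant = True
strategy_concentration_control_P_supported = True
strategy_limitation_control_NP_supported = True
tradeoff_nre_vs_n_min_rate_negative = True
tradeoff_pre_vs_p_min_rate_negative = False
```

Read: across the 30 simulated sites, mean P resorption efficiency (74.4%)
clearly exceeds mean N resorption efficiency (58.9%; paired *P* ≈ 10⁻¹⁶,
|*d*| ≈ 3.1), senesced P sits at the 0.4 g kg⁻¹ complete-resorption
boundary, P resorption follows concentration control (fitted exponent
*b* ≈ 1.22 > 1), limitation control holds (λ < 1), and N — but not P —
resorption trades off against its soil mineralization rate. Per-stage CSVs
(`resorption.csv`, `strategies.csv`, `mineralization.csv`, `tradeoff.csv`,
`comparisons.csv`) hold the full fit statistics.

The same stages are available individually (`resorb compute-resorption`,
`resorb diagnose-strategies`, `resorb mineralization`, `resorb tradeoff`,
`resorb compare`) and as library functions.

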