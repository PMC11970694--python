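# growthcanal

Tools for a recurring question in child-growth epidemiology: when the mean
height-for-age z-score (HAZ) of a population of under-fives declines steeply
over the first two years of life, is that **growth faltering** — an
environmental insult — or a **deceleration toward target height**, the
normal canalization of children born longer than their genetic channel
predicts?

The package is written for biostatisticians and growth researchers working
with cross-sectional parent–child survey data (one measured child plus both
parents' adult heights per row). It implements the full analysis chain:

1. **LMS z-scoring.** A measurement `y` is converted to SD units of a
   growth reference described by age- and sex-specific Box-Cox parameters
   (L, M, S):

   `z = ((y/M)^L − 1) / (L·S)` for `L ≠ 0`, `z = ln(y/M)/S` for `L = 0`.

   Height-for-age (HAZ) and BMI-for-age (BAZ) both use this transform, with
   the recumbent/standing 0.7 cm convention at the 24-month boundary, a
   strict ±4 SD outlier exclusion, and BAZ-based nutritional-status
   categories (underweight < −2; normal −2 to < +2; overweight–obese ≥ +2).

2. **Target heights.** The sex-corrected mid-parental target height is
   `TH = (F + M ± d)/2` (`+` boys, `−` girls), where `d` is the mean
   father−mother height difference estimated per survey wave. TH is
   z-scored at 228 months (19 years) against an adult reference by the
   child's sex, giving the target-height z-score **THz**.

3. **Discrepancy trajectories.** The per-child discrepancy `HAZ − THz`
   (positive = currently taller than the parental prediction) is smoothed
   against age with a from-scratch LOWESS (tricube weights, local linear
   fit), binned into 3-month age bins, and compared between urban and rural
   children with Welch-style normal CIs.

4. **Association statistics.** One-way ANOVA, Pearson chi-square, and
   age-stratified OLS of HAZ on THz plus household covariates, reporting
   both the Pearson correlation and the standardized THz coefficient, with
   R² and adjusted R².

5. **Synthetic cohorts.** Because the motivating survey data are
   access-restricted, a generator produces cohorts with the same
   statistical structure: per-wave secular increase in parental heights, a
   canalization offset δ(age) declining from δ₀ ≈ 1.5 SD at birth to zero
   at 24 months, an urban–rural gap, and a THz coefficient of exactly 1.

No official growth-reference tables are bundled; real WHO 2006/2007 files
are supplied by the user as CSV (`sex,age_months,L,M,S` or per-sex
`Month,L,M,S` files). All tests and simulations run on toy references with
closed-form parameters.

## Worked example

```python
import growthcanal as gc
from growthcanal.trajectory_analysis import bin_discrepancy_by_age, urban_rural_gaps

refs = gc.default_toy_references()
cfg = gc.SimulationConfig(n_per_wave=1250, seed=42)       # 4 waves x 1250
cohort = gc.simulate_cohort(cfg, refs)
cohort = gc.add_zscores(cohort, refs["child_std"], refs["bmi_std"])
cohort = cohort[cohort["age_in_range"] & ~cohort["haz_excluded"]]
cohort = gc.add_target_height(cohort, refs["adult_ref"])
cohort = gc.add_discrepancy(cohort[cohort["thz"].notna()])

print(bin_discrepancy_by_age(cohort).set_index("bin").loc[["0-3", "21-24", "57-60"]].round(2))
```

```
         n  mean    sd
bin
0-3    247  1.34  1.00
21-24  230  0.05  1.02
57-60  250  0.07  0.96
```

Newborns sit ≈ 1.3–1.5 SD above their target-height z-score; from the
21–24-month bin onward the discrepancy is statistically indistinguishable
from zero — deceleration toward target height, not faltering. The
urban–rural contrast and the age-stratified THz association come from the
same frame:

```python
print(urban_rural_gaps(cohort).round(2))      # gap per wave with 95% CI
print(gc.thz_haz_association(cohort).round(2))
```

```
 wave  gap    lo   hi  n_urban  n_rural
 1993 0.12 -0.02 0.27      377      355
 2014 0.31  0.17 0.45      376      384
age_group  pearson_r  beta_thz  std_beta_thz   r2  adj_r2    n
     m0_6       0.56      1.03          0.55 0.34    0.32  486
     y2_5       0.56      1.00          0.56 0.32    0.32 3005
```

(middle rows elided). The raw THz coefficient is ≈ 1 in every age band, as
the generating canalization model implies.

The same pipeline is scriptable from a shell:

```bash
growthcanal simulate --config config.yaml --out cohort.csv
growthcanal zscore   --config config.yaml --out cohort_z.csv
growthcanal analyze  --config config.yaml --out report/
```

`analyze` writes `trajectories.csv`, `age_bins.csv`, `gaps.csv`,
`regression.csv`, `tests.csv` and a `manifest.json` recording the config,
seed and the row-count ledger of every filter step.

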