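# cfmkit

Child-anthropometry analysis toolkit for **coexisting forms of malnutrition
(CFM)** in children under five. It implements the full analytic chain used
in multi-country nutrition surveillance work on DHS-style survey microdata:

1. **z-score engine** — HAZ/LAZ, WAZ and WHZ/WLZ from raw age, sex, weight
   and length/height via the LMS method of the WHO child growth standards,
   `z = ((y/M)^L − 1)/(L·S)` with the log-limit at `L → 0`, including the
   WHO restricted-application adjustment that linearises weight-based
   z-scores beyond |z| = 3 in units of the SD2–SD3 band;
2. **plausibility screening** — |HAZ| ≤ 6, |WHZ| ≤ 5, −6 ≤ WAZ ≤ +5
   (inclusive), with per-record dispositions;
3. **nine-way classification** — normal, the four standalone forms
   (stunting, wasting, underweight, overweight/obese) and the four
   coexisting forms: CUW (underweight + wasting), CUS (underweight +
   stunting), CUWS (underweight + wasting + stunting) and CSO (stunting +
   overweight/obesity, with WAZ ≥ +2 *and/or* WHZ ≥ +2 as the excess
   criterion). Deficits use z ≤ −2, excess uses z ≥ +2. Combinations the
   taxonomy leaves unnamed (e.g. stunted + wasted but not underweight)
   receive a deterministic category plus a conflict flag;
4. **survey-weighted prevalence** — Horvitz–Thompson ratios with Wilson
   (default) or Wald 95% CIs on the Kish effective sample size, at
   national, regional (six LMIC regions, 62-country lookup) and global
   levels, with per-country weight rescaling for pooled estimates;
5. **association models** — Pearson chi-square screening (p ≤ 0.05),
   multinomial logistic regression by Newton–Raphson (underweight as the
   reference outcome for CUW/CUS/CUWS; stunted vs CSO as a binary model),
   likelihood-ratio backward elimination of covariate blocks at α = 0.05,
   and VIF collinearity diagnostics;
6. **synthetic data generator** — DHS-like microdata from a latent
   trivariate-normal z-model with planted covariate effects, calibrated
   odds ratios, gamma sampling weights and cluster/country structure, plus
   an exact category-probability oracle, so every stage is testable
   without restricted survey data.

Intended users: epidemiologists and biostatisticians who need a tested,
reproducible CFM pipeline, and methodologists who want a simulation
sandbox with known ground truth.

## Worked example

```bash
cfmkit simulate --seed 17 --clusters 8 --emit measurements \
    --out children.csv --truth truth.json
cfmkit run --input children.csv --out-dir reports/ --seed 17
```

which prints

```
wrote 1200 records to children.csv
pipeline complete: {'input': 1200, 'analyzed': 1199, 'excluded_incomplete': 0, 'excluded_outlier': 1}
```

`reports/prevalence.csv` then starts

```
level,unit,category,point_pct,ci_low_pct,ci_high_pct,n_unweighted,n_weighted
national,Egypt,malnourished,34.338349,27.538408,41.847676,200,206.343687
national,Egypt,sfm,24.028447,18.160008,31.073253,200,206.343687
```

read: of the 1,200 simulated children, 1,199 had complete, biologically
plausible anthropometry (one record fell beyond the ±6/±5 SD outlier
bounds); in the synthetic "Egypt" survey 34.3% of children are
malnourished (weighted), 24.0% carry exactly one form (SFM), and the CFM
rows below split the remainder into CUW/CUS/CUWS/CSO. Within each unit
the report satisfies *malnourished = SFM + CFM* and
*CFM = CUW + CUS + CUWS + CSO* to numerical precision.

The same chain is available as library calls
(`cfmkit.generate_population`, `cfmkit.classify_frame`,
`cfmkit.aggregate`, `cfmkit.models.backward_eliminate`); the CLI is a
thin wrapper.

## Layout

```
src/cfmkit/
  growth_reference.py   LMS tables, z-scores, restricted adjustment
  classification.py     plausibility bounds, nine-way taxonomy, tallies
  regions.py            62-country -> six-region lookup
  survey.py             weighted prevalence, Kish n_eff, Wilson/Wald CIs
  models.py             chi-square screen, multinomial NR fitter, backward
                        elimination, VIF, OR tables
  synthetic.py          generator, category-probability oracles, OR calibration
  io_utils.py           CSV dialects (incl. DHS child-recode), dispositions
  pipeline.py, cli.py   stage orchestration and the `cfmkit` CLI
docs/methods.md         model assumptions, parameter choices, limitations
```
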