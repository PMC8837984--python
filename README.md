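# dietcvd

Diet-quality scoring and cardiovascular risk analysis for longitudinal
cohorts, with a calibrated synthetic-cohort generator.

Nutritional epidemiology has shifted from nutrient-based rules ("eat
less saturated fat") to food-based dietary patterns ("eat a
nutritionally rich, plant-centered diet").  This package implements the
statistical machinery for comparing the two kinds of rule head-to-head
in a prospective cohort of young adults followed for incident coronary
heart disease (CHD) and stroke over 32 years:

* **A Priori Diet Quality Score (APDQS)** — 46 food groups rated
  beneficial (n=20), adverse (n=13) or neutral (n=13); beneficial
  groups score 0–4 by ascending intake quintile, adverse groups 4–0,
  neutral groups 0; total range 0–132, higher = more plant-centered.
* **Keys Score** — the classic dietary-lipid predictor of serum
  cholesterol, `1.35·(2·P_sf − P_pufa) + 1.5·√C`, with `P_sf`/`P_pufa`
  the percent of energy from saturated/polyunsaturated fat and `C`
  dietary cholesterol in mg/1000 kcal.
* **Plasma lipid derivations** — Friedewald LDL-C
  (`TC − HDL − TG/2.2` mmol/L, invalid above TG 4.52 mmol/L),
  non-HDL-C, mg/dL ↔ mmol/L conversion (factor 0.0259).
* **Cumulative-average time-varying exposures** — the baseline value
  predicts events on follow-up years (0, 7], the mean of exams Y0+Y7
  predicts (7, 20], and the mean of Y0+Y7+Y20 predicts (20, 32];
  missing later exams fall back on the running mean of what was seen.
* **Models** — OLS of concurrent lipid change on per-SD score change
  with the full epidemiologic adjustment set, and time-varying Cox
  proportional-hazards models on counting-process `(start, stop]`
  intervals (own Newton solver with analytic score/Hessian, Breslow or
  Efron ties), with quintile and per-1-SD codings, Wald trend tests, an
  exposure × log(time) proportional-hazards check, and effect-modifier
  interaction tests.
* **Synthetic cohort generator** — zero-inflated gamma food-group
  intakes driven by a latent plant-preference factor, nutrients coupled
  to foods (so the two scores correlate ≈ −0.31), lipid change tied to
  score change, and rare events from a piecewise-exponential hazard on
  the cumulative-average exposures — giving every downstream stage a
  known ground truth.

## Worked example

```python
import numpy as np
from dietcvd import SimulationConfig, simulate_cohort, fit_cox_timevarying
from dietcvd.pipeline import score_cohort, prepare_stage, risk_table_for
from dietcvd.lipids import derive_lipid_panel

cohort = simulate_cohort(SimulationConfig(seed=42))   # default n = 5115
scores = score_cohort(cohort.intakes, cohort.nutrients)
lipids = derive_lipid_panel(cohort.lipids)
ids, log = prepare_stage(cohort, lipids)              # eligibility filters
risk = risk_table_for(cohort, scores, lipids, ids, "apdqs", "chd")
effect = fit_cox_timevarying(risk, "apdqs")
```

With seed 42 this prints (via `print(log)`, the score summaries and
`effect.to_frame()`):

```
initial n = 5115
  removed (implausible energy): 129
  removed (prevalent condition): 276
  removed (missing covariates): 53
remaining n = 4657

Y0 APDQS 66.0 +/- 12.9, Keys 48.4 +/- 9.8, corr -0.30
CHD per-1-SD APDQS HR 0.74 (0.59-0.92), trend p 0.007, events 131

quintile   hr  ci_low  ci_high  events    n
      Q1 1.00     NaN      NaN      39 1329
      Q2 0.70    0.43     1.13      30 1604
      Q3 0.80    0.50     1.28      32 1661
      Q4 0.48    0.28     0.84      20 1710
      Q5 0.36    0.18     0.74      10 1223
```

Read: after excluding participants with implausible energy intake,
prevalent disease or missing covariates, 4657 remain; the generator's
true per-1-SD (13-point) APDQS hazard ratio for CHD is 0.73, and the
adjusted time-varying Cox model recovers 0.74 (95% CI 0.59–0.92) from
131 events, with a monotone gradient across quintiles of the
cumulative-average score (reference Q1 = 1.00).  The proportional-
hazards check (`ph_assumption_check(risk, "apdqs")`) gives p = 0.74 —
no evidence against proportionality, as expected under this generator.

A command-line interface wraps the same stages:

```bash
dietcvd simulate --seed 5 --out-dir run/      # writes TSV tables
dietcvd score --in-dir run/
dietcvd prepare --in-dir run/
dietcvd exposures --in-dir run/ --exposure apdqs --outcome chd
dietcvd fit --in-dir run/ --exposure apdqs --outcome chd
dietcvd report                                 # food-group contrast table
dietcvd run-all --seed 5 --out-dir run/        # everything + manifest
```

## Layout

- `src/dietcvd/catalog.py` — 46-group catalog (bundled TSV) and invariants
- `src/dietcvd/scoring.py` — quintile-rank APDQS, Keys Score, %-energy
- `src/dietcvd/lipids.py` — Friedewald, non-HDL-C, unit conversion
- `src/dietcvd/simulate.py` — synthetic cohort generator
- `src/dietcvd/prepare.py` — eligibility exclusions, pack-years, change covariates
- `src/dietcvd/exposures.py` — cumulative averages, counting-process rows, quintiles
- `src/dietcvd/coxph.py` — partial likelihood, score/Hessian, Newton solver
- `src/dietcvd/models.py` — lipid-change OLS and Cox wrappers + tests
- `src/dietcvd/reporting.py` — descriptive and contrast tables
- `src/dietcvd/experiments.py` — calibration / parameter-recovery experiments
- `src/dietcvd/pipeline.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for the modeling assumptions, generator
calibration and numerical choices.
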