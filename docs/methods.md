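# Methods

This note documents the statistical models, the synthetic-data
generating mechanism and its calibration, and the numerical choices
made where the design was genuinely open.

## Diet scores

**APDQS.** Each of the 46 food groups carries a fixed rating
(beneficial / adverse / neutral; 20/13/13 in the bundled catalog).  For
a rated group, intakes (servings/day) are ranked against the 20/40/60/
80th empirical percentiles of the analysis sample; a participant's
category is the number of cut points their intake *strictly exceeds*.
Beneficial groups contribute the category (0–4), adverse groups the
reverse (4–0), neutral groups 0; the total spans 0–132.

Two conventions needed fixing where common practice varies:

* *Quintile reference population.*  Cut points are computed within each
  exam separately, because diet distributions drift over 20 years of
  follow-up; `score_cohort` applies this per exam.  (Freezing baseline
  cut points is a one-line change — pass the baseline sample to
  `assign_quintile_points` — but is not the default.)
* *Ties and mass points.*  Ties at a cut point fall in the lower
  category, and coincident cut points (e.g. a 40% mass of
  non-consumers) collapse categories downward.  This makes scoring
  deterministic and order-independent, and guarantees that zero intake
  of a beneficial group always scores 0 and of an adverse group always
  4.  Alcohol groups (beer, wine, liquor) are scored like any other
  beneficial group — no U-shape is imposed; in young-adult samples the
  upper quintile cut-offs sit at light-to-moderate consumption anyway.

**Keys Score** is `1.35·(2·P_sf − P_pufa) + 1.5·√C`.  The radicand is
the dimensionless numeric value of dietary cholesterol density in
mg/1000 kcal; this reproduces the conventional score scale (typical
range ≈ 25–75) and the published quintile ranges.

## Lipid derivations

LDL-C uses Friedewald on the mmol/L scale, `TC − HDL − TG/2.2`
(equivalent to TG/5 in mg/dL), declared missing when TG > 4.52 mmol/L
(≈400 mg/dL, the standard applicability bound) or when the derived
value is negative (surfaced as a warning — a data-quality signal, not
clamped).  Non-HDL-C is `TC − HDL`.  Cholesterol unit conversion uses
the factor 0.0259 mmol/L per mg/dL.

## Eligibility and covariates

Baseline exclusions are applied in a fixed order with first-match
attribution: (1) missing baseline LDL-C; (2) implausible energy intake
— men outside 800–8000 kcal/d, women outside 600–6000 kcal/d, strict
inequalities so exactly 800 kcal/d is retained; (3) prevalent CVD,
diabetes or hypertension, diagnosed *or* treated (OR-combined flag);
(4) any missing baseline covariate from the adjustment set (missing sex
lands here unless an earlier rule fired).  The exclusion log's counts
sum exactly to the rows removed and the filter is idempotent.

Pack-years = packs/day × years smoked.  Change covariates are
follow-up minus baseline for energy, pack-years, physical activity
(exercise units) and BMI; participants missing either exam of a change
period are dropped from that period only.

## Time-varying exposures and the risk table

Each exposure's value on follow-up interval *(s, e]* is the arithmetic
mean of the exam values observed at years ≤ *s* (baseline interval: the
Y0 value).  With exams at years 0/7/20 this gives Y0 on (0,7], mean
(Y0,Y7) on (7,20], mean(Y0,Y7,Y20) on (20,32]; a participant missing
both later exams keeps the Y0 value throughout.  The builder accepts
arbitrary exam schedules, so denser lipid exam lists can feed the
lipid exposures; the generator emits lipids at the diet exams only, so
that is the default.  The schedule is prefix-monotone (a later exam
never changes earlier intervals).

Follow-up is encoded as counting-process rows split at years 7 and 20
and truncated at the first of event, death, or administrative censoring
at 32 years (death is treated as non-informative censoring; no
competing-risks model).  The time-varying adjustment covariates
(energy, pack-years, activity, BMI, lipid-medication use) are
cumulatively averaged with the same three-interval scheme as the
exposures.  The follow-up clock is years since baseline; age enters as
a baseline covariate.

Exposures are analyzed per 1 reference SD (APDQS 13 points, Keys 11,
LDL-C 0.80 mmol/L, non-HDL-C 0.87, %-energy fat 6, %-energy
carbohydrate 7.4) and as quintiles of the cumulatively averaged value
(cut points over the risk-table person-intervals; reference Q1 for
APDQS and the lipids, Q5 for Keys and the %-energy exposures, matching
each score's "unhealthy" end).  Keys and the %-energy exposures are
reported per 1-SD *decrease*, i.e. the reported HR is the reciprocal
direction of the per-increase coefficient.

## Models

**Lipid change.**  OLS of concurrent LDL-C (or non-HDL-C) change on the
per-SD score change, adjusted for baseline lipid, baseline age, sex,
race, education, parental CVD history, energy (baseline and change),
pack-years (baseline and change), activity (baseline and change),
lipid-medication use during the period, and BMI (baseline and change);
complete-case per period with the per-model n reported.  Collinear
designs are rejected with the aliased columns named.

**Hazards.**  The Cox partial likelihood for `(start, stop]` data is
implemented directly with analytic gradient and Hessian.  Risk-set
aggregates are computed by suffix cumulative sums over rows sorted by
start and stop, so an evaluation costs O(n·p²) regardless of the event
count.  Newton iteration starts at 0, uses step-halving on overshoot
(up to 30 halvings; a flat likelihood where no step improves is
accepted as converged), relative log-likelihood tolerance 1e-9, cap 100
iterations, and a tiny ridge if the Hessian is numerically singular.
Breslow tie handling is the default — event times are continuous in the
generator so ties are rare — with Efron available.  Wald confidence
intervals and tests are used throughout, two-sided α = 0.05, no
multiplicity correction.  Quintiles with zero events are reported
non-estimable rather than fitted.

**Trend test** = Wald test of the continuously coded exposure (invariant
to linear rescaling, so identical to the per-SD test).

**Proportional-hazards check** adds an exposure × log(follow-up time)
interaction.  The interaction covariate is evaluated *at each event
time* inside the partial likelihood rather than frozen at a row's own
stop time: using the row's stop time correlates the covariate with
event status and inflates the type-I error, while the exact
construction is correctly sized (verified by null simulation; ≈5%
rejection).

**Interaction tests** add exposure × modifier product terms
(medication use, race, sex, BMI) and report the Wald p.

## The synthetic cohort generator

The generator emulates a CARDIA-like cohort: n = 5115 adults aged 18–30
at baseline, diet history at exam years 0/7/20, fasting lipids at the
same exams, biannual-style covariate updates collapsed to the exam
years, and 32 years of event follow-up.  Mechanism:

1. **Latent plant preference** Z ~ N(0,1) per person, AR(1) across
   exams with correlation 0.6.  (No published within-person tracking
   correlation was available; 0.6 is a typical diet-pattern tracking
   value and is exposed in config.)
2. **Intakes**: per group, a zero-inflated gamma (shape 0.8).  The
   non-consumption probability falls with the group's typical intake
   (floor 0.04 + 0.55·exp(−mean/0.3)) and shifts with ±Z on the logit
   scale; the gamma mean is the catalog's typical servings/day scaled
   by exp(±0.30·Z) — plus for beneficial, minus for adverse, flat for
   neutral groups.
3. **Nutrients**: a standardized adverse-vs-beneficial log-intake
   contrast D drives saturated fat (loading 0.235, SD 3.0 around
   14.3%E), PUFA (−0.17, SD 2.0 around 6.9%E), MUFA, dietary
   cholesterol (0.21, SD 65 around 167 mg/1000 kcal) and energy;
   remainders are independent noise.  Percent energy from carbohydrate
   closes the energy balance; alcohol energy comes from the beer/wine/
   liquor servings.
4. **Lipids**: baseline LDL-C ~ N(2.82, 0.80) mmol/L; HDL-C ~ N(1.38,
   0.33) with a small tilt along −D; TG lognormal (median 0.72,
   log-SD 0.45); TC is assembled as LDL + HDL + TG/2.2 so the
   Friedewald inversion is exact.  Later-exam LDL-C adds a drift
   (0.012 mmol/L/y), the score-change effect γ = −0.05 mmol/L per 13
   APDQS points (the generating value for the change models), a
   −0.8 mmol/L lipid-medication effect, and residual noise (SD 0.45 at
   7 y, 0.65 at 20 y).
5. **Events**: piecewise-exponential hazards over (0,7], (7,20],
   (20,32] driven by the *same* cumulative-average exposure and
   covariate schedules the analysis reconstructs, so parameter-recovery
   experiments fit a correctly specified model.  Default per-1-SD
   effects: APDQS HR 0.73 for CHD and 0.70 for stroke; the Keys and
   LDL-C hazard effects default to zero (each recovery experiment turns
   on only the effect under test, since simultaneous effects on
   correlated exposures would leave no single "generating value" for a
   single-exposure model).  Covariate log-hazards (age, sex, race,
   smoking, BMI, activity, education, parental history, medication) are
   modest, plausible values and are all in the fitted adjustment set.
   Baseline rates rise over follow-up (CHD 1.5/5.7/14.5 per 10⁴
   person-years across the three intervals; stroke 1.0/3.85/9.6) and
   death is an independent 3/10³ per year censoring process.
6. **Attrition**: exam attendance 0.75 (Y7) and 0.62 (Y20),
   missing-at-random; 5.5% carry a prevalent-condition flag and 1.2% a
   missing baseline covariate, so the eligibility filter removes ≈8%.

**Calibration.**  The latent-factor loading, nutrient couplings and
baseline rates were calibrated once, by simulation on a handful of
seeds, to the published cohort's anchors: baseline APDQS ≈ 62.7 ± 13.0
and Keys ≈ 48.0 ± 10.5 (the generator gives ≈66 ± 12.9 and
≈48.2 ± 9.7 — the mean sits high because quintile scoring with ties
centers near 2 points/group, but all moments are within 10%), APDQS–
Keys correlation ≈ −0.31, LDL-C ≈ 2.82 ± 0.80 mmol/L, and ≈116 CHD /
≈80 stroke events per ≈4700 eligible participants over 32 years.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: recruitment design and center
effects, differential (informative) attrition, measurement error in
the diet history, seasonal/secular diet trends, interim lipid exams,
correlated competing risks, and any true U-shaped alcohol effect.
Recovery experiments demonstrate that the estimators are correct under
the stated model, not that the model is correct for any real cohort.

## Reported experiment sizes

The bundled experiments use 20 replicates of n = 5000 for the
correlation calibration and 200 replicates for each recovery
experiment (n = 5000 for the hazard models under rare-event rates,
n = 2824 with full attendance for the 20-year lipid-change model) —
enough for Monte-Carlo standard errors of ≈0.007 on a hazard ratio
near 0.73 and ≈0.0007 on the change slope.  Null-calibration checks
(type-I error of the PH and interaction tests) use 150 replicates of
compact piecewise-exponential cohorts with amplified event rates.

## Known limitations

* Quintile labels in the hazard models are assigned per person-interval
  over the risk table, weighting participants by intervals rather than
  person-time; the published tables' exact weighting is not documented.
* The exclusion cascade's rule order is a convention; sources rarely
  state one, so per-rule counts (not the remaining n) depend on it.
* With very small cohorts (a few events), the 14-parameter quintile
  model is unidentifiable; the solver reports flat-likelihood
  convergence with huge standard errors, and smoke configurations
  should amplify baseline rates instead.
* No multiple imputation, survey weights, penalized fitting, or
  Fine–Gray competing-risks models.
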