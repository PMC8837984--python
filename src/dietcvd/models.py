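"""Association models: linear lipid-change regressions and time-varying
proportional-hazards models of CHD and stroke.

Two model families mirror the analysis design:

* OLS of concurrent lipid change (LDL-C or non-HDL-C, mmol/L) on diet
  score change per reference SD, adjusted for baseline lipid, baseline
  age, sex, race, education, parental CVD history, energy (baseline and
  change), smoking pack-years (baseline and change), physical activity
  (baseline and change), lipid-lowering medication, and BMI (baseline
  and change).
* Cox proportional hazards on counting-process risk intervals with the
  cumulative-average exposure coded continuously (per reference SD) and
  as quintiles, adjusted for baseline age/sex/race/education/parental
  history and cumulatively averaged time-varying energy, pack-years,
  activity, medication use, and BMI.  Wald tests throughout; the trend
  test is the Wald test of the continuous coding; the proportional-
  hazards check adds an exposure x log(follow-up time) interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .coxph import CoxFit, CoxPartialLikelihood
from .exposures import (
    build_counting_process,
    cumulative_average_exposure,
    exam_matrix,
    per_sd,
    quintile_categorize,
)
from .simulate import INTERVAL_BOUNDARIES

#: signed reference SDs for per-1-SD reporting (Keys Score and the
#: %-energy messages are reported per 1-SD *decrease*)
SIGNED_REFERENCE_SD = {
    "apdqs": 13.0,
    "keys_score": -11.0,
    "ldl_c": 0.80,
    "non_hdl_c": 0.87,
    "pct_energy_fat": -6.0,
    "pct_energy_carbohydrate": -7.4,
}

#: reference quintile per exposure (the table orientation: lowest quintile
#: for APDQS and the lipids, highest for Keys and the %-energy exposures)
REFERENCE_QUINTILE = {
    "apdqs": "Q1",
    "keys_score": "Q5",
    "ldl_c": "Q1",
    "non_hdl_c": "Q1",
    "pct_energy_fat": "Q5",
    "pct_energy_carbohydrate": "Q5",
}

#: adjustment covariates for the hazards models: baseline + cumulative-
#: average time-varying (the risk table carries them under these names)
DEFAULT_COX_ADJUSTMENT = (
    "age",
    "female",
    "black",
    "education",
    "parental_cvd",
    "energy_kcal_d",
    "pack_years",
    "physical_activity",
    "lipid_med",
    "bmi",
)


@dataclass
class LinearChangeResult:
    outcome: str
    score: str
    period: str
    beta: float
    se: float
    p: float
    n: int
    covariates: list

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "score": self.score,
            "period": self.period,
            "beta_per_sd": self.beta,
            "se": self.se,
            "p": self.p,
            "n": self.n,
        }


@dataclass
class EffectTable:
    outcome: str
    exposure: str
    per_sd_hr: float
    per_sd_ci: tuple
    per_sd_p: float
    trend_p: float | None = None
    quintile_hr: dict = field(default_factory=dict)   # label -> (hr, lo, hi) or None
    quintile_events: dict = field(default_factory=dict)  # label -> (events, n)
    quintile_cuts: np.ndarray | None = None
    reference: str | None = None
    ph_p: float | None = None
    n_events: int = 0
    fit: CoxFit | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for q in sorted(self.quintile_hr):
            hr = self.quintile_hr[q]
            ev = self.quintile_events.get(q, (np.nan, np.nan))
            if q == self.reference:
                rows.append((q, 1.0, np.nan, np.nan, *ev))
            elif hr is None:
                rows.append((q, np.nan, np.nan, np.nan, *ev))
            else:
                rows.append((q, *hr, *ev))
        df = pd.DataFrame(
            rows, columns=["quintile", "hr", "ci_low", "ci_high", "events", "n"]
        )
        df.attrs["per_sd"] = (self.per_sd_hr, *self.per_sd_ci, self.per_sd_p)
        return df


# --------------------------------------------------------------------------
# dataset assembly
# --------------------------------------------------------------------------

def build_risk_table(
    exposure_exams: pd.DataFrame,
    events: pd.DataFrame,
    outcome: str,
    covariates_tv: pd.DataFrame,
    baseline: pd.DataFrame,
    exposure_name: str = "exposure",
    exam_years=(0, 7, 20),
    boundaries=INTERVAL_BOUNDARIES,
) -> pd.DataFrame:
    """Assemble the counting-process table for one exposure and outcome.

    ``exposure_exams`` is a participants x exam-years frame of exposure
    values (as from :func:`dietcvd.exposures.exam_matrix`); time-varying
    adjustment covariates are cumulatively averaged with the same
    three-interval scheme as the exposure.
    """
    ids = exposure_exams.index
    schedules = {
        exposure_name: cumulative_average_exposure(
            exposure_exams, exam_years, boundaries
        )
    }
    for cov in ("energy_kcal_d", "pack_years", "physical_activity", "bmi", "lipid_med"):
        if cov in covariates_tv.columns:
            mat = exam_matrix(covariates_tv, cov, exam_years).reindex(ids)
            schedules[cov] = cumulative_average_exposure(mat, exam_years, boundaries)
    bl_cols = [
        c
        for c in ("participant_id", "age", "female", "black", "education", "parental_cvd")
        if c in baseline.columns
    ]
    ev = events[events["participant_id"].isin(ids)]
    return build_counting_process(
        schedules, ev, outcome, boundaries, baseline=baseline[bl_cols]
    )


def build_change_dataset(
    scores: pd.DataFrame,
    lipids_derived: pd.DataFrame,
    covariates_tv: pd.DataFrame,
    baseline: pd.DataFrame,
    baseline_exam: float,
    followup_exam: float,
) -> pd.DataFrame:
    """Complete-case dataset for one lipid-change period.

    Joins score changes (per reference SD), lipid changes (mmol/L), and
    the baseline+change adjustment covariates for participants with both
    exams observed.
    """
    from .prepare import build_change_covariates

    sc_b = scores[scores["exam"] == baseline_exam].set_index("participant_id")
    sc_f = scores[scores["exam"] == followup_exam].set_index("participant_id")
    lp_b = lipids_derived[lipids_derived["exam"] == baseline_exam].set_index(
        "participant_id"
    )
    lp_f = lipids_derived[lipids_derived["exam"] == followup_exam].set_index(
        "participant_id"
    )
    chg = build_change_covariates(covariates_tv, baseline_exam, followup_exam)
    ids = (
        sc_b.index.intersection(sc_f.index)
        .intersection(lp_b.index)
        .intersection(lp_f.index)
        .intersection(pd.Index(chg["participant_id"]))
    )
    out = pd.DataFrame({"participant_id": ids})
    for score in ("apdqs", "keys_score"):
        delta = sc_f.loc[ids, score].to_numpy() - sc_b.loc[ids, score].to_numpy()
        out[f"d_{score}_sd"] = per_sd(delta, score)
    for lipid in ("ldl_c", "non_hdl_c"):
        out[f"d_{lipid}"] = lp_f.loc[ids, lipid].to_numpy() - lp_b.loc[ids, lipid].to_numpy()
        out[f"{lipid}_baseline"] = lp_b.loc[ids, lipid].to_numpy()
    out = out.merge(chg, on="participant_id", how="left")
    bl = baseline[
        ["participant_id", "age", "female", "black", "education", "parental_cvd"]
    ]
    out = out.merge(bl, on="participant_id", how="left")
    out["period"] = f"{int(followup_exam - baseline_exam)}-year"
    return out.dropna().reset_index(drop=True)


# --------------------------------------------------------------------------
# linear lipid-change models
# --------------------------------------------------------------------------

def fit_lipid_change_model(
    data: pd.DataFrame,
    score: str = "apdqs",
    outcome: str = "ldl_c",
    period: str = "",
) -> LinearChangeResult:
    """OLS of concurrent lipid change on per-SD score change.

    ``data`` comes from :func:`build_change_dataset`; the coefficient is
    in mmol/L per 1 reference SD of score change.
    """
    ycol = f"d_{outcome}"
    xcol = f"d_{score}_sd"
    covariates = [
        f"{outcome}_baseline",
        "age",
        "female",
        "black",
        "education",
        "parental_cvd",
        "energy_kcal_d_baseline",
        "energy_kcal_d_change",
        "pack_years_baseline",
        "pack_years_change",
        "physical_activity_baseline",
        "physical_activity_change",
        "lipid_med",
        "bmi_baseline",
        "bmi_change",
    ]
    cols = [ycol, xcol] + [c for c in covariates if c in data.columns]
    cc = data[cols].dropna()
    n = len(cc)
    if n < len(cols) + 2:
        raise ValueError(f"too few complete cases ({n}) for {len(cols)} parameters")
    X = sm.add_constant(cc[cols[1:]], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # name the aliased columns via near-zero pivots of a QR decomposition
        r = np.abs(np.diag(np.linalg.qr(X.to_numpy(), mode="r")))
        aliased = [c for c, d in zip(X.columns, r) if d < 1e-8 * r.max()]
        raise ValueError(f"collinear design matrix in lipid-change model: {aliased}")
    res = sm.OLS(cc[ycol], X).fit()
    return LinearChangeResult(
        outcome=outcome,
        score=score,
        period=period,
        beta=float(res.params[xcol]),
        se=float(res.bse[xcol]),
        p=float(res.pvalues[xcol]),
        n=n,
        covariates=cols[2:],
    )


# --------------------------------------------------------------------------
# time-varying Cox models
# --------------------------------------------------------------------------

def _design(risk: pd.DataFrame, cols) -> tuple[np.ndarray, list]:
    use = [c for c in cols if c in risk.columns]
    X = risk[use].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [c for c in use if risk[c].isna().any()]
        raise ValueError(f"missing values in Cox design columns: {bad}")
    return X, use

def _signed_sd(exposure: str, sd: float | None):
    if sd is not None:
        return sd
    if exposure in SIGNED_REFERENCE_SD:
        return SIGNED_REFERENCE_SD[exposure]
    raise ValueError(f"no reference SD registered for exposure {exposure!r}; pass sd=")


def fit_cox_timevarying(
    risk: pd.DataFrame,
    exposure: str,
    adjustment=DEFAULT_COX_ADJUSTMENT,
    extra_exposures=(),
    sd: float | None = None,
    ties: str = "breslow",
    coding: str = "both",
    with_trend: bool = True,
) -> EffectTable:
    """Fit the adjusted time-varying Cox model for one exposure.

    ``coding="continuous"`` fits only the per-SD model, ``"quintile"``
    only the quintile-indicator model, ``"both"`` (default) fits both and
    reports the per-SD estimate alongside per-quintile HRs vs the
    reference quintile.  ``extra_exposures`` adds further per-SD-coded
    exposure columns for mutual adjustment (e.g. the other diet score or
    a lipid).  The trend p is the Wald p of the continuous coding.
    """
    sd_signed = _signed_sd(exposure, sd)
    start = risk["start"].to_numpy(float)
    stop = risk["stop"].to_numpy(float)
    event = risk["event"].to_numpy(int)
    Xadj, adj_names = _design(risk, adjustment)

    extra_cols = []
    for name in extra_exposures:
        v = per_sd(risk[name].to_numpy(float), sd=abs(_signed_sd(name, None)))
        extra_cols.append((f"{name}_sd", v))

    result = EffectTable(
        outcome=str(risk.attrs.get("outcome", "")),
        exposure=exposure,
        per_sd_hr=np.nan,
        per_sd_ci=(np.nan, np.nan),
        per_sd_p=np.nan,
    )

    if coding in ("continuous", "both"):
        xsd = per_sd(risk[exposure].to_numpy(float), sd=abs(sd_signed))
        X = np.column_stack([xsd, *(v for _, v in extra_cols), Xadj])
        names = [f"{exposure}_sd", *(n for n, _ in extra_cols), *adj_names]
        fit = CoxPartialLikelihood(start, stop, event, X, ties=ties).fit(names=names)
        sign = np.sign(sd_signed)
        beta = sign * fit.params[0]
        se = fit.se[0]
        result.per_sd_hr = float(np.exp(beta))
        result.per_sd_ci = (
            float(np.exp(beta - 1.96 * se)),
            float(np.exp(beta + 1.96 * se)),
        )
        result.per_sd_p = float(fit.wald_p()[0])
        result.n_events = fit.n_events
        result.fit = fit
        if with_trend:
            result.trend_p = result.per_sd_p

    if coding in ("quintile", "both"):
        labels, cuts = quintile_categorize(risk[exposure])
        ref = REFERENCE_QUINTILE.get(exposure, "Q1")
        qlabels = [f"Q{i}" for i in range(1, 6)]
        dummies = []
        dummy_names = []
        for q in qlabels:
            if q == ref:
                continue
            dummies.append((np.asarray(labels) == q).astype(float))
            dummy_names.append(q)
        # events and row counts per quintile (participants on their final row)
        for q in qlabels:
            mask = np.asarray(labels) == q
            result.quintile_events[q] = (
                int(event[mask].sum()),
                int(risk.loc[mask, "participant_id"].nunique()),
            )
        estimable = [i for i, q in enumerate(dummy_names) if event[dummies[i] == 1].sum() > 0]
        Xq = np.column_stack([*(dummies[i] for i in estimable), *(v for _, v in extra_cols), Xadj])
        names = [dummy_names[i] for i in estimable] + [n for n, _ in extra_cols] + adj_names
        fitq = CoxPartialLikelihood(start, stop, event, Xq, ties=ties).fit(names=names)
        lo, hi = fitq.confint()
        result.quintile_cuts = cuts
        result.reference = ref
        result.quintile_hr[ref] = None
        for q in dummy_names:
            if q in names:
                i = names.index(q)
                result.quintile_hr[q] = (
                    float(fitq.hazard_ratios()[i]),
                    float(lo[i]),
                    float(hi[i]),
                )
            else:
                result.quintile_hr[q] = None  # no events: non-estimable
        result.quintile_hr[ref] = None
    return result


def trend_test(
    risk: pd.DataFrame,
    exposure: str,
    adjustment=DEFAULT_COX_ADJUSTMENT,
    sd: float | None = None,
    ties: str = "breslow",
) -> float:
    """Wald p-value for the continuous exposure in the adjusted model."""
    et = fit_cox_timevarying(
        risk, exposure, adjustment, sd=sd, ties=ties, coding="continuous"
    )
    return et.per_sd_p


def ph_assumption_check(
    risk: pd.DataFrame,
    exposure: str,
    adjustment=DEFAULT_COX_ADJUSTMENT,
    sd: float | None = None,
) -> float:
    """Proportional-hazards check: Wald p for exposure x log(time).

    The interaction covariate is evaluated at each event time inside the
    partial likelihood; p > 0.05 is read as consistent with proportional
    hazards.
    """
    sd_signed = _signed_sd(exposure, sd)
    xsd = per_sd(risk[exposure].to_numpy(float), sd=abs(sd_signed))
    if np.ptp(xsd) == 0:
        raise ValueError("exposure constant across rows; interaction inestimable")
    Xadj, adj_names = _design(risk, adjustment)
    X = np.column_stack([xsd, Xadj])
    pl = CoxPartialLikelihood(
        risk["start"].to_numpy(float),
        risk["stop"].to_numpy(float),
        risk["event"].to_numpy(int),
        X,
        ties="breslow",
        log_time_idx=0,
    )
    fit = pl.fit(names=[f"{exposure}_sd", *adj_names])
    return float(fit.wald_p()[-1])


def interaction_wald(
    risk: pd.DataFrame,
    exposure: str,
    modifier: str,
    adjustment=DEFAULT_COX_ADJUSTMENT,
    sd: float | None = None,
    ties: str = "breslow",
) -> float:
    """Wald p for the exposure x modifier product term in the adjusted model."""
    if modifier == exposure:
        raise ValueError("modifier must differ from the exposure")
    if modifier not in risk.columns:
        raise KeyError(f"modifier column {modifier!r} not in risk table")
    mod = risk[modifier].to_numpy(float)
    if np.ptp(mod) == 0:
        raise ValueError(f"modifier {modifier!r} is constant; interaction inestimable")
    sd_signed = _signed_sd(exposure, sd)
    xsd = per_sd(risk[exposure].to_numpy(float), sd=abs(sd_signed))
    adj = [c for c in adjustment if c != modifier]
    Xadj, adj_names = _design(risk, adj)
    X = np.column_stack([xsd, mod, xsd * mod, Xadj])
    names = [f"{exposure}_sd", modifier, f"{exposure}_sd:{modifier}", *adj_names]
    fit = CoxPartialLikelihood(
        risk["start"].to_numpy(float),
        risk["stop"].to_numpy(float),
        risk["event"].to_numpy(int),
        X,
        ties=ties,
    ).fit(names=names)
    return float(fit.wald_p()[2])
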