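"""Eligibility filtering and derived covariates.

Exclusions at baseline (applied in order, each participant attributed to
the first failing rule):

1. missing baseline LDL-C;
2. implausible energy intake (men outside 800-8000 kcal/d, women outside
   600-6000 kcal/d, strict inequalities);
3. prevalent CVD, diabetes or hypertension, or treatment for those
   conditions, at baseline;
4. missing baseline covariates from the adjustment set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ENERGY_BOUNDS = {"male": (800.0, 8000.0), "female": (600.0, 6000.0)}

EXCLUSION_RULES = (
    "missing_y0_ldl",
    "implausible_energy",
    "prevalent_condition",
    "missing_covariates",
)

#: baseline covariates that must be complete (the adjustment set)
REQUIRED_COVARIATES = (
    "age",
    "female",
    "black",
    "education",
    "parental_cvd",
    "pack_years",
    "physical_activity",
    "bmi",
)


@dataclass
class ExclusionLog:
    initial_n: int
    removed: dict = field(default_factory=lambda: {r: 0 for r in EXCLUSION_RULES})

    @property
    def remaining_n(self) -> int:
        return self.initial_n - sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("initial", self.initial_n)]
        rows += [(rule, self.removed[rule]) for rule in EXCLUSION_RULES]
        rows.append(("remaining", self.remaining_n))
        return pd.DataFrame(rows, columns=["rule", "n"])

    def __str__(self) -> str:
        lines = [f"initial n = {self.initial_n}"]
        for rule in EXCLUSION_RULES:
            lines.append(f"  removed ({rule.replace('_', ' ')}): {self.removed[rule]}")
        lines.append(f"remaining n = {self.remaining_n}")
        return "\n".join(lines)


def pack_years(packs_per_day, years_smoked):
    """Smoking dose: packs of cigarettes per day times years smoked."""
    p = np.asarray(packs_per_day, dtype=float)
    y = np.asarray(years_smoked, dtype=float)
    if np.any(p[~np.isnan(p)] < 0) or np.any(y[~np.isnan(y)] < 0):
        raise ValueError("packs_per_day and years_smoked must be >= 0")
    out = p * y
    return float(out) if out.ndim == 0 else out


def _energy_ok(energy, female) -> np.ndarray:
    lo_m, hi_m = ENERGY_BOUNDS["male"]
    lo_f, hi_f = ENERGY_BOUNDS["female"]
    lo = np.where(female == 1, lo_f, lo_m)
    hi = np.where(female == 1, hi_f, hi_m)
    # strict bounds: exactly 800 kcal/d (men) is retained, 799 excluded
    return (energy >= lo) & (energy <= hi) & ~np.isnan(energy)


def apply_exclusions(
    baseline: pd.DataFrame,
    y0_ldl: pd.Series,
    y0_energy: pd.Series,
    required_covariates=REQUIRED_COVARIATES,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Filter the baseline table to the analysis sample.

    Parameters
    ----------
    baseline
        One row per participant with ``participant_id``, the covariates in
        ``required_covariates``, and a ``prevalent_condition`` 0/1 flag
        (diagnosed-or-treated CVD/diabetes/hypertension, OR-combined).
    y0_ldl, y0_energy
        Baseline LDL-C (mmol/L) and energy intake (kcal/d), indexed by
        participant id.

    Returns the retained rows and an :class:`ExclusionLog`; the log counts
    attribute each removal to the first failing rule, and counts sum
    exactly to rows removed.  Missing sex is treated as a missing
    covariate (rule 4) unless an earlier rule already fired.
    """
    log = ExclusionLog(initial_n=len(baseline))
    if len(baseline) == 0:
        return baseline.copy(), log
    df = baseline.set_index("participant_id", drop=False)
    ldl = y0_ldl.reindex(df.index)
    energy = y0_energy.reindex(df.index)
    female = df["female"] if "female" in df else pd.Series(np.nan, index=df.index)

    fail_ldl = ldl.isna().to_numpy()
    sex_known = ~female.isna().to_numpy()
    fail_energy = ~_energy_ok(energy.to_numpy(dtype=float), female.to_numpy()) & sex_known
    fail_prev = df.get("prevalent_condition", pd.Series(0, index=df.index)).fillna(0).to_numpy() == 1
    cov_missing = ~sex_known
    for c in required_covariates:
        if c == "female":
            continue
        if c not in df.columns:
            cov_missing |= True
        else:
            cov_missing |= df[c].isna().to_numpy()

    rule_matrix = np.stack([fail_ldl, fail_energy, fail_prev, cov_missing])
    first_rule = np.full(len(df), -1)
    for r in range(rule_matrix.shape[0]):
        first_rule[(first_rule == -1) & rule_matrix[r]] = r
    for r, rule in enumerate(EXCLUSION_RULES):
        log.removed[rule] = int((first_rule == r).sum())
    keep = first_rule == -1
    return baseline.iloc[np.flatnonzero(keep)].reset_index(drop=True), log


#: covariates carried as baseline + change in the lipid-change models
CHANGE_COVARIATES = ("energy_kcal_d", "pack_years", "physical_activity", "bmi")


def build_change_covariates(
    tv: pd.DataFrame,
    baseline_exam: float,
    followup_exam: float,
    covariates=CHANGE_COVARIATES,
) -> pd.DataFrame:
    """Baseline and change values of the time-varying covariates for one
    change period (e.g. Y0 -> Y20 for the 20-year change analysis).

    ``tv`` is the long participant/exam covariate table.  Participants
    missing either exam are dropped (complete-case per period).  Returns
    one row per retained participant with ``<c>_baseline`` and
    ``<c>_change`` columns plus the period's ``lipid_med`` flag at
    follow-up (time-varying medication use).
    """
    need = {"participant_id", "exam", *covariates}
    missing = need - set(tv.columns)
    if missing:
        raise KeyError(f"covariate table missing columns: {sorted(missing)}")
    base = tv[tv["exam"] == baseline_exam].set_index("participant_id")
    fup = tv[tv["exam"] == followup_exam].set_index("participant_id")
    ids = base.index.intersection(fup.index)
    out = pd.DataFrame({"participant_id": ids})
    for c in covariates:
        out[f"{c}_baseline"] = base.loc[ids, c].to_numpy()
        out[f"{c}_change"] = fup.loc[ids, c].to_numpy() - base.loc[ids, c].to_numpy()
    if "lipid_med" in tv.columns:
        out["lipid_med"] = (
            base.loc[ids, "lipid_med"].to_numpy() + fup.loc[ids, "lipid_med"].to_numpy()
            > 0
        ).astype(int)
    out["period_years"] = float(followup_exam - baseline_exam)
    return out
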