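"""Association models: OLS oracle, Cox wrappers, trend/PH/interaction tests."""

import numpy as np
import pandas as pd
import pytest

from dietcvd.models import (
    build_change_dataset,
    fit_cox_timevarying,
    fit_lipid_change_model,
    interaction_wald,
    ph_assumption_check,
    trend_test,
)
from dietcvd.pipeline import risk_table_for


@pytest.fixture(scope="module")
def chd_risk(small_cohort, small_analysis):
    risk = risk_table_for(
        small_cohort,
        small_analysis["scores"],
        small_analysis["lipids"],
        small_analysis["ids"],
        "apdqs",
        "chd",
    )
    return risk


class TestLipidChange:
    def test_matches_normal_equations_oracle(self):
        """Coefficient equals the closed-form least-squares solution on a
        30-row fixture."""
        rng = np.random.default_rng(8)
        n = 30
        data = pd.DataFrame(
            {
                "d_ldl_c": rng.normal(size=n),
                "d_apdqs_sd": rng.normal(size=n),
                "ldl_c_baseline": rng.normal(2.8, 0.8, n),
                "age": rng.uniform(18, 30, n),
                "female": rng.integers(0, 2, n).astype(float),
            }
        )
        res = fit_lipid_change_model(data, "apdqs", "ldl_c", "toy")
        X = np.column_stack(
            [np.ones(n), data["d_apdqs_sd"], data["ldl_c_baseline"], data["age"], data["female"]]
        )
        beta_hat = np.linalg.solve(X.T @ X, X.T @ data["d_ldl_c"].to_numpy())
        assert res.beta == pytest.approx(beta_hat[1], rel=1e-9)
        resid = data["d_ldl_c"].to_numpy() - X @ beta_hat
        sigma2 = resid @ resid / (n - X.shape[1])
        se_hat = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.se == pytest.approx(se_hat, rel=1e-9)

    def test_null_slope_unbiased(self):
        """With gamma_score = 0 the recovered slope is centred at 0 and the
        two-sided test rejects at ~5%."""
        from dietcvd.lipids import derive_lipid_panel
        from dietcvd.pipeline import score_cohort
        from dietcvd.simulate import SimulationConfig, simulate_cohort

        betas, pvals = [], []
        for seed in range(30):
            cfg = SimulationConfig(
                n_participants=400, seed=1000 + seed, gamma_score=0.0,
                p_attend_y7=1.0, p_attend_y20=1.0,
                p_prevalent_condition=0.0, p_missing_covariate=0.0,
            )
            c = simulate_cohort(cfg)
            scores = score_cohort(c.intakes, c.nutrients)
            lip = derive_lipid_panel(c.lipids)
            data = build_change_dataset(scores, lip, c.covariates_tv, c.baseline, 0.0, 20.0)
            r = fit_lipid_change_model(data, "apdqs", "ldl_c", "20-year")
            betas.append(r.beta)
            pvals.append(r.p)
        se = np.std(betas) / np.sqrt(len(betas))
        assert abs(np.mean(betas)) < 3 * se + 1e-4
        assert np.mean(np.asarray(pvals) < 0.05) < 0.25

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(9)
        n = 30
        data = pd.DataFrame(
            {
                "d_ldl_c": rng.normal(size=n),
                "d_apdqs_sd": rng.normal(size=n),
                "ldl_c_baseline": np.ones(n),   # aliased with the intercept
                "age": rng.uniform(18, 30, n),
                "female": rng.integers(0, 2, n).astype(float),
            }
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_lipid_change_model(data, "apdqs", "ldl_c", "toy")

    def test_too_few_rows_rejected(self):
        data = pd.DataFrame(
            {"d_ldl_c": [0.1, 0.2], "d_apdqs_sd": [0.0, 1.0], "ldl_c_baseline": [2.5, 3.0],
             "age": [22.0, 25.0], "female": [0.0, 1.0]}
        )
        with pytest.raises(ValueError, match="complete cases"):
            fit_lipid_change_model(data, "apdqs", "ldl_c", "toy")


class TestCoxWrappers:
    def test_effect_table_shape(self, chd_risk):
        et = fit_cox_timevarying(chd_risk, "apdqs")
        assert et.reference == "Q1"
        assert et.quintile_hr["Q1"] is None  # reference cell
        frame = et.to_frame()
        assert set(frame["quintile"]) == {"Q1", "Q2", "Q3", "Q4", "Q5"}
        assert frame.loc[frame["quintile"] == "Q1", "hr"].item() == 1.0
        # CI brackets the estimate and reproduces exp(beta +/- 1.96 se)
        lo, hi = et.per_sd_ci
        assert lo < et.per_sd_hr < hi
        fit = et.fit
        np.testing.assert_allclose(
            [lo, hi],
            [np.exp(fit.params[0] - 1.96 * fit.se[0]), np.exp(fit.params[0] + 1.96 * fit.se[0])],
        )
        # per-quintile participant counts cover the analysis sample
        n_total = sum(n for _, n in et.quintile_events.values())
        assert n_total >= chd_risk["participant_id"].nunique()

    def test_trend_equals_per_sd_test(self, chd_risk):
        """The trend test is the Wald test of the continuous coding, which is
        invariant to linear rescaling of the exposure."""
        p1 = trend_test(chd_risk, "apdqs")
        p2 = fit_cox_timevarying(chd_risk, "apdqs", sd=1.0, coding="continuous").per_sd_p
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_mutual_adjustment_runs(self, small_cohort, small_analysis):
        risk = risk_table_for(
            small_cohort, small_analysis["scores"], small_analysis["lipids"],
            small_analysis["ids"], "apdqs", "chd",
        )
        # attach the Keys schedule for mutual adjustment
        risk_keys = risk_table_for(
            small_cohort, small_analysis["scores"], small_analysis["lipids"],
            small_analysis["ids"], "keys_score", "chd",
        )
        risk = risk.merge(
            risk_keys[["participant_id", "start", "keys_score"]],
            on=["participant_id", "start"],
        )
        et = fit_cox_timevarying(risk, "apdqs", extra_exposures=("keys_score",),
                                 coding="continuous")
        assert "keys_score_sd" in et.fit.names
        assert np.isfinite(et.per_sd_hr)

    def test_keys_sign_convention(self, small_cohort, small_analysis):
        """Keys effects are reported per 1-SD decrease: the reported HR is the
        reciprocal direction of the raw per-11-point-increase HR."""
        risk = risk_table_for(
            small_cohort, small_analysis["scores"], small_analysis["lipids"],
            small_analysis["ids"], "keys_score", "chd",
        )
        et_signed = fit_cox_timevarying(risk, "keys_score", coding="continuous")
        et_raw = fit_cox_timevarying(risk, "keys_score", sd=11.0, coding="continuous")
        assert et_signed.per_sd_hr == pytest.approx(1.0 / et_raw.per_sd_hr, rel=1e-9)


class TestPhCheck:
    def test_constant_exposure_flagged(self, chd_risk):
        risk = chd_risk.copy()
        risk["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            ph_assumption_check(risk, "flat", sd=1.0)

    def test_ph_data_gives_large_p_typically(self, chd_risk):
        p = ph_assumption_check(chd_risk, "apdqs")
        assert 0.0 <= p <= 1.0


class TestInteraction:
    def test_guards(self, chd_risk):
        with pytest.raises(ValueError, match="differ"):
            interaction_wald(chd_risk, "apdqs", "apdqs")
        risk = chd_risk.copy()
        risk["flat"] = 2.0
        with pytest.raises(ValueError, match="constant"):
            interaction_wald(risk, "apdqs", "flat")
        with pytest.raises(KeyError):
            interaction_wald(chd_risk, "apdqs", "not_a_column")

    def test_sex_interaction_p_valid(self, chd_risk):
        p = interaction_wald(chd_risk, "apdqs", "female")
        assert 0.0 <= p <= 1.0
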