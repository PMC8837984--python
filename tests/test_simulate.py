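"""Synthetic cohort generator: reproducibility, structure, null behavior."""

import numpy as np
import pandas as pd
import pytest

from dietcvd.simulate import (
    HazardModel,
    SimulationConfig,
    simulate_cohort,
    simulate_event_times,
)


class TestReproducibility:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(n_participants=200, seed=123)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for name, df in a.tables().items():
            pd.testing.assert_frame_equal(df, b.tables()[name])

    def test_different_seed_differs(self):
        a = simulate_cohort(SimulationConfig(n_participants=200, seed=1))
        b = simulate_cohort(SimulationConfig(n_participants=200, seed=2))
        assert not a.intakes.equals(b.intakes)

    def test_seed_recorded_in_truth(self):
        c = simulate_cohort(SimulationConfig(n_participants=50, seed=77))
        assert c.truth["seed"] == 77


class TestStructure:
    def test_every_participant_has_baseline(self, small_cohort):
        n = len(small_cohort.baseline)
        y0 = small_cohort.intakes[small_cohort.intakes["exam"] == 0]
        assert len(y0) == n
        assert small_cohort.events["participant_id"].nunique() == n

    def test_event_times_in_range(self, small_cohort):
        ev = small_cohort.events
        for oc in ("chd", "stroke"):
            t = ev[f"{oc}_time"]
            assert ((t > 0) & (t <= 32.0)).all()
            # flags only 0/1 and at most one first event per outcome
            assert ev[f"{oc}_event"].isin([0, 1]).all()

    def test_intakes_nonnegative(self, small_cohort):
        groups = [c for c in small_cohort.intakes.columns if c not in ("participant_id", "exam")]
        assert (small_cohort.intakes[groups] >= 0).all().all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_participants=3)
        with pytest.raises(ValueError):
            SimulationConfig(p_attend_y7=1.4)
        with pytest.raises(ValueError):
            SimulationConfig(hazard=HazardModel(death_rate=-0.1))


class TestEventTimeSampler:
    def test_zero_hazard_never_fires(self):
        rng = np.random.default_rng(0)
        t = simulate_event_times(rng, np.zeros((500, 3)))
        assert np.isinf(t).all()

    def test_truncated_exponential_mean(self):
        """Single segment, rate 0.01/y: mean event time among events matches
        the truncated-exponential closed form."""
        rng = np.random.default_rng(1)
        lam = 0.01
        t = simulate_event_times(rng, np.full((200_000, 1), lam), boundaries=(0.0, 32.0))
        events = t[np.isfinite(t)]
        expected = 1 / lam - 32.0 * np.exp(-32.0 * lam) / (1 - np.exp(-32.0 * lam))
        assert events.mean() == pytest.approx(expected, rel=0.02)
        # and the event fraction matches 1 - exp(-32 lam)
        frac = np.isfinite(t).mean()
        assert frac == pytest.approx(1 - np.exp(-32 * lam), abs=0.005)

    def test_rare_event_rate_doubling(self):
        rng = np.random.default_rng(2)
        base = np.full((100_000, 3), 2e-4) * np.array([1.0, 2.0, 3.0])
        n1 = np.isfinite(simulate_event_times(rng, base)).sum()
        n2 = np.isfinite(simulate_event_times(rng, 2 * base)).sum()
        assert n2 / n1 == pytest.approx(2.0, rel=0.1)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_event_times(np.random.default_rng(0), np.array([[-1e-4, 0, 0]]))


class TestNullGenerator:
    def test_no_coupling_no_effects(self):
        """With all couplings and hazard effects off, the two scores are
        uncorrelated and the fitted diet HR is near 1."""
        hz = HazardModel(
            log_hr_apdqs_chd=0.0,
            log_hr_apdqs_stroke=0.0,
            base_rates_chd=(2e-3, 2e-3, 2e-3),  # more events for a stable fit
            log_hr_age_per_y=0.0,
            log_hr_female=0.0,
            log_hr_black=0.0,
            log_hr_pack_years_per_10=0.0,
            log_hr_bmi_per_unit=0.0,
            log_hr_activity_per_100eu=0.0,
            log_hr_education_per_grade=0.0,
            log_hr_parental_cvd=0.0,
            log_hr_lipid_med=0.0,
        )
        cfg = SimulationConfig(
            n_participants=3000,
            seed=5,
            loading=0.0,
            zero_loading=0.0,
            sfa_coupling=0.0,
            pufa_coupling=0.0,
            chol_coupling=0.0,
            mufa_coupling=0.0,
            energy_coupling=0.0,
            gamma_score=0.0,
            hazard=hz,
        )
        c = simulate_cohort(cfg)
        s0 = c.scores[c.scores["exam"] == 0]
        r = np.corrcoef(s0["apdqs"], s0["keys_score"])[0, 1]
        assert abs(r) < 3 / np.sqrt(len(s0))  # within Monte-Carlo error of 0
        # null hazard: per-SD HR near 1
        from dietcvd.lipids import derive_lipid_panel
        from dietcvd.models import fit_cox_timevarying
        from dietcvd.pipeline import prepare_stage, risk_table_for, score_cohort

        scores = score_cohort(c.intakes, c.nutrients)
        lip = derive_lipid_panel(c.lipids)
        ids, _ = prepare_stage(c, lip)
        risk = risk_table_for(c, scores, lip, ids, "apdqs", "chd")
        et = fit_cox_timevarying(risk, "apdqs", coding="continuous")
        se = abs(np.log(et.per_sd_ci[1]) - np.log(et.per_sd_hr)) / 1.96
        assert abs(np.log(et.per_sd_hr)) < 3 * se


class TestCalibrationMoments:
    def test_baseline_lipid_moments(self, small_cohort):
        from dietcvd.lipids import derive_lipid_panel

        lip = derive_lipid_panel(small_cohort.lipids)
        y0 = lip[lip["exam"] == 0]
        assert y0["ldl_c"].mean() == pytest.approx(2.82, abs=0.15)
        assert y0["ldl_c"].std() == pytest.approx(0.80, abs=0.12)
        assert y0["non_hdl_c"].mean() == pytest.approx(3.19, abs=0.15)

    def test_scores_match_recomputation(self, small_cohort):
        """Generator-emitted scores equal what the scoring stage computes."""
        from dietcvd.pipeline import score_cohort

        recomputed = score_cohort(small_cohort.intakes, small_cohort.nutrients)
        merged = small_cohort.scores.merge(
            recomputed, on=["participant_id", "exam"], suffixes=("_gen", "_re")
        )
        np.testing.assert_allclose(merged["apdqs_gen"], merged["apdqs_re"])
        np.testing.assert_allclose(merged["keys_score_gen"], merged["keys_score_re"])
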