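"""Synthetic cohort generation, recalibration, follow-up, estimation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from statin_cua.markov import STATE_INDEX, HealthState, band_for_age
from statin_cua.population import uniform_census_weights
from statin_cua.synthetic import (CalibrationTargets,
                                  estimate_transition_table, generate_cohort,
                                  recalibrate_risk, simulate_followup)


def soft_event_fraction(events: pd.DataFrame, cohort: pd.DataFrame) -> float:
    if events.empty:
        return 0.0
    firsts = events.sort_values(["id", "time"]).groupby("id").first()
    return (firsts["event"] != "fatal_non_ASCVD").sum() / len(cohort)


def constant_hazard_cohort(n, hazard_soft, hazard_death=0.0):
    return pd.DataFrame({
        "id": np.arange(n),
        "age": np.full(n, 52.0),
        "sex": np.array(["female"] * n),
        "region": np.array(["urban_1"] * n),
        "risk_soft": np.full(n, 0.10),
        "risk_hard": np.full(n, 0.05),
        "hazard_soft": np.full(n, hazard_soft),
        "hazard_death": np.full(n, hazard_death),
        "hard_share": np.full(n, 0.675),
    })


class TestGenerateCohort:
    def test_medians_hit_calibration_targets(self, study_cohort):
        assert study_cohort["risk_soft"].median() == pytest.approx(0.098,
                                                                   abs=0.005)
        assert study_cohort["risk_hard"].median() == pytest.approx(0.052,
                                                                   abs=0.005)

    def test_structure_and_ranges(self, study_cohort):
        assert study_cohort["age"].between(30, 75).all()
        assert set(study_cohort["sex"]) == {"female", "male"}
        assert study_cohort["region"].nunique() == 10
        assert ((study_cohort["risk_soft"] >= 0)
                & (study_cohort["risk_soft"] < 1)).all()

    def test_soft_risk_dominates_hard_risk(self, study_cohort):
        assert (study_cohort["risk_soft"] >= study_cohort["risk_hard"]).all()

    def test_same_seed_identical_cohort(self):
        a = generate_cohort(500, seed=77)
        b = generate_cohort(500, seed=77)
        pd.testing.assert_frame_equal(a, b)

    def test_single_individual(self):
        one = generate_cohort(1, seed=0)
        assert len(one) == 1
        assert 0 <= one.loc[0, "risk_soft"] < 1

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            CalibrationTargets(median_soft=0.05, median_hard=0.10)
        with pytest.raises(ValueError):
            generate_cohort(0, seed=0)


class TestRecalibrate:
    def test_identity_when_observed_equals_mean(self):
        rng = np.random.default_rng(1)
        risks = rng.uniform(0.01, 0.3, 1000)
        regions = np.array(["urban_1"] * 1000)
        out = recalibrate_risk(risks, regions,
                               {"urban_1": float(np.mean(risks))})
        np.testing.assert_allclose(out, risks, atol=1e-9)

    def test_doubled_observed_mean_is_matched(self):
        rng = np.random.default_rng(2)
        risks = rng.uniform(0.01, 0.2, 2000)
        regions = np.array(["rural_3"] * 2000)
        target = 2 * float(np.mean(risks))
        out = recalibrate_risk(risks, regions, {"rural_3": target})
        assert np.mean(out) == pytest.approx(target, abs=1e-6)

    def test_ordering_preserved(self):
        rng = np.random.default_rng(3)
        risks = rng.uniform(0.01, 0.4, 500)
        regions = np.array(["urban_2"] * 500)
        out = recalibrate_risk(risks, regions, {"urban_2": 0.15})
        rho = stats.spearmanr(risks, out).statistic
        assert rho == pytest.approx(1.0)

    @pytest.mark.parametrize("observed", [0.0, 1.0])
    def test_degenerate_region_rejected(self, observed):
        with pytest.raises(ValueError):
            recalibrate_risk(np.array([0.1]), np.array(["urban_1"]),
                             {"urban_1": observed})


class TestSimulateFollowup:
    def test_zero_hazards_no_events(self):
        cohort = constant_hazard_cohort(200, 0.0)
        events = simulate_followup(cohort, 12.0, seed=4)
        assert events.empty

    def test_soft_event_fraction_matches_target(self, study_cohort,
                                                study_events):
        frac = soft_event_fraction(study_events, study_cohort)
        assert frac == pytest.approx(0.169, abs=0.005)

    def test_hard_fraction_below_soft(self, study_cohort, study_events):
        firsts = study_events.sort_values(["id", "time"]).groupby("id").first()
        hard = firsts["event"].isin(["acute_MI", "IS", "fatal_ASCVD"]).sum()
        soft = (firsts["event"] != "fatal_non_ASCVD").sum()
        assert hard < soft
        assert hard / len(study_cohort) == pytest.approx(0.114, abs=0.01)

    def test_at_most_one_fatal_event_each(self, study_events):
        fatal = study_events[study_events["event"].str.startswith("fatal")]
        assert fatal["id"].is_unique

    def test_bad_duration_rejected(self, study_cohort):
        with pytest.raises(ValueError):
            simulate_followup(study_cohort.head(5), 0.0, seed=0)


class TestEstimateTable:
    def test_single_stratum_recovers_true_p10(self):
        """Binomial sampling oracle: with a known constant hazard the
        estimated 10-year disease-free exit probability lands within three
        binomial standard errors of the truth."""
        p10_true = 0.10
        hazard = -np.log1p(-p10_true) / 10.0
        n = 100_000
        cohort = constant_hazard_cohort(n, hazard)
        events = simulate_followup(cohort, 12.0, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = estimate_transition_table(events, cohort)
        probs = table.frame
        df_rows = probs[(probs["from_state"] == "disease_free")
                        & (probs["risk_group"] == "overall")
                        & (probs["sex"] == "female")]
        p10_hat = df_rows["value"].sum()
        se = np.sqrt(p10_true * (1 - p10_true) / n)
        assert abs(p10_hat - p10_true) < 3 * se

    def test_eligible_exceeds_non_eligible(self, study_cohort, study_tables):
        """Risk score and latent hazard are positively linked, so in any
        stratum large enough for sampling noise not to dominate the
        eligible group's first-event probability exceeds the rest's."""
        tables, _ = study_tables
        frame = tables[18.0].frame
        df = frame[frame["from_state"] == "disease_free"]
        counts = study_cohort.assign(
            age_group=[band_for_age(a) for a in study_cohort["age"]],
            eligible=study_cohort["risk_soft"] >= 0.18,
        ).groupby(["sex", "age_group"])["eligible"].agg(["sum", "count"])
        checked = 0
        for (sex, band), grp in df.groupby(["sex", "age_group"]):
            n_elig, n_all = counts.loc[(sex, band)]
            if min(n_elig, n_all - n_elig) < 500:
                continue
            by_group = grp.groupby("risk_group")["value"].sum()
            assert by_group["eligible"] >= by_group["non_eligible"]
            checked += 1
        assert checked >= 4

    def test_deterministic_given_seeds(self, study_cohort, study_events):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = estimate_transition_table(study_events, study_cohort,
                                          threshold=0.18, model="soft")
            b = estimate_transition_table(study_events, study_cohort,
                                          threshold=0.18, model="soft")
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_census_weights_only_affect_pooled_rows(self, study_cohort,
                                                    study_events):
        """Disease-free rows are within-cell proportions, independent of the
        weight table; a single-cell cohort makes the pooled rows weight-free
        too, so census and uniform weighting then agree exactly."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            census = estimate_transition_table(study_events, study_cohort)
            uniform = estimate_transition_table(study_events, study_cohort,
                                                uniform_census_weights())
        df_c = census.frame[census.frame["from_state"] == "disease_free"]
        df_u = uniform.frame[uniform.frame["from_state"] == "disease_free"]
        pd.testing.assert_frame_equal(df_c.reset_index(drop=True),
                                      df_u.reset_index(drop=True))

        one_cell = constant_hazard_cohort(5000, 0.02)
        ev = simulate_followup(one_cell, 12.0, seed=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = estimate_transition_table(ev, one_cell)
            b = estimate_transition_table(ev, one_cell,
                                          uniform_census_weights())
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_no_events_gives_zero_probabilities(self):
        cohort = constant_hazard_cohort(100, 0.0)
        events = simulate_followup(cohort, 12.0, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = estimate_transition_table(events, cohort)
        df = table.frame[table.frame["from_state"] == "disease_free"]
        assert (df["value"] == 0).all()


class TestEndToEndRecovery:
    def test_pipeline_ten_year_incidence_matches_generator_truth(
            self, study_cohort, study_tables):
        """Generate -> simulate -> estimate -> propagate: the cohort model's
        10-year first-event ASCVD fraction per cell tracks the analytic
        expectation of the latent hazards within Monte-Carlo error."""
        from statin_cua.markov import build_transition_matrix, run_cohort, \
            lifetime_ascvd_fraction
        tables, _ = study_tables
        table = tables[20.0]
        cohort = study_cohort.assign(
            age_group=[band_for_age(a) for a in study_cohort["age"]])
        for sex, band in (("female", "50-54"), ("male", "60-64")):
            cell = cohort[(cohort["sex"] == sex)
                          & (cohort["age_group"] == band)]
            lam_s = cell["hazard_soft"].to_numpy()
            lam_d = cell["hazard_death"].to_numpy()
            tot = lam_s + lam_d
            truth = float(np.mean(lam_s / tot * -np.expm1(-10 * tot)))
            m = build_transition_matrix(table, sex, band, "overall")
            init = np.zeros(9)
            init[STATE_INDEX[HealthState.DISEASE_FREE_UNTREATED]] = 1.0
            trace = run_cohort([m] * 10, init, 10)
            modeled = lifetime_ascvd_fraction(trace)
            se = np.sqrt(truth * (1 - truth) / len(cell))
            assert abs(modeled - truth) < 3 * se
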