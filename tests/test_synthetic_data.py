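import numpy as np
import pandas as pd
import pytest

from chwvitals.synthetic_data import (
    CaptureModel,
    SimulationConfig,
    SurveyModel,
    apply_chw_observation,
    apply_survey_observation,
    simulate_ledger,
)


class TestSimulationConfig:
    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            SimulationConfig(hazard_neonatal=1.5)

    def test_rejects_zero_population(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_catchments=0)

    def test_rejects_inverted_horizon(self):
        with pytest.raises(ValueError):
            SimulationConfig(sim_start_cmc=100, sim_end_cmc=100)


class TestSimulateLedger:
    def test_no_birth_process(self):
        cfg = SimulationConfig(monthly_birth_prob=0.0)
        assert len(simulate_ledger(cfg)) == 0

    def test_certain_neonatal_death(self):
        cfg = SimulationConfig(hazard_neonatal=1.0, stillbirth_prob=0.0,
                               monthly_birth_prob=0.1, seed=3)
        ledger = simulate_ledger(cfg)
        assert len(ledger) > 0
        assert ledger["died"].all()
        assert (ledger["age_at_death_days"] < 28).all()
        assert (ledger["age_at_death_months"] == 0).all()

    def test_binomial_birth_count(self):
        # 10,000 woman-months at p = 0.02: births within 3 binomial SD of 200
        cfg = SimulationConfig(
            n_catchments=1, households_per_catchment=500, women_per_household=1,
            monthly_birth_prob=0.02, stillbirth_prob=0.0,
            sim_start_cmc=1, sim_end_cmc=20, seed=11)
        assert cfg.n_women * 20 == 10_000
        n = len(simulate_ledger(cfg))
        sd = np.sqrt(10_000 * 0.02 * 0.98)
        assert abs(n - 200) <= 3 * sd

    def test_ledger_invariants(self, small_ledger):
        died = small_ledger[small_ledger["died"]]
        assert (died["death_cmc"] >= died["birth_cmc"]).all()
        assert (died["age_at_death_months"] < 60).all()
        neonatal = died["age_at_death_months"] == 0
        assert (died.loc[neonatal, "age_at_death_days"] < 28).all()
        assert died.loc[~neonatal, "age_at_death_days"].isna().all()
        stillborn = small_ledger[small_ledger["stillbirth"]]
        assert not stillborn["died"].any()
        assert stillborn["death_cmc"].isna().all()

    def test_reproducible(self, small_config):
        a = simulate_ledger(small_config)
        b = simulate_ledger(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_sex_ratio_recovery(self):
        cfg = SimulationConfig(
            n_catchments=1, households_per_catchment=2000, women_per_household=2,
            monthly_birth_prob=0.05, stillbirth_prob=0.0,
            sim_start_cmc=1, sim_end_cmc=48, srb_true=105.0, seed=5)
        ledger = simulate_ledger(cfg)
        m = (ledger["sex"] == "M").sum()
        f = (ledger["sex"] == "F").sum()
        p = 105 / 205
        se = np.sqrt(p * (1 - p) / len(ledger))
        assert abs(m / len(ledger) - p) <= 3 * se


class TestApplyChwObservation:
    def test_perfect_observation_matches_ledger(self, small_ledger, small_config):
        reports = apply_chw_observation(
            small_ledger, CaptureModel(), seed=1,
            period_start_cmc=small_config.sim_start_cmc,
            period_end_cmc=small_config.sim_end_cmc,
            n_catchments=small_config.n_catchments)
        live = small_ledger[~small_ledger["stillbirth"]]
        in_period = live[live["birth_cmc"] <= small_config.sim_end_cmc]
        assert reports["births_male"].sum() == (in_period["sex"] == "M").sum()
        assert reports["births_female"].sum() == (in_period["sex"] == "F").sum()
        died = live[live["died"] & (live["death_cmc"] <= small_config.sim_end_cmc)]
        assert reports["deaths_neonatal"].sum() == (died["age_at_death_months"] == 0).sum()
        assert reports["deaths_under5"].sum() == len(died)
        # every catchment-month submitted
        n_months = small_config.sim_end_cmc - small_config.sim_start_cmc + 1
        assert len(reports) == small_config.n_catchments * n_months

    def test_zero_birth_capture(self, small_ledger):
        reports = apply_chw_observation(
            small_ledger, CaptureModel(p_capture_birth=0.0), seed=1)
        assert reports["births_male"].sum() == 0
        assert reports["births_female"].sum() == 0

    def test_half_capture_binomial(self):
        cfg = SimulationConfig(
            n_catchments=2, households_per_catchment=500, women_per_household=2,
            monthly_birth_prob=0.05, stillbirth_prob=0.0,
            sim_start_cmc=1, sim_end_cmc=12, seed=21)
        ledger = simulate_ledger(cfg)
        n_true = len(ledger)
        assert n_true > 800
        reports = apply_chw_observation(
            ledger, CaptureModel(p_capture_birth=0.5), seed=2,
            period_start_cmc=1, period_end_cmc=12, n_catchments=2)
        n_rep = reports[["births_male", "births_female"]].to_numpy().sum()
        sd = np.sqrt(n_true * 0.25)
        assert abs(n_rep - n_true / 2) <= 3 * sd

    def test_missing_months_suppress_events(self, small_ledger, small_config):
        reports = apply_chw_observation(
            small_ledger, CaptureModel(p_monthly_report_missing=0.3), seed=9,
            period_start_cmc=small_config.sim_start_cmc,
            period_end_cmc=small_config.sim_end_cmc,
            n_catchments=small_config.n_catchments)
        n_cells = small_config.n_catchments * \
            (small_config.sim_end_cmc - small_config.sim_start_cmc + 1)
        assert len(reports) < n_cells
        # no duplicated catchment-month rows
        assert not reports.duplicated(["catchment_id", "cmc"]).any()

    def test_stillbirth_misclassification(self):
        cfg = SimulationConfig(monthly_birth_prob=0.05, stillbirth_prob=1.0,
                               sim_start_cmc=1, sim_end_cmc=12, seed=4)
        ledger = simulate_ledger(cfg)
        reports = apply_chw_observation(
            ledger, CaptureModel(p_stillbirth_as_neonatal=1.0), seed=5)
        assert reports["deaths_neonatal"].sum() == len(ledger)
        reports0 = apply_chw_observation(
            ledger, CaptureModel(p_stillbirth_as_neonatal=0.0), seed=5)
        assert reports0["deaths_neonatal"].sum() == 0

    def test_reported_subset_of_truth(self, small_ledger, small_config):
        """No duplication: per catchment-month, reported <= true counts."""
        model = CaptureModel(p_capture_birth=0.7, p_capture_death_neonatal=0.7,
                             p_capture_death_postneonatal=0.7, p_capture_death_child=0.7)
        reports = apply_chw_observation(
            small_ledger, model, seed=3,
            period_start_cmc=small_config.sim_start_cmc,
            period_end_cmc=small_config.sim_end_cmc,
            n_catchments=small_config.n_catchments)
        live = small_ledger[~small_ledger["stillbirth"]]
        for _, row in reports.iterrows():
            true_b = ((live["catchment_id"] == row["catchment_id"])
                      & (live["birth_cmc"] == row["cmc"])).sum()
            assert row["births_male"] + row["births_female"] <= true_b

    def test_model_validation(self):
        with pytest.raises(ValueError):
            CaptureModel(p_capture_birth=1.2)


class TestApplySurveyObservation:
    def test_faithful_census(self, small_ledger, faithful_census):
        h = apply_survey_observation(small_ledger, faithful_census, seed=1)
        live = small_ledger[~small_ledger["stillbirth"]]
        assert len(h) == len(live)
        assert set(h["child_id"]) == set(live["child_id"])
        merged = h.merge(live, on="child_id", suffixes=("_s", "_t"))
        assert (merged["birth_cmc_s"] == merged["birth_cmc_t"]).all()
        assert (merged["died_s"] == merged["died_t"]).all()
        d = merged[merged["died_t"]]
        assert (d["death_cmc_s"] == d["death_cmc_t"]).all()

    def test_stillbirths_excluded(self, small_ledger, faithful_census):
        h = apply_survey_observation(small_ledger, faithful_census, seed=1)
        stillborn_ids = set(small_ledger.loc[small_ledger["stillbirth"], "child_id"])
        assert not stillborn_ids & set(h["child_id"])

    def test_total_heaping(self):
        cfg = SimulationConfig(monthly_birth_prob=0.05, hazard_neonatal=0.0,
                               hazard_postneonatal=1.0, stillbirth_prob=0.0,
                               sim_start_cmc=1, sim_end_cmc=24, seed=8)
        ledger = simulate_ledger(cfg)
        # restrict to deaths in the heapable band
        ledger = ledger[ledger["age_at_death_months"].between(10, 14)]
        assert len(ledger) > 0
        model = SurveyModel(interview_cmc=100, p_heap_to_12m=1.0)
        h = apply_survey_observation(ledger, model, seed=2)
        assert (h["age_at_death_months"] == 12).all()

    def test_sample_fraction_binomial(self, rng):
        n_hh = 4000
        ledger = pd.DataFrame({
            "child_id": np.arange(n_hh),
            "mother_id": np.arange(n_hh),
            "household_id": np.arange(n_hh),
            "catchment_id": 0,
            "birth_cmc": 100,
            "sex": "F",
            "stillbirth": False,
            "died": False,
            "age_at_death_days": np.nan,
            "age_at_death_months": np.nan,
            "death_cmc": np.nan,
        })
        model = SurveyModel(design="household_sample", sample_fraction=0.25,
                            interview_cmc=200)
        h = apply_survey_observation(ledger, model, seed=6)
        n_sampled = h["household_id"].nunique()
        sd = np.sqrt(n_hh * 0.25 * 0.75)
        assert abs(n_sampled - 1000) <= 3 * sd

    def test_interview_predating_events_rejected(self, small_ledger):
        with pytest.raises(ValueError):
            apply_survey_observation(
                small_ledger, SurveyModel(interview_cmc=1), seed=1)

    def test_empty_selection_rejected(self, small_ledger):
        model = SurveyModel(design="household_sample", sample_fraction=0.0,
                            interview_cmc=2000)
        with pytest.raises(ValueError):
            apply_survey_observation(small_ledger, model, seed=1)

    def test_recall_omission_only_hits_dead_children(self, small_ledger):
        model = SurveyModel(interview_cmc=1400, p_omit_per_year_recall=0.5)
        h = apply_survey_observation(small_ledger, model, seed=3)
        live = small_ledger[~small_ledger["stillbirth"]]
        survivors = set(live.loc[~live["died"], "child_id"])
        assert survivors <= set(h["child_id"])
        n_dead_true = int(live["died"].sum())
        n_dead_obs = int(h["died"].sum())
        assert n_dead_obs < n_dead_true

    def test_date_displacement_moves_dates(self, small_ledger):
        model = SurveyModel(interview_cmc=1400, date_displacement_sd=2.0)
        h = apply_survey_observation(small_ledger, model, seed=4)
        live = small_ledger[~small_ledger["stillbirth"]]
        merged = h.merge(live, on="child_id", suffixes=("_s", "_t"))
        shifts = merged["birth_cmc_s"] - merged["birth_cmc_t"]
        assert shifts.abs().max() > 0
        assert abs(shifts.mean()) < 1.0  # centered displacement

    def test_determinism(self, small_ledger):
        model = SurveyModel(interview_cmc=1400, p_omit_per_year_recall=0.2,
                            p_heap_to_12m=0.5, date_displacement_sd=1.0)
        a = apply_survey_observation(small_ledger, model, seed=5)
        b = apply_survey_observation(small_ledger, model, seed=5)
        pd.testing.assert_frame_equal(a, b)
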