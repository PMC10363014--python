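import numpy as np
import pandas as pd
import pytest

import marchphys as mp
from marchphys.config import CohortConfig
from marchphys.energetics import paee_series
from marchphys.segmentation import BREAK, MARCH, classify_states
from marchphys.synthetic import generate_cohort, generate_dataset, generate_sensor_streams, state_template


class TestConfigValidation:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            CohortConfig(n_soldiers=0)
        with pytest.raises(ValueError):
            CohortConfig(vo2peak_mean_sd=(54.2, -1.0))
        with pytest.raises(ValueError):
            CohortConfig(break_starts=(90, 100), break_durations_min=(15, 15))  # overlap
        with pytest.raises(ValueError):
            CohortConfig(break_starts=(90,), break_durations_min=(9,))  # below 10 min
        with pytest.raises(ValueError):
            CohortConfig(march_start_clock="15:11", march_end_clock="16:11",
                         break_starts=(10,), break_durations_min=(55,))

    def test_default_timeline_is_the_study_protocol(self):
        config = CohortConfig()
        assert config.total_minutes == 475  # 15:11 -> 23:06, 7:55 h
        template = state_template(config)
        assert len(template) == 475
        assert all(19 <= d <= 24 for d in config.break_durations_min)
        assert len(config.break_starts) == 4


class TestGenerateCohort:
    def test_reproducible_under_seed(self):
        a, _ = generate_cohort(CohortConfig(n_soldiers=3, seed=5))
        b, _ = generate_cohort(CohortConfig(n_soldiers=3, seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_sd_gives_identical_soldiers(self):
        config = CohortConfig(
            n_soldiers=5, age_mean_sd=(20.3, 0), height_mean_sd=(178.5, 0),
            weight_mean_sd=(74.8, 0), vo2peak_mean_sd=(54.2, 0), resting_hr_mean_sd=(60, 0))
        roster, _ = generate_cohort(config)
        for col in ("age_y", "height_cm", "weight_kg", "run_peak_velocity_kmh", "vo2peak"):
            assert roster[col].nunique() == 1

    def test_cohort_emulates_study_distributions(self):
        roster, _ = generate_cohort(CohortConfig(n_soldiers=1000, seed=0))
        assert roster["vo2peak"].mean() == pytest.approx(54.2, abs=0.8)
        assert roster["age_y"].mean() == pytest.approx(20.3, abs=3 * 1.3 / np.sqrt(1000))
        assert roster["weight_kg"].mean() == pytest.approx(74.8, abs=3 * 9.8 / np.sqrt(1000))
        assert (roster["vo2peak"] > 0).all()

    def test_velocity_quantized_to_run_stages(self):
        roster, _ = generate_cohort(CohortConfig(n_soldiers=50, seed=1))
        offsets = (roster["run_peak_velocity_kmh"] - 8.5) % 0.5
        assert np.allclose(np.minimum(offsets, 0.5 - offsets), 0.0, atol=1e-9)


class TestSensorStreams:
    def test_byte_identical_under_seed(self):
        a = generate_dataset(n_soldiers=4, seed=9)
        b = generate_dataset(n_soldiers=4, seed=9)
        pd.testing.assert_frame_equal(a.roster, b.roster)
        for sid in a.minutes:
            pd.testing.assert_frame_equal(a.minutes[sid], b.minutes[sid])
        pd.testing.assert_frame_equal(a.diary, b.diary)
        pd.testing.assert_frame_equal(a.questionnaire, b.questionnaire)

    def test_step_frequency_separates_states(self, clean_dataset):
        for sid, mins in clean_dataset.minutes.items():
            states = clean_dataset.truth.states[sid]
            sf = mins["step_freq"].to_numpy()
            assert (sf[states == MARCH] > 1.0).all()
            assert (sf[states == BREAK] < 1.0).all()

    def test_noise_free_inversion_recovers_true_paee(self, clean_dataset):
        roster = clean_dataset.roster.set_index("id")
        for sid, mins in clean_dataset.minutes.items():
            classified = classify_states(mins)
            est = paee_series(classified, roster.loc[sid, "resting_hr_bpm"])
            np.testing.assert_allclose(est, clean_dataset.truth.paee[sid], atol=1e-9)

    def test_hr_within_physiological_bounds(self, noisy_dataset):
        for mins in noisy_dataset.minutes.values():
            assert mins["hr"].between(30, 220).all()

    def test_ground_truth_tee_consistent(self, clean_dataset):
        clean_dataset.truth.check_consistency(clean_dataset.roster)

    def test_bct_rises_toward_plateau_and_low_fitness_runs_hotter(self, clean_dataset):
        roster = clean_dataset.roster
        peaks = {}
        for sid, mins in clean_dataset.minutes.items():
            bct = mins["bct"].to_numpy()
            assert bct[0] == pytest.approx(37.3, abs=0.7)
            assert bct.max() > bct[0] + 0.5
            peaks[sid] = bct.max()
        by_tert = roster.assign(peak=roster["id"].map(peaks)).groupby("tertile")["peak"].mean()
        assert by_tert["LT"] > by_tert["HT"]

    def test_monte_carlo_tee_estimate_unbiased(self):
        # 200 replicate soldiers at 3 bpm HR noise: mean TEE bias within +/-2%
        ds = generate_dataset(n_soldiers=200, seed=31, hr_noise_sd=3.0,
                              dropout_hazard_per_pain_point=0.0)
        res = mp.analyze_dataset(ds)
        truth = res.per_soldier["id"].map(ds.truth.tee)
        bias = (res.per_soldier["tee"] - truth).mean() / truth.mean()
        assert abs(bias) < 0.02


class TestDiaryAndQuestionnaire:
    def test_zero_intake_fraction_empties_diary(self):
        ds = generate_dataset(n_soldiers=5, seed=3, intake_fraction_by_tertile=(0, 0, 0),
                              dropout_hazard_per_pain_point=0.0)
        assert len(ds.diary) == 0
        res = mp.analyze_dataset(ds)
        assert (res.per_soldier["deficit"] == -res.per_soldier["tee"]).all()
        assert (res.per_soldier["pct_replaced"] == 0).all()

    def test_intake_matches_configured_fraction_of_true_tee(self, clean_dataset):
        frac = dict(zip(("LT", "MT", "HT"), clean_dataset.config.intake_fraction_by_tertile))
        totals = clean_dataset.diary.groupby("id")["kcal"].sum()
        for sid, intake in totals.items():
            tert = clean_dataset.truth.tertile[sid]
            assert intake == pytest.approx(frac[tert] * clean_dataset.truth.tee[sid], rel=1e-9)

    def test_null_hazard_means_no_dropouts(self, clean_dataset):
        assert not any(clean_dataset.truth.dropout.values())
        assert clean_dataset.questionnaire["dropout"].sum() == 0

    def test_dropout_probability_increases_with_pain(self):
        ds = generate_dataset(n_soldiers=400, seed=13, dropout_hazard_per_pain_point=0.08)
        q = ds.questionnaire
        assert q["dropout"].sum() > 0
        pain_dropped = q.loc[q["dropout"] == 1, "pain_pre"].mean()
        pain_stayed = q.loc[q["dropout"] == 0, "pain_pre"].mean()
        assert pain_dropped > pain_stayed

    def test_dropout_streams_truncated(self):
        ds = generate_dataset(n_soldiers=60, seed=21, dropout_hazard_per_pain_point=0.3)
        q = ds.questionnaire.set_index("id")
        total = ds.config.total_minutes
        for sid, mins in ds.minutes.items():
            if q.loc[sid, "dropout"]:
                assert len(mins) < total
            else:
                assert len(mins) == total
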