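"""Synthetic cohort generator: ground truth validity, planted signals,
determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import normaltest

from wardhmm.config import BLOOD_TESTS, N_BLOOD_TESTS, VITAL_SIGNS
from wardhmm.synthetic import (
    CohortConfig,
    GroundTruth,
    SamplingConfig,
    assign_outcome,
    cohort_to_frames,
    emit_observations,
    sample_ground_truth,
    simulate_cohort,
    simulate_state_path,
    write_cohort,
)


class TestSampleGroundTruth:
    def test_single_state_chain_is_degenerate(self):
        gt = sample_ground_truth(K=1, D=2, seed=0)
        np.testing.assert_array_equal(gt.params_true.pi, [1.0])
        np.testing.assert_array_equal(gt.params_true.A, [[1.0]])

    def test_covariances_are_spd_by_cholesky(self):
        gt = sample_ground_truth(K=5, D=23, separation=3.0, seed=7)
        for S in gt.params_true.covariances:
            np.linalg.cholesky(S)  # raises LinAlgError if not SPD

    def test_production_model_dimensions(self):
        gt = sample_ground_truth(K=17, D=23, separation=2.0, seed=1)
        assert gt.params_true.means.shape == (17, 23)
        assert gt.params_true.covariances.shape == (17, 23, 23)
        gt.validate()

    def test_transition_rows_and_affinity_rows_sum_to_one(self):
        gt = sample_ground_truth(K=6, D=10, separation=2.0, seed=3)
        np.testing.assert_allclose(gt.params_true.A.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(gt.diagnosis_affinity.sum(axis=1), 1.0, atol=1e-12)

    def test_separation_scales_mean_distances(self):
        gt = sample_ground_truth(K=4, D=8, separation=6.0, seed=2)
        m = gt.params_true.means
        d = np.linalg.norm(m[:, None] - m[None, :], axis=-1)
        min_dist = d[~np.eye(4, dtype=bool)].min()
        mean_sd = np.sqrt(np.mean([np.diag(S) for S in gt.params_true.covariances]))
        assert min_dist >= 6.0 * mean_sd - 1e-9

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            sample_ground_truth(K=0, D=3)
        with pytest.raises(ValueError):
            sample_ground_truth(K=3, D=0)
        with pytest.raises(ValueError):
            sample_ground_truth(K=3, D=3, separation=-1.0)

    def test_spherical_covariance_option(self):
        gt = sample_ground_truth(K=3, D=6, separation=3.0, seed=4, covariance="spherical")
        for S in gt.params_true.covariances:
            np.testing.assert_array_equal(S, np.eye(6))

    def test_stationary_weights_give_target_occupancy(self):
        w = np.array([0.45, 0.20, 0.20, 0.15])
        gt = sample_ground_truth(K=4, D=5, separation=3.0, seed=5, stationary_weights=w)
        # w is the exact stationary vector of A = s I + (1-s) 1 w^T
        np.testing.assert_allclose(w @ gt.params_true.A, w, atol=1e-12)
        path = simulate_state_path(gt, 60_000, seed=6)
        occ = np.bincount(path, minlength=4) / 60_000
        np.testing.assert_allclose(occ, w, atol=0.02)

    def test_json_round_trip(self, tmp_path, small_ground_truth):
        path = tmp_path / "gt.json"
        small_ground_truth.save(path)
        import json

        loaded = GroundTruth.from_dict(json.loads(path.read_text()))
        np.testing.assert_allclose(
            loaded.params_true.A, small_ground_truth.params_true.A
        )


class TestSimulateStatePath:
    def test_identity_transitions_freeze_initial_state(self, small_ground_truth):
        gt = GroundTruth(**{**small_ground_truth.__dict__})
        gt.params_true = small_ground_truth.params_true.permuted(np.arange(3))
        gt.params_true.A = np.eye(3)
        path = simulate_state_path(gt, 20, seed=4)
        assert np.all(path == path[0])

    def test_deterministic_two_cycle(self, small_ground_truth):
        gt = GroundTruth(**{**small_ground_truth.__dict__})
        gt.params_true = small_ground_truth.params_true.permuted(np.arange(3))
        gt.params_true.pi = np.array([1.0, 0.0, 0.0])
        gt.params_true.A = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        np.testing.assert_array_equal(simulate_state_path(gt, 4, seed=0)[:4], [0, 1, 0, 1])

    def test_long_run_transition_frequencies_match(self, small_ground_truth):
        path = simulate_state_path(small_ground_truth, 10_000, seed=3)
        A = small_ground_truth.params_true.A
        counts = np.zeros_like(A)
        np.add.at(counts, (path[:-1], path[1:]), 1)
        empirical = counts / counts.sum(axis=1, keepdims=True)
        assert np.max(np.abs(empirical - A)) < 0.02

    def test_zero_length_rejected(self, small_ground_truth):
        with pytest.raises(ValueError):
            simulate_state_path(small_ground_truth, 0)


class TestEmitObservations:
    def test_full_probability_means_every_day_rich(self):
        gt = sample_ground_truth(K=2, D=23, separation=2.0, seed=0)
        sampling = SamplingConfig(blood_test_daily_prob=1.0, vital_daily_prob=1.0)
        obs, _ = emit_observations(np.zeros(5, dtype=int), gt, sampling, seed=1)
        per_day = obs.assign(day=obs["timestamp"].dt.day).groupby("day")["variable"].nunique()
        assert (per_day == 23).all()

    def test_suppressed_blood_tests_make_every_day_poor(self):
        # 10 of 17 tests never observed -> at most 7 < 14 observed per day
        gt = sample_ground_truth(K=2, D=23, separation=2.0, seed=0)
        probs = np.ones(N_BLOOD_TESTS)
        probs[:10] = 0.0
        sampling = SamplingConfig(blood_test_daily_prob=probs, vital_daily_prob=1.0)
        obs, _ = emit_observations(np.zeros(4, dtype=int), gt, sampling, seed=1)
        tests = obs[obs["variable"].isin(BLOOD_TESTS)]
        n_tests_per_day = tests.groupby(tests["timestamp"].dt.date)["variable"].nunique()
        assert (n_tests_per_day <= 7).all()

    def test_deterministic_under_seed(self):
        gt = sample_ground_truth(K=2, D=23, separation=2.0, seed=0)
        states = np.array([0, 1, 1, 0])
        a, _ = emit_observations(states, gt, seed=9)
        b, _ = emit_observations(states, gt, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_timestamps_within_episode_days(self):
        gt = sample_ground_truth(K=2, D=23, separation=2.0, seed=0)
        from datetime import date

        obs, _ = emit_observations(
            np.zeros(3, dtype=int), gt, seed=2, admit_date=date(2020, 5, 1)
        )
        day_idx = (obs["timestamp"].dt.normalize() - pd.Timestamp("2020-05-01")).dt.days
        assert day_idx.min() >= 0 and day_idx.max() < 3

    def test_event_count_bounds(self):
        gt = sample_ground_truth(K=2, D=23, separation=2.0, seed=0)
        obs, _ = emit_observations(np.zeros(6, dtype=int), gt, seed=3)
        obs["day"] = obs["timestamp"].dt.date
        counts = obs.groupby(["day", "variable"]).size()
        tests = counts[counts.index.get_level_values(1).isin(BLOOD_TESTS)]
        vitals = counts[counts.index.get_level_values(1).isin(VITAL_SIGNS)]
        assert tests.max() <= 2
        assert vitals.max() <= 8

    def test_empty_sequence_rejected(self, small_ground_truth):
        with pytest.raises(ValueError):
            emit_observations(np.array([], dtype=int), small_ground_truth)


class TestAssignOutcome:
    def test_minus_infinity_logit_never_dies(self, small_ground_truth):
        gt = GroundTruth(**{**small_ground_truth.__dict__})
        gt.mortality_logit_per_state = np.full(3, -np.inf)
        outcomes = {assign_outcome(np.array([0, 1, 2]), gt, seed=s) for s in range(50)}
        assert "IM" not in outcomes

    def test_saturated_logit_always_dies(self, small_ground_truth):
        gt = GroundTruth(**{**small_ground_truth.__dict__})
        gt.mortality_logit_per_state = np.array([10.0, 0.0, 0.0])
        gt.base_mortality_logit = 0.0
        outcomes = [assign_outcome(np.zeros(5, dtype=int), gt, seed=s) for s in range(100)]
        assert outcomes.count("IM") >= 99

    def test_value_weights_add_presenting_acuity_term(self, small_ground_truth):
        gt = GroundTruth(**{**small_ground_truth.__dict__})
        gt.mortality_logit_per_state = np.zeros(3)
        gt.base_mortality_logit = 0.0
        rng = np.random.default_rng(0)
        states = np.zeros(6, dtype=int)
        latent = rng.normal(size=(6, 5))
        w = np.zeros(5)
        w[0] = 100.0  # saturating weight on the first variable
        latent[:3, 0] = 1.0   # high early acuity
        outcomes = [
            assign_outcome(states, gt, seed=s, latent=latent, value_weights=w, value_days=3)
            for s in range(30)
        ]
        assert all(o == "IM" for o in outcomes)
        latent[:3, 0] = -1.0  # low early acuity
        outcomes = [
            assign_outcome(states, gt, seed=s, latent=latent, value_weights=w, value_days=3)
            for s in range(30)
        ]
        assert not any(o == "IM" for o in outcomes)
        with pytest.raises(ValueError, match="latent"):
            assign_outcome(states, gt, seed=0, value_weights=w)

    def test_empirical_mortality_matches_analytic_expectation(self, small_ground_truth):
        gt = small_ground_truth
        rng = np.random.default_rng(5)
        n = 2000
        outcomes = []
        expected = []
        for _ in range(n):
            path = simulate_state_path(gt, 8, seed=rng)
            outcomes.append(assign_outcome(path, gt, seed=rng))
            expected.append(
                expit(
                    gt.base_mortality_logit
                    + np.mean(gt.mortality_logit_per_state[path])
                )
            )
        empirical = np.mean([o == "IM" for o in outcomes])
        assert abs(empirical - np.mean(expected)) < 0.02


class TestSimulateCohort:
    def test_byte_identical_serialization_under_seed(self, tmp_path):
        conf = CohortConfig(n_patients=10, K=2, D=23)
        for run in ("a", "b"):
            eps, gt = simulate_cohort(conf, seed=1)
            write_cohort(eps, gt, tmp_path / run)
        for name in ("observations.csv", "episodes.csv", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_lengths_respect_minimum_stay(self):
        conf = CohortConfig(n_patients=300, K=2, D=23, mean_length=8.0)
        eps, _ = simulate_cohort(conf, seed=2, emit=False)
        assert len(eps) == 300
        assert min(e.length for e in eps) >= 3

    def test_length_support_below_three_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=5, mean_length=2.0)

    def test_patient_effect_is_constant_within_episode(self):
        # a huge patient offset shifts whole episodes without changing the
        # within-episode day-to-day structure
        conf = CohortConfig(
            n_patients=40, K=1, D=23, mean_length=6.0, patient_effect_sd=50.0
        )
        eps, gt = simulate_cohort(conf, seed=9, emit=False)
        within = np.mean([e.latent_daily.std(axis=0).mean() for e in eps])
        between = np.std([e.latent_daily.mean(axis=0) for e in eps], axis=0).mean()
        assert between > 10 * within

    def test_single_state_cohort_has_gaussian_marginals(self):
        conf = CohortConfig(n_patients=300, K=1, D=23, mean_length=5.0)
        eps, _ = simulate_cohort(conf, seed=3, emit=False)
        pooled = np.vstack([e.latent_daily for e in eps])
        # one Gaussian state implies Gaussian pooled marginals
        for j in range(0, 23, 5):
            assert normaltest(pooled[:, j]).pvalue > 0.01

    def test_observation_days_lie_within_episode(self, small_cohort):
        episodes, _ = small_cohort
        for e in episodes:
            days = (
                e.observations["timestamp"].dt.normalize()
                - pd.Timestamp(e.admit_date)
            ).dt.days
            assert days.min() >= 0
            assert days.max() < e.length

    def test_phenotypes_respect_cohort_constraints(self, small_cohort):
        episodes, gt = small_cohort
        for e in episodes:
            assert e.phenotype.age >= 65
            assert 1 <= e.phenotype.cfs <= 9
            assert e.phenotype.sex in ("F", "M")
            assert e.phenotype.admission_diagnosis in gt.diagnosis_codes

    def test_frames_cover_all_episodes(self, small_cohort):
        episodes, _ = small_cohort
        obs, meta = cohort_to_frames(episodes)
        assert set(obs["patient_id"]) == set(meta["patient_id"])
        assert len(meta) == len(episodes)
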