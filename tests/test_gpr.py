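"""GP continuization: grid search, posterior correctness, recovery."""

import numpy as np
import pytest

from phqtraj.cohort import ConfigurationError, SimConfig, generate_cohort
from phqtraj.gpr import (
    GprSettings,
    Hyperparams,
    UnfittablePatientError,
    default_settings,
    fit_cohort,
    fit_patient,
    grid_search_hyperparams,
    patient_series,
)
from tests.conftest import gp_loglik_oracle, gp_posterior_oracle


@pytest.fixture(scope="module")
def three_patient_obs(rng):
    obs = {}
    for i in range(3):
        t = np.sort(rng.uniform(0, 38, size=8))
        y = 10 + 4 * np.sin(t / 6.0) + rng.normal(0, 0.5, size=8)
        obs[f"p{i}"] = (t, y)
    return obs


class TestGridSearch:
    def test_single_point_grid_returned(self, three_patient_obs):
        settings = GprSettings(
            measure="phq8", length_scale_weeks=(8.0,), signal_variance=(2.0,), noise_variance=(0.5,)
        )
        hp = grid_search_hyperparams(three_patient_obs, settings)
        assert hp == Hyperparams(8.0, 2.0, 0.5)

    def test_two_point_grid_picks_higher_mean_loglik(self, three_patient_obs):
        settings = GprSettings(
            measure="phq8", length_scale_weeks=(2.0, 8.0), signal_variance=(4.0,), noise_variance=(0.5,)
        )
        means = {}
        for ls in (2.0, 8.0):
            means[ls] = np.mean(
                [gp_loglik_oracle(t, y, ls, 4.0, 0.5) for t, y in three_patient_obs.values()]
            )
        expected = max(means, key=means.get)
        hp = grid_search_hyperparams(three_patient_obs, settings)
        assert hp.length_scale_weeks == expected

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            GprSettings(measure="phq8", length_scale_weeks=())

    def test_lengthscale_recovery_from_gp_draws(self):
        # data truly drawn from a GP with length-scale 8 weeks: the grid
        # search should identify 8 among {2, 8, 32} in >= 90% of replicates
        rng = np.random.default_rng(99)
        settings = GprSettings(
            measure="phq8", length_scale_weeks=(2.0, 8.0, 32.0),
            signal_variance=(4.0,), noise_variance=(0.5,),
        )
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            obs = {}
            for i in range(3):
                t = np.sort(rng.uniform(0, 38, size=15))
                K = 4.0 * np.exp(-((t[:, None] - t[None, :]) ** 2) / (2 * 64.0))
                obs[f"p{i}"] = (t, rng.multivariate_normal(np.zeros(15), K + 0.5 * np.eye(15)))
            hp = grid_search_hyperparams(obs, settings)
            hits += hp.length_scale_weeks == 8.0
        assert hits >= 0.9 * n_rep


class TestFitPatient:
    HP = Hyperparams(length_scale_weeks=8.0, signal_variance=4.0, noise_variance=1e-8)

    def test_constant_series_fits_exactly(self):
        t = np.array([0.0, 5.0, 14.0, 30.0])
        tr = fit_patient(t, np.full(4, 5.0), self.HP, measure="phq8")
        np.testing.assert_allclose(tr.mean, 5.0, atol=1e-6)

    def test_interpolation_limit(self):
        # observations at grid times, noise -> 0: posterior interpolates
        t = np.array([0.0, 10.0, 20.0, 30.0, 38.0])
        y = np.array([3.0, 7.0, 12.0, 9.0, 4.0])
        tr = fit_patient(t, y, self.HP, measure="phq8")
        for ti, yi in zip(t, y):
            idx = int(np.where(tr.grid_weeks == ti)[0][0]) if ti in tr.grid_weeks else None
            if idx is not None:
                assert abs(tr.mean[idx] - yi) < 1e-6

    def test_posterior_mean_matches_matrix_oracle(self):
        hp = Hyperparams(length_scale_weeks=6.0, signal_variance=3.0, noise_variance=0.4)
        t = np.array([1.0, 6.0, 15.0, 22.0, 35.0])
        y = np.array([4.0, 9.0, 11.0, 6.0, 3.0])
        tr = fit_patient(t, y, hp, measure="phq8", clip=False)
        oracle = gp_posterior_oracle(t, y, tr.grid_weeks, 6.0, 3.0, 0.4)
        np.testing.assert_allclose(tr.mean, oracle, atol=1e-8)

    def test_loglik_matches_closed_form(self):
        hp = Hyperparams(8.0, 2.0, 0.3)
        t = np.array([0.0, 4.0, 11.0, 25.0, 33.0])
        y = np.array([1.0, 2.5, 2.0, 0.5, 1.5])
        tr = fit_patient(t, y, hp, measure="item9")
        assert tr.loglik == pytest.approx(gp_loglik_oracle(t, y, 8.0, 2.0, 0.3), abs=1e-8)

    def test_means_clipped_to_legal_range(self):
        hp = Hyperparams(2.0, 36.0, 0.01)
        t = np.array([0.0, 2.0, 4.0, 36.0, 38.0])
        y = np.array([24.0, 0.0, 24.0, 0.0, 24.0])
        tr = fit_patient(t, y, hp, measure="phq8")
        assert tr.mean.min() >= 0.0 and tr.mean.max() <= 24.0
        tr9 = fit_patient(t, y / 8.0, hp, measure="item9")
        assert tr9.mean.min() >= 0.0 and tr9.mean.max() <= 3.0

    def test_single_observation_unfittable(self):
        with pytest.raises(UnfittablePatientError):
            fit_patient(np.array([3.0]), np.array([5.0]), self.HP)

    def test_posterior_sd_smaller_near_observations(self):
        hp = Hyperparams(4.0, 4.0, 0.25)
        t = np.array([0.0, 2.0, 4.0, 6.0])
        y = np.array([5.0, 6.0, 5.5, 6.5])
        tr = fit_patient(t, y, hp, measure="phq8")
        # sd at an observed grid time <= sd at the farthest grid point
        assert tr.sd[0] <= tr.sd[-1]
        assert tr.sd[1] <= tr.sd[-1]


class TestFitCohort:
    def test_rmse_beats_observation_noise(self):
        # patients with >= 10 visits and smooth latent curves: posterior
        # RMSE against the noiseless latent beats the observation noise
        rmses = []
        hp = None
        for seed in range(5):
            cfg = SimConfig(n_patients=8, noise_sd=0.5, seed=seed)
            visits, _, truth = generate_cohort(cfg)
            series = patient_series(visits, "phq8")
            keep = {p for p, (t, y) in series.items() if len(y) >= 10}
            if hp is None:
                hp = grid_search_hyperparams(
                    {p: series[p] for p in keep}, default_settings("phq8")
                )
            for tr in fit_cohort(visits, "phq8", hp, patient_ids=keep):
                latent = truth.patients[tr.patient_id].phq8_latent_grid
                rmses.append(float(np.sqrt(np.mean((tr.mean - latent) ** 2))))
        assert np.mean(rmses) < 0.5

    def test_constant_item9_fit_is_exactly_constant(self):
        # all-zero ideation series must come back exactly flat, so the
        # patient lands in the degenerate-CCF exclusion downstream
        cfg = SimConfig(n_patients=6, item9_zero_prob=1.0, noise_sd=0.3, seed=4)
        visits, _, _ = generate_cohort(cfg)
        hp = Hyperparams(8.0, 0.5, 0.1)
        for tr in fit_cohort(visits, "item9", hp):
            assert float(np.std(tr.mean)) == 0.0
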