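"""Residuals, constant-ϵ per-arm fits, and the joint dynamic-ϵ fit."""

import numpy as np
import pytest

from pdl1dyn import (
    BaseParams,
    TherapyDataset,
    fit_constant_eps,
    fit_dynamic_eps,
    integrate,
    residuals,
    standard_schedule,
)

P = BaseParams()


def _dataset_from_constant_truth(arm: str, eps_true: float, days=(0.0, 4, 8, 12, 16, 20)):
    traj = integrate(P, standard_schedule(arm), eps=eps_true, horizon=max(days))
    v = np.maximum(traj.volume_at(np.asarray(days)), np.finfo(float).tiny)
    return TherapyDataset(arm, np.asarray(days, float), v)


class TestTherapyDataset:
    def test_validation(self):
        with pytest.raises(ValueError, match="nondecreasing"):
            TherapyDataset("a", [3.0, 1.0], [10.0, 20.0])
        with pytest.raises(ValueError, match="duplicate"):
            TherapyDataset("a", [1.0, 1.0], [10.0, 20.0])
        with pytest.raises(ValueError, match="positive"):
            TherapyDataset("a", [1.0, 2.0], [10.0, 0.0])

    def test_include_mask_controls_n(self):
        d = TherapyDataset("a", [0.0, 1, 2], [1.0, 2, 3], include=[True, False, True])
        assert d.n == 2
        np.testing.assert_array_equal(d.observed_days, [0.0, 2.0])


class TestResiduals:
    def test_self_sampled_data_gives_zero(self):
        traj = integrate(P, standard_schedule("a"), eps=10.0, horizon=20.0)
        days = np.array([0.0, 5.0, 10.0, 20.0])
        data = TherapyDataset("a", days, traj.volume_at(days))
        np.testing.assert_allclose(residuals(traj, data), 0.0, atol=1e-9)

    def test_single_point_difference(self):
        traj = integrate(P, standard_schedule("a"), eps=10.0, horizon=5.0)
        v = traj.volume_at([5.0])[0]
        data = TherapyDataset("a", [5.0], [v - 10.0])
        np.testing.assert_allclose(residuals(traj, data), [10.0], rtol=1e-9)

    def test_log_scale_residuals(self):
        traj = integrate(P, standard_schedule("a"), eps=10.0, horizon=5.0)
        v = traj.volume_at([5.0])[0]
        data = TherapyDataset("a", [5.0], [v / np.e])
        np.testing.assert_allclose(residuals(traj, data, scale="log"), [1.0], rtol=1e-9)
        with pytest.raises(ValueError, match="scale"):
            residuals(traj, data, scale="sqrt")

    def test_observation_outside_span_rejected(self):
        traj = integrate(P, standard_schedule("a"), eps=10.0, horizon=5.0)
        data = TherapyDataset("a", [8.0], [100.0])
        with pytest.raises(ValueError, match="span"):
            residuals(traj, data)

    def test_noise_variance_recovered(self, rng):
        """RSS/n on noisy arms estimates sigma^2 (in volume units)."""
        traj = integrate(P, standard_schedule("a"), eps=60.0, horizon=20.0)
        days = np.array([4.0, 8, 12, 16, 20])
        true_v = traj.volume_at(days)
        ratios = []
        for _ in range(150):
            noisy = true_v + 25.0 * rng.standard_normal(days.size)
            data = TherapyDataset("a", days, noisy)
            ratios.append(np.mean(residuals(traj, data) ** 2))
        assert np.mean(ratios) == pytest.approx(25.0**2, rel=0.2)


class TestFitConstantEps:
    def test_noiseless_recovery(self):
        for arm, eps_true in [("a", 60.0), ("d", 1.5)]:
            data = _dataset_from_constant_truth(arm, eps_true)
            fit = fit_constant_eps(data, P, restarts=6, seed=0)
            assert fit.converged and fit.k == 1
            assert fit.params["eps"] == pytest.approx(eps_true, rel=0.01)
            assert fit.total_rss < 1.0

    def test_low_eps_recovery(self):
        """Small true propensities are recovered too (near-zero regime)."""
        data = _dataset_from_constant_truth("a", 0.01)
        fit = fit_constant_eps(data, P, bounds=(0.0, 100.0), restarts=6, seed=0)
        assert fit.params["eps"] == pytest.approx(0.01, abs=0.01)

    def test_eps_ordering_identifiable(self):
        """Datasets from two eps levels yield estimates in the same order."""
        lo = fit_constant_eps(_dataset_from_constant_truth("a", 30.0), P, restarts=4, seed=0)
        hi = fit_constant_eps(_dataset_from_constant_truth("a", 120.0), P, restarts=4, seed=0)
        assert lo.params["eps"] < hi.params["eps"]

    def test_empty_dataset_rejected(self):
        d = TherapyDataset("a", [0.0, 4.0], [100.0, 150.0], include=[False, False])
        with pytest.raises(ValueError, match="no included observations"):
            fit_constant_eps(d, P)

    def test_seed_determinism(self):
        data = _dataset_from_constant_truth("b", 250.0)
        f1 = fit_constant_eps(data, P, restarts=5, seed=11)
        f2 = fit_constant_eps(data, P, restarts=5, seed=11)
        assert f1.params == f2.params
        assert f1.per_therapy_rss == f2.per_therapy_rss

    def test_median_recovery_under_multiplicative_noise(self):
        """Median eps-hat over seeded noisy replicates stays near eps_true."""
        from pdl1dyn import ExperimentDesign, NoiseModel, generate_arm

        eps_true = 60.0
        design = ExperimentDesign(variant="constant", constant_eps={"a": eps_true})
        design.arms = {"a": standard_schedule("a")}
        estimates = []
        for rep in range(20):
            data = generate_arm(design, "a", NoiseModel(sigma=0.1, seed=1000 + rep))
            estimates.append(fit_constant_eps(data, P, restarts=3, seed=rep).params["eps"])
        assert np.median(estimates) == pytest.approx(eps_true, rel=0.15)

    def test_rss_matches_independent_resimulation(self):
        """Reported RSS equals the SSE recomputed from the returned eps."""
        data = _dataset_from_constant_truth("b", 250.0)
        noisy = TherapyDataset("b", data.days, data.volumes * 1.07)
        fit = fit_constant_eps(noisy, P, restarts=4, seed=2)
        eps_hat = fit.params["eps"]
        traj = integrate(P, standard_schedule("b"), eps=eps_hat, horizon=20.0, rtol=1e-10)
        rss_check = float(np.sum(residuals(traj, noisy) ** 2))
        assert fit.per_therapy_rss["b"] == pytest.approx(rss_check, rel=1e-3)


class TestFitDynamicEps:
    def test_missing_arm_named_in_error(self, noiseless_dynamic_experiment):
        _, datasets, _ = noiseless_dynamic_experiment
        partial = {k: v for k, v in datasets.items() if k != "d"}
        with pytest.raises(ValueError, match="'d'"):
            fit_dynamic_eps(partial, P, restarts=1, seed=0)

    def test_all_zero_bounds_degenerate_to_frozen_eps(self, noiseless_dynamic_experiment):
        """With every parameter pinned at 0, the fit is the eps=0 base model."""
        _, datasets, _ = noiseless_dynamic_experiment
        bounds = {k: (0.0, 0.0) for k in ("k_basal", "K_V", "alpha_A1", "alpha_A2", "d_eps")}
        fit = fit_dynamic_eps(datasets, P, bounds=bounds, restarts=1, seed=0)
        assert fit.converged
        assert all(v == 0.0 for v in fit.params.values())
        traj = integrate(P, standard_schedule("a"), eps=0.0, horizon=20.0)
        data = datasets["a"]
        rss_const0 = float(np.sum(residuals(traj, data) ** 2))
        assert fit.per_therapy_rss["a"] == pytest.approx(rss_const0, rel=1e-4)

    def test_pooled_rss_is_sum_of_arms(self, noiseless_dynamic_experiment):
        _, datasets, _ = noiseless_dynamic_experiment
        bounds = {k: (0.0, 0.0) for k in ("k_basal", "K_V", "alpha_A1", "alpha_A2", "d_eps")}
        fit = fit_dynamic_eps(datasets, P, bounds=bounds, restarts=1, seed=0)
        assert fit.total_rss == pytest.approx(sum(fit.per_therapy_rss.values()))
        assert fit.k == 5
        assert set(fit.n_per_therapy) == set("abcdef")
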