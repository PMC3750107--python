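"""LP estimator: transition matrices, slack-variable L1 program, pipeline."""

import numpy as np
import pytest

from odespline.basis import SplineBasis, uniform_knot_vector
from odespline.lp_estimator import (
    TransitionMatrices,
    estimate_linear,
    solve_lp,
    transition_matrices,
)
from odespline.smoother import SmoothingConfig, smooth_experiment, solve_smoothing_qp
from odespline.synthetic import make_benchmark_dataset, simulation_call_count


@pytest.fixture(scope="module")
def smoothed_clean(enzyme_model, enzyme_clean):
    exp = enzyme_clean.experiments[0]
    return smooth_experiment(
        exp, SmoothingConfig(lam=0.0),
        balance=enzyme_model.mass_balance(exp.initial_state),
    )


class TestTransitionMatrices:
    def test_first_matrix_is_zero(self, enzyme_model, smoothed_clean):
        tm = transition_matrices(enzyme_model, smoothed_clean)
        np.testing.assert_array_equal(tm.psi[0], 0.0)

    def test_constant_state_closed_form(self, enzyme_model):
        times = np.linspace(0, 4, 9)
        const = np.array([0.7, 0.4, 0.2, 0.1])
        sm = solve_smoothing_qp(
            times, np.tile(const, (9, 1)), SmoothingConfig(lam=0.0, n_basis=5)
        )
        tm = transition_matrices(enzyme_model, sm)
        phi_c = enzyme_model.phi(const)
        for j, t in enumerate(times):
            np.testing.assert_allclose(tm.psi[j], phi_c * t, atol=1e-10)

    def test_integrated_prediction_tracks_true_trajectory(
        self, enzyme_model, enzyme_clean, smoothed_clean
    ):
        exp = enzyme_clean.experiments[0]
        tm = transition_matrices(enzyme_model, smoothed_clean)
        pred = tm.psi @ enzyme_model.nominal_params + smoothed_clean.x0
        assert np.abs(pred - exp.clean).max() <= 1e-3

    def test_refinement_validated(self, enzyme_model, smoothed_clean):
        with pytest.raises(ValueError):
            transition_matrices(enzyme_model, smoothed_clean, refine=0)


class TestSolveLp:
    def test_planted_consistent_system_recovered_exactly(
        self, enzyme_model, smoothed_clean
    ):
        tm = transition_matrices(enzyme_model, smoothed_clean)
        theta_star = np.array([0.3, 0.15, 0.4])
        x0 = smoothed_clean.x0
        y = tm.psi @ theta_star + x0[None, :]
        res = solve_lp(tm, y, x0, (np.zeros(3), np.full(3, np.inf)))
        assert res.objective == pytest.approx(0.0, abs=1e-7)
        np.testing.assert_allclose(res.theta_hat, theta_star, atol=1e-7)

    def test_matches_dense_grid_search_l1_oracle(self, rng):
        """Brute-force oracle: minimize the weighted L1 misfit over a dense
        theta grid on small random instances."""
        for _ in range(5):
            n_t, n_s, k = 7, 2, 2
            times = np.linspace(0, 1, n_t)
            increments = rng.uniform(-0.5, 0.5, size=(n_t - 1, n_s, k))
            psi = np.concatenate(
                [np.zeros((1, n_s, k)), np.cumsum(increments, axis=0)]
            )
            theta_star = rng.uniform(0.1, 0.9, k)
            x0 = rng.uniform(0, 1, n_s)
            y = psi @ theta_star + x0[None, :] + rng.normal(0, 0.02, (n_t, n_s))
            res = solve_lp(
                TransitionMatrices(psi=psi, times=times), y, x0,
                (np.zeros(k), np.ones(k)),
            )
            grid = np.arange(0.0, 1.0 + 1e-12, 1e-3)
            ga, gb = np.meshgrid(grid, grid, indexing="ij")
            thetas = np.stack([ga.ravel(), gb.ravel()], axis=1)
            resid = y[None, :, :] - (
                np.tensordot(thetas, psi, axes=[[1], [2]]) + x0[None, None, :]
            )
            costs = np.abs(resid).sum(axis=(1, 2))
            best = thetas[np.argmin(costs)]
            # the LP optimum must be at least as good as the best grid point,
            # and close to it (L1 optima can sit on flat faces, so location
            # agreement is only up to the valley width)
            lp_cost = np.abs(
                y - (psi @ res.theta_hat + x0[None, :])
            ).sum()
            assert lp_cost <= costs.min() + 1e-9
            assert np.abs(res.theta_hat - best).max() <= 1e-2

    def test_optimal_slacks_equal_absolute_residuals(
        self, enzyme_model, smoothed_clean, enzyme_clean
    ):
        exp = enzyme_clean.experiments[0]
        tm = transition_matrices(enzyme_model, smoothed_clean)
        res = solve_lp(
            tm, exp.observed, smoothed_clean.x0,
            enzyme_model.param_bounds,
        )
        np.testing.assert_allclose(
            res.alpha[0], np.abs(exp.observed - res.predicted[0]), atol=1e-7
        )

    def test_zero_weights_rejected(self, enzyme_model, smoothed_clean):
        tm = transition_matrices(enzyme_model, smoothed_clean)
        y = np.zeros((40, 4))
        with pytest.raises(ValueError, match="weights are zero"):
            solve_lp(tm, y, np.zeros(4), enzyme_model.param_bounds,
                     weights=np.zeros((40, 4)))

    def test_contradictory_bounds_rejected(
        self, enzyme_model, smoothed_clean
    ):
        tm = transition_matrices(enzyme_model, smoothed_clean)
        with pytest.raises(ValueError, match="contradictory"):
            solve_lp(tm, np.zeros((40, 4)), np.zeros(4),
                     (np.ones(3), np.zeros(3)))


class TestEstimateLinear:
    def test_noise_free_recovery_within_one_percent(
        self, enzyme_model, enzyme_clean
    ):
        res = estimate_linear(enzyme_model, enzyme_clean)
        rel = np.abs(res.theta_hat - enzyme_model.nominal_params) / (
            enzyme_model.nominal_params
        )
        assert rel.max() < 0.01

    def test_estimator_path_never_calls_the_simulator(
        self, enzyme_model, enzyme_clean
    ):
        before = simulation_call_count()
        estimate_linear(enzyme_model, enzyme_clean)
        assert simulation_call_count() == before

    def test_nonlinear_model_rejected(self, g1s_model, g1s_clean):
        with pytest.raises(TypeError, match="not linear"):
            estimate_linear(g1s_model, g1s_clean)

    def test_pooling_does_not_increase_variance(self, enzyme_model):
        pooled, single = [], []
        for seed in range(12):
            ds = make_benchmark_dataset("enzyme", 0.05, seed=2000 + seed)
            cfg = SmoothingConfig(lam=0.01)
            pooled.append(estimate_linear(enzyme_model, ds,
                                          config=cfg).theta_hat)
            per_exp = estimate_linear(enzyme_model, ds, config=cfg,
                                      pooled=False)
            single.append(per_exp[0].theta_hat)
        var_pooled = np.var(np.array(pooled), axis=0)
        var_single = np.var(np.array(single), axis=0)
        # statistical sanity at reduced reps: allow a small slack factor
        assert (var_pooled <= 1.5 * var_single).all()

    def test_per_experiment_mode_returns_one_result_each(
        self, enzyme_model, enzyme_clean
    ):
        results = estimate_linear(
            enzyme_model, enzyme_clean, pooled=False
        )
        assert len(results) == 4
        for res in results:
            assert res.theta_hat.shape == (3,)
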