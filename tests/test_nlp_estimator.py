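"""Collocation NLP: problem assembly, gradients, solvers, cost surfaces."""

import numpy as np
import pytest

from odespline.lp_estimator import estimate_linear
from odespline.nlp_estimator import (
    build_collocation,
    cost_surface,
    estimate_nonlinear,
    normalized_total_variation,
    solve_nlp,
)
from odespline.smoother import SmoothingConfig, solve_smoothing_qp
from odespline.synthetic import make_benchmark_dataset, simulation_call_count


@pytest.fixture(scope="module")
def small_problem():
    ds = make_benchmark_dataset("enzyme", 0.0, n_points=12, seed=3)
    from odespline.models import get_model

    return build_collocation(get_model("enzyme"), ds, n_basis=6)


class TestBuildCollocation:
    def test_near_feasible_at_smoothed_nominal_point(
        self, enzyme_model, enzyme_clean
    ):
        problem = build_collocation(enzyme_model, enzyme_clean, n_basis=20)
        coeffs = []
        for e in range(problem.n_experiments):
            sm = solve_smoothing_qp(
                problem.times[e], problem.observations[e],
                SmoothingConfig(lam=0.0, n_basis=20), bases=problem.basis,
            )
            coeffs.append(np.vstack(sm.coefficients))
        z = problem.pack(enzyme_model.nominal_params[problem.free_idx], coeffs)
        assert problem.objective(z) < 1e-3
        res = problem.dynamics_residuals(z)
        assert np.abs(res).max() < 0.05

    def test_zero_weights_zero_objective(self, enzyme_clean, enzyme_model, rng):
        problem = build_collocation(enzyme_model, enzyme_clean, weights=0.0)
        z = rng.standard_normal(problem.n_vars)
        assert problem.objective(z) == 0.0

    def test_objective_gradient_matches_finite_differences(
        self, small_problem, rng
    ):
        for _ in range(20):
            z = rng.standard_normal(small_problem.n_vars) * 0.5
            g = small_problem.objective_grad(z)
            h = 1e-6
            for i in rng.choice(small_problem.n_vars, size=5, replace=False):
                e = np.zeros(small_problem.n_vars)
                e[i] = h
                fd = (
                    small_problem.objective(z + e) - small_problem.objective(z - e)
                ) / (2 * h)
                assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_dynamics_jacobian_matches_finite_differences(
        self, small_problem, rng
    ):
        z = rng.standard_normal(small_problem.n_vars) * 0.5
        J = small_problem.dynamics_jacobian(z)
        h = 1e-6
        for i in rng.choice(small_problem.n_vars, size=10, replace=False):
            e = np.zeros(small_problem.n_vars)
            e[i] = h
            fd = (
                small_problem.dynamics_residuals(z + e)
                - small_problem.dynamics_residuals(z - e)
            ) / (2 * h)
            np.testing.assert_allclose(J[:, i], fd, rtol=1e-5, atol=1e-7)

    def test_unknown_free_parameter_rejected(self, enzyme_model, enzyme_clean):
        with pytest.raises(KeyError, match="valid names"):
            build_collocation(enzyme_model, enzyme_clean, free_params=["k9"])


class TestSolveNlp:
    def test_planted_spline_trajectory_is_zero_cost_optimum(self, enzyme_model):
        """With more basis functions than collocation points a spline can
        satisfy the dynamics *exactly* at the sample times; data generated
        from such a spline admit a feasible zero-cost optimum, which the
        solver must retain."""
        from scipy.optimize import least_squares

        ds = make_benchmark_dataset("enzyme", 0.0, n_points=10, seed=4,
                                    n_experiments=2)
        theta_star = enzyme_model.nominal_params
        helper = build_collocation(enzyme_model, ds, n_basis=14,
                                   free_params=[])
        coeffs0 = [
            np.vstack(
                solve_smoothing_qp(
                    helper.times[e], helper.observations[e],
                    SmoothingConfig(lam=1e-6, n_basis=14),
                    bases=helper.basis,
                ).coefficients
            )
            for e in range(helper.n_experiments)
        ]
        sol = least_squares(
            lambda z: helper.dynamics_residuals(z),
            helper.pack(np.empty(0), coeffs0),
            jac=lambda z: helper.dynamics_jacobian(z),
            method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        assert np.abs(helper.dynamics_residuals(sol.x)).max() < 1e-10
        _, planted = helper.split(sol.x)
        synthetic = tuple(
            helper.B[e] @ planted[e].T for e in range(helper.n_experiments)
        )
        planted_problem = build_collocation(
            enzyme_model, _replace_observations(ds, synthetic), n_basis=14
        )
        z_star = planted_problem.pack(theta_star, planted)
        assert planted_problem.objective(z_star) <= 1e-12
        res = solve_nlp(
            planted_problem,
            options={
                "theta0": theta_star,
                "init_coeffs": [c.copy() for c in planted],
                "mu_schedule": (10, 1e3, 1e6),
            },
        )
        assert res.objective <= 1e-8
        np.testing.assert_allclose(res.theta_hat, theta_star, rtol=2e-2)

    def test_enzyme_cross_method_agreement_with_lp(
        self, enzyme_model, enzyme_clean
    ):
        lp = estimate_linear(enzyme_model, enzyme_clean)
        nlp = estimate_nonlinear(enzyme_model, enzyme_clean, n_basis=26)
        rel = np.abs(nlp.theta_hat - lp.theta_hat) / lp.theta_hat
        assert rel.max() < 0.02

    def test_solver_free_guarantee(self, enzyme_model, enzyme_clean):
        before = simulation_call_count()
        estimate_nonlinear(enzyme_model, enzyme_clean, n_basis=13)
        assert simulation_call_count() == before

    def test_objective_invariant_to_experiment_order(
        self, enzyme_model, enzyme_clean, rng
    ):
        problem = build_collocation(enzyme_model, enzyme_clean, n_basis=8)
        reversed_ds = _reorder_experiments(enzyme_clean)
        problem_r = build_collocation(enzyme_model, reversed_ds, n_basis=8)
        theta = rng.uniform(0.1, 0.3, 3)
        coeffs = [rng.standard_normal((4, 8)) for _ in range(4)]
        z = problem.pack(theta, coeffs)
        z_r = problem_r.pack(theta, coeffs[::-1])
        assert problem.objective(z) == pytest.approx(problem_r.objective(z_r))

    def test_recovery_improves_with_basis_size(self, enzyme_model, enzyme_clean):
        errors = []
        for nb in (13, 20, 26):
            res = estimate_nonlinear(enzyme_model, enzyme_clean, n_basis=nb)
            rel = np.abs(res.theta_hat - enzyme_model.nominal_params) / (
                enzyme_model.nominal_params
            )
            errors.append(rel.max())
        assert errors[-1] < errors[0]
        assert errors[-1] < 0.02

    def test_sres_is_seed_deterministic_and_reports_diagnostics(
        self, enzyme_model
    ):
        ds = make_benchmark_dataset("enzyme", 0.0, n_points=12, seed=5)
        problem = build_collocation(enzyme_model, ds, n_basis=6)
        opts = {"generations": 5, "n_parents": 5, "n_offspring": 20}
        a = solve_nlp(problem, method="sres", options=opts, seed=9)
        b = solve_nlp(problem, method="sres", options=opts, seed=9)
        np.testing.assert_array_equal(a.theta_hat, b.theta_hat)
        assert a.diagnostics["method"] == "sres"
        assert a.diagnostics["generations"] == 5

    def test_unknown_method_rejected(self, small_problem):
        with pytest.raises(ValueError, match="unknown method"):
            solve_nlp(small_problem, method="newton")


@pytest.fixture(scope="module")
def tiny_dataset():
    return make_benchmark_dataset("enzyme", 0.0, n_points=15, seed=6)


class TestCostSurface:
    def test_p0_minimum_at_nominal(self, enzyme_model, tiny_dataset):
        ka = np.linspace(0.1, 0.3, 5)
        kb = np.linspace(0.1, 0.3, 5)
        s = cost_surface(enzyme_model, tiny_dataset, ("k1", "k2"), ka, kb, "p0")
        assert s.argmin() == (pytest.approx(0.2, abs=0.06),
                              pytest.approx(0.2, abs=0.06))

    def test_p3_cost_at_nominal_not_above_neighbors(
        self, enzyme_model, tiny_dataset
    ):
        ka = np.array([0.12, 0.18, 0.24])
        kb = np.array([0.14, 0.20, 0.26])
        s = cost_surface(enzyme_model, tiny_dataset, ("k1", "k2"), ka, kb,
                         "p3", n_basis=10)
        assert s.cost[1, 1] <= s.cost.min() + 1e-9

    def test_unknown_formulation_rejected(self, enzyme_model, tiny_dataset):
        with pytest.raises(ValueError, match="p0.*p3|formulation"):
            cost_surface(enzyme_model, tiny_dataset, ("k1", "k2"),
                         [0.1], [0.1], "p5")

    def test_total_variation_scores_cliff_above_bowl(self):
        from odespline.nlp_estimator import CostSurface

        g = np.linspace(0, 1, 21)
        xx, yy = np.meshgrid(g, g, indexing="ij")
        bowl = CostSurface(("a", "b"), g, g, (xx - 0.5) ** 2 + (yy - 0.5) ** 2,
                           "p3")
        cliff_cost = np.where(np.abs(xx - 0.5) < 0.1, 1e-9, 1e9)
        cliff = CostSurface(("a", "b"), g, g, cliff_cost, "p0")
        assert normalized_total_variation(bowl) < normalized_total_variation(
            cliff
        )


def _replace_observations(dataset, new_obs):
    from dataclasses import replace

    exps = tuple(
        replace(exp, observed=np.asarray(o), clean=np.asarray(o))
        for exp, o in zip(dataset.experiments, new_obs)
    )
    from dataclasses import replace as rep

    return rep(dataset, experiments=exps)


def _reorder_experiments(dataset):
    from dataclasses import replace

    return replace(dataset, experiments=tuple(reversed(dataset.experiments)))
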