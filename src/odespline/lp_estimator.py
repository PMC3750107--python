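"""L1 linear-programming estimator for linear-in-parameter ODE models.

For models ``xdot = Phi(x) theta`` the integrated dynamics are affine in
theta:

    x(t_j) = ( integral_{t0}^{t_j} Phi(x(t)) dt ) theta + x0
           = Psi_j theta + x0.

Replacing x(t) by the smoothed spline trajectory xhat(t) makes the
transition matrices Psi_j computable once by quadrature, after which the
weighted L1 misfit between observations and ``Psi_j theta + xhat_0`` is
minimized by a standard slack-variable linear program

    min_{theta, alpha} sum_ij w_ij alpha_ij
    s.t.  -alpha_ij <= y_i(t_j) - (Psi_j theta + xhat_0)_i <= alpha_ij,
          alpha >= 0,  theta_L <= theta <= theta_U.

No ODE solver is invoked anywhere on this path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import linprog

from .models import LinearInParamsModel
from .smoother import SmoothedStates, SmoothingConfig, default_lambda, smooth_experiment
from .synthetic import TimeCourseSet

__all__ = [
    "TransitionMatrices",
    "LpResult",
    "transition_matrices",
    "solve_lp",
    "estimate_linear",
]


@dataclass(frozen=True)
class TransitionMatrices:
    """Cumulative integrals Psi_j of Phi along the smoothed trajectory."""

    psi: np.ndarray  # (N, n, k); psi[0] == 0
    times: np.ndarray


def transition_matrices(
    model: LinearInParamsModel,
    smoothed: SmoothedStates,
    times=None,
    refine: int = 10,
) -> TransitionMatrices:
    """Integrate Phi(xhat(t)) cumulatively from t0 to each sample time.

    Each inter-sample interval is covered by composite Simpson quadrature
    on a ``2 * refine + 1``-point subgrid; the spline is exactly evaluable
    anywhere, so refinement costs only arithmetic.
    """
    if refine < 1:
        raise ValueError("refine must be >= 1")
    times = smoothed.times if times is None else np.asarray(times, dtype=float)
    n, k = model.n_states, model.n_params
    psi = np.zeros((times.size, n, k))
    acc = np.zeros((n, k))
    for j in range(times.size - 1):
        sub = np.linspace(times[j], times[j + 1], 2 * refine + 1)
        states = smoothed.evaluate(sub)  # (2r+1, n)
        phis = np.stack([model.phi(x) for x in states])
        acc = acc + simpson(phis, x=sub, axis=0)
        psi[j + 1] = acc
    return TransitionMatrices(psi=psi, times=times)


@dataclass(frozen=True)
class LpResult:
    """Solution of the slack-variable LP."""

    theta_hat: np.ndarray
    objective: float
    alpha: tuple  # per experiment, (N, n) optimal slacks
    predicted: tuple  # per experiment, (N, n) x-tilde = Psi_j theta + x0
    param_names: tuple = ()


def solve_lp(
    psi: Sequence[TransitionMatrices],
    observations: Sequence[np.ndarray],
    x0_hat: Sequence[np.ndarray],
    bounds,
    weights: Optional[Sequence[np.ndarray]] = None,
    param_names: tuple = (),
) -> LpResult:
    """Solve P2 for one or several pooled experiments sharing theta.

    Parameters are lists over experiments: transition matrices, observed
    (N, n) matrices, initial-state estimates, and optional (N, n) weight
    matrices (default all ones).  ``bounds`` is the pair (theta_L,
    theta_U); entries may be infinite.
    """
    if isinstance(psi, TransitionMatrices):
        psi = [psi]
        observations = [observations]
        x0_hat = [x0_hat]
        weights = None if weights is None else [weights]
    n_exp = len(psi)
    k = psi[0].psi.shape[2]
    lo, hi = bounds
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (k,))
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (k,))
    if np.any(lo > hi):
        raise ValueError("contradictory parameter bounds (lower > upper)")

    if weights is None:
        weights = [np.ones_like(np.asarray(observations[e])) for e in range(n_exp)]
    w_all = np.concatenate([np.asarray(w, dtype=float).ravel() for w in weights])
    if np.all(w_all == 0):
        raise ValueError("all LP weights are zero: objective is degenerate")

    blocks_M, blocks_r = [], []
    sizes = []
    for e in range(n_exp):
        y = np.asarray(observations[e], dtype=float)
        n_samples, n_states = y.shape
        # rows ordered time-major then state: index (j, i) -> j * n + i
        M = psi[e].psi.reshape(n_samples * n_states, k)
        r = (y - np.asarray(x0_hat[e], dtype=float)[None, :]).ravel()
        blocks_M.append(M)
        blocks_r.append(r)
        sizes.append(n_samples * n_states)
    M = np.vstack(blocks_M)
    r = np.concatenate(blocks_r)
    n_res = M.shape[0]

    # variables z = [theta, alpha]; constraints r - M theta <= alpha and
    # -(r - M theta) <= alpha
    eye = np.eye(n_res)
    a_ub = np.block([[-M, -eye], [M, -eye]])
    b_ub = np.concatenate([-r, r])
    c = np.concatenate([np.zeros(k), w_all])
    var_bounds = [(lo[i], None if np.isinf(hi[i]) else hi[i]) for i in range(k)]
    var_bounds += [(0, None)] * n_res
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=var_bounds, method="highs")
    if res.status == 2:
        raise RuntimeError(
            "LP infeasible: with free slack variables this can only happen "
            "for contradictory parameter bounds"
        )
    if res.status != 0:
        raise RuntimeError(f"LP solver failed: {res.message}")
    theta = res.x[:k]
    alpha_flat = res.x[k:]
    alphas, preds = [], []
    pos = 0
    for e in range(n_exp):
        y = np.asarray(observations[e], dtype=float)
        a = alpha_flat[pos : pos + sizes[e]].reshape(y.shape)
        pred = psi[e].psi @ theta + np.asarray(x0_hat[e], dtype=float)[None, :]
        alphas.append(a)
        preds.append(pred)
        pos += sizes[e]
    return LpResult(
        theta_hat=theta,
        objective=float(res.fun),
        alpha=tuple(alphas),
        predicted=tuple(preds),
        param_names=tuple(param_names),
    )


def estimate_linear(
    model: LinearInParamsModel,
    dataset: TimeCourseSet,
    config: Optional[SmoothingConfig] = None,
    refine: int = 10,
    pooled: bool = True,
    weights=None,
):
    """Full LP pipeline: smooth -> transition matrices -> slack LP.

    Smoothing imposes the model's mass balance when defined; the penalty
    weight defaults to the noise-calibrated lookup.  With ``pooled`` (the
    default) all experiments enter one LP with a shared theta and
    per-experiment xhat_0 and Psi; otherwise a result per experiment is
    returned.
    """
    if getattr(model, "phi", None) is None:
        raise TypeError(f"model {model.name!r} is not linear in its parameters")
    if config is None:
        config = SmoothingConfig(lam=default_lambda(dataset.noise_level))
    psis, obs, x0s = [], [], []
    for exp in dataset.experiments:
        balance = model.mass_balance(exp.initial_state) if model.mass_balance else None
        smoothed = smooth_experiment(exp, config=config, balance=balance)
        psis.append(transition_matrices(model, smoothed, refine=refine))
        obs.append(exp.observed)
        x0s.append(smoothed.x0)
    if pooled:
        return solve_lp(
            psis, obs, x0s, model.param_bounds, weights=weights,
            param_names=model.param_names,
        )
    return [
        solve_lp(
            psis[e], obs[e], x0s[e], model.param_bounds,
            weights=None if weights is None else weights[e],
            param_names=model.param_names,
        )
        for e in range(len(psis))
    ]
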