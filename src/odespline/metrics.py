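"""Fitness measures and the Monte-Carlo benchmarking harness.

The headline fitness measure is the relative squared error (RSE)

    J = (1 / (N n)) sum_i sum_j ((xhat_i(t_j) - x_i(t_j)) / x_i(t_j))^2

between the trajectory of an inferred model (re-simulated from the
estimated parameters and the true initial state) and the noise-free
truth.  Points where the truth is numerically zero are excluded from both
the sum and the count — the enzyme benchmark starts with no complex and
no product, so the raw ratio is undefined there.

``run_trials`` repeats dataset generation -> estimation -> scoring over
independent noise realizations and aggregates per-parameter means and
standard deviations, the shape in which benchmark recovery statistics are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .models import OdeModel, get_model
from .synthetic import make_benchmark_dataset, simulate

__all__ = ["rse", "relative_error", "run_trials", "TrialStatistics"]


def rse(estimated, truth, zero_tol: float = 1e-8) -> float:
    """Relative squared error J between trajectory matrices.

    Both arguments are (N, n); ``truth`` must be noise-free.  Per state,
    points with ``|truth| < zero_tol * max_j |truth|`` are excluded.
    Raises if every point of some all-zero comparison is excluded.
    """
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimated.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: {estimated.shape} vs {truth.shape}"
        )
    total, count = 0.0, 0
    for i in range(truth.shape[1]):
        col = truth[:, i]
        eps = zero_tol * np.abs(col).max()
        mask = np.abs(col) >= max(eps, 1e-300)
        total += float(np.sum(((estimated[mask, i] - col[mask]) / col[mask]) ** 2))
        count += int(mask.sum())
    if count == 0:
        raise ValueError("all points excluded (truth is identically ~0); J undefined")
    return total / count


def relative_error(theta_hat, theta_nominal):
    """Elementwise |theta_hat - theta| / |theta|.

    Entries with zero nominal value fall back to absolute error; the
    returned mask flags them.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    theta_nominal = np.asarray(theta_nominal, dtype=float)
    zero = theta_nominal == 0.0
    out = np.empty_like(theta_hat)
    out[~zero] = np.abs(theta_hat[~zero] - theta_nominal[~zero]) / np.abs(
        theta_nominal[~zero]
    )
    out[zero] = np.abs(theta_hat[zero])
    return out, zero


@dataclass(frozen=True)
class TrialStatistics:
    """Per-parameter recovery statistics over repeated noisy trials."""

    param_names: tuple
    mean: np.ndarray
    std: np.ndarray
    mean_rse: float
    std_rse: float
    n_trials: int
    n_failed: int
    noise_level: float
    base_seed: int
    estimates: np.ndarray  # (n_ok, k) per-trial estimates
    rse_values: np.ndarray


def run_trials(
    estimator: Callable,
    model_name: str,
    noise_level: float,
    n_trials: int = 200,
    base_seed: int = 0,
    n_experiments: int = 4,
    n_points: int = 40,
    compute_rse: bool = True,
) -> TrialStatistics:
    """Monte-Carlo benchmark of an estimator on a registered model.

    ``estimator(model, dataset) -> theta_hat array`` is called once per
    trial on a freshly noised dataset (sub-seeded deterministically from
    ``base_seed``).  When ``compute_rse`` is set, the inferred model is
    re-simulated from the true initial states and scored with J against
    the noise-free trajectories.  Failed trials are recorded and excluded,
    never silently dropped.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    model = get_model(model_name)
    root = np.random.SeedSequence(base_seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_trials)]
    estimates, rses = [], []
    n_failed = 0
    for seed in seeds:
        try:
            dataset = make_benchmark_dataset(
                model_name, noise_level, n_experiments=n_experiments,
                n_points=n_points, seed=seed,
            )
            theta = np.asarray(estimator(model, dataset), dtype=float)
            if compute_rse:
                js = []
                for exp in dataset.experiments:
                    est = simulate(model, theta, exp.initial_state, exp.times)
                    js.append(rse(est, exp.clean))
                rses.append(float(np.mean(js)))
            estimates.append(theta)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if not estimates:
        raise RuntimeError(f"all {n_trials} trials failed")
    estimates = np.vstack(estimates)
    have_rse = bool(rses)
    rses = np.asarray(rses) if have_rse else np.full(len(estimates), np.nan)
    ddof = 0 if len(estimates) < 2 else 1
    return TrialStatistics(
        param_names=model.param_names,
        mean=estimates.mean(axis=0),
        std=estimates.std(axis=0, ddof=ddof) if len(estimates) > 1
        else np.zeros(estimates.shape[1]),
        mean_rse=float(np.mean(rses)) if have_rse else float("nan"),
        std_rse=float(np.std(rses, ddof=ddof))
        if have_rse and len(estimates) > 1 else 0.0,
        n_trials=n_trials,
        n_failed=n_failed,
        noise_level=float(noise_level),
        base_seed=base_seed,
        estimates=estimates,
        rse_values=rses,
    )
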