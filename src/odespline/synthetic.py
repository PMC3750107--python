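"""Artificial benchmark datasets: simulate a model, then corrupt it.

The study conditions emulated here: four time courses per benchmark, 40
uniformly spaced samples each, all states observed, multiplicative
zero-mean Gaussian noise at a stated level (0%, 5%, 10%).  Noise is
relative, ``y = x * (1 + level * z)`` with z standard normal, so a "10%
noise level" means the same thing for states that differ by orders of
magnitude.  An additive per-state-amplitude mode is available for
comparison.

This module is the only place the package integrates ODEs during
estimation workflows (the estimators themselves are solver-free); every
integration increments :data:`SIMULATION_CALLS` so tests can assert that
guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .models import OdeModel, get_model

__all__ = [
    "Experiment",
    "TimeCourseSet",
    "simulate",
    "add_noise",
    "make_benchmark_dataset",
    "simulation_call_count",
]

#: Running count of ODE integrations performed by :func:`simulate`.
SIMULATION_CALLS = 0


def simulation_call_count() -> int:
    return SIMULATION_CALLS


@dataclass(frozen=True)
class Experiment:
    """One time course: initial state, sampling grid, clean and noisy data."""

    initial_state: np.ndarray
    times: np.ndarray
    clean: np.ndarray  # (N, n) noise-free states
    observed: np.ndarray  # (N, n) noisy observations

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.clean.shape != self.observed.shape or self.clean.shape[0] != len(
            self.times
        ):
            raise ValueError("clean/observed shapes inconsistent with times")


@dataclass(frozen=True)
class TimeCourseSet:
    """A collection of experiments from one model at one noise level."""

    model_name: str
    experiments: tuple
    noise_level: float
    seed: int | None = None
    state_names: tuple = field(default=())

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)


def simulate(model: OdeModel, params, x0, times, rtol=1e-10, atol=1e-12):
    """High-accuracy solution of the model ODE sampled at ``times``.

    Returns an (N, n) array.  Used only for data generation and for
    re-simulating fitted models when scoring them; never inside an
    estimator's optimization loop.
    """
    global SIMULATION_CALLS
    times = np.asarray(times, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    params = np.asarray(params, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    SIMULATION_CALLS += 1
    if times.size == 1:
        return x0[None, :].copy()
    sol = solve_ivp(
        lambda t, x: model.rhs(x, params),
        (times[0], times[-1]),
        x0,
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        jac=(lambda t, x: model.jac_state(x, params)) if model.jac_state else None,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration of {model.name!r} failed ({sol.message}) "
            f"at x0={x0.tolist()}, params={params.tolist()}"
        )
    return sol.y.T


def add_noise(clean, level, seed, mode="relative"):
    """Perturb a clean trajectory matrix with Gaussian noise.

    relative mode: ``observed = clean * (1 + level * z)``;
    additive mode: ``observed = clean + level * amplitude_i * z`` with
    ``amplitude_i = max_j |clean[j, i]|`` per state.  Deterministic given
    the seed; level 0 returns the input exactly.
    """
    clean = np.asarray(clean, dtype=float)
    if level < 0:
        raise ValueError(f"noise level must be nonnegative, got {level}")
    if level == 0:
        return clean.copy()
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(clean.shape)
    if mode == "relative":
        return clean * (1.0 + level * z)
    elif mode == "additive":
        amplitude = np.abs(clean).max(axis=0, keepdims=True)
        return clean + level * amplitude * z
    raise ValueError(f"unknown noise mode {mode!r}")


def make_benchmark_dataset(
    model_name,
    noise_level,
    n_experiments=4,
    n_points=40,
    seed=0,
    horizon=None,
    noise_mode="relative",
    initial_states=None,
) -> TimeCourseSet:
    """Simulate a registered benchmark and perturb it with noise.

    Each experiment gets ``n_points`` uniform samples over the model's
    default horizon and its own noise draw (sub-seeded from ``seed``).
    Initial states cycle through the model's defaults when more
    experiments than defaults are requested.
    """
    model = get_model(model_name)
    if n_points < 4:
        raise ValueError(
            f"n_points={n_points} is too few to fit a cubic spline; need >= 4"
        )
    t0, tN = horizon if horizon is not None else model.default_horizon
    times = np.linspace(t0, tN, n_points)
    if initial_states is None:
        initial_states = model.default_initial_states
    root = np.random.SeedSequence(seed)
    subseeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_experiments)]
    experiments = []
    for e in range(n_experiments):
        x0 = np.asarray(initial_states[e % len(initial_states)], dtype=float)
        clean = simulate(model, model.nominal_params, x0, times)
        observed = add_noise(clean, noise_level, subseeds[e], mode=noise_mode)
        experiments.append(
            Experiment(initial_state=x0, times=times, clean=clean, observed=observed)
        )
    return TimeCourseSet(
        model_name=model_name,
        experiments=tuple(experiments),
        noise_level=float(noise_level),
        seed=seed,
        state_names=model.state_names,
    )
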