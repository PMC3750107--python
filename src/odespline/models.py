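"""Benchmark ODE models and the model abstraction.

Two systems-biology benchmarks are shipped:

``enzyme``
    The classic four-state enzyme kinetic scheme
    S + E <-> ES -> E + P with rate constants (k1, k2, k3).  Its right-hand
    side is *linear in the parameters*, ``xdot = Phi(x) theta``, and obeys
    two mass-balance laws (total enzyme and total substrate material are
    conserved), which makes it the natural target for the LP estimator.

``g1s``
    The mammalian G1/S cell-cycle transition network (Swat-type model):
    nine species (pRB, E2F1, cyclin D inactive/active, AP-1, singly and
    doubly phosphorylated pRB, cyclin E inactive/active) coupled through
    Michaelis-Menten and Hill-type regulation terms; 39 tabulated kinetic
    constants plus the basal AP-1 production rate F_m.  Nonlinear in the
    parameters, so it exercises the collocation NLP.

The G1/S right-hand side is defined once symbolically; value and Jacobian
functions (w.r.t. state and parameters) are generated from that single
definition, so gradients used by the collocation estimator are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import sympy as sp

__all__ = [
    "OdeModel",
    "LinearInParamsModel",
    "enzyme_rhs",
    "enzyme_phi",
    "enzyme_mass_balance",
    "g1s_rhs",
    "ENZYME_PARAM_NAMES",
    "G1S_PARAM_NAMES",
    "G1S_PARAM_ALIASES",
    "get_model",
    "list_models",
]


@dataclass(frozen=True)
class OdeModel:
    """An autonomous ODE model ``xdot = f(x, theta)`` with metadata.

    ``rhs(x, theta, u=None)`` accepts a state vector of shape (n,) or a
    stack of states (n, T) and returns derivatives of matching shape.  The
    input slot ``u`` is kept for generality; both benchmarks are
    autonomous.  ``jac_state`` / ``jac_params`` return the exact Jacobians
    df/dx (n x n) and df/dtheta (n x k) at a single state.
    """

    name: str
    state_names: tuple
    param_names: tuple
    rhs: Callable
    nominal_params: np.ndarray
    param_bounds: tuple
    default_initial_states: tuple
    default_horizon: tuple
    jac_state: Optional[Callable] = None
    jac_params: Optional[Callable] = None

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __post_init__(self):
        lo, hi = self.param_bounds
        nominal = np.asarray(self.nominal_params, dtype=float)
        if np.any(nominal < np.asarray(lo)) or np.any(nominal > np.asarray(hi)):
            raise ValueError(f"nominal parameters of {self.name!r} violate bounds")

    def param_index(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown parameter {name!r} for model {self.name!r}; "
                f"valid names: {', '.join(self.param_names)}"
            ) from None


@dataclass(frozen=True)
class LinearInParamsModel(OdeModel):
    """ODE model linear in its parameters: ``xdot = Phi(x) theta``.

    ``phi(x)`` returns the n x k regressor matrix.  ``mass_balance(x0)``
    returns the conservation-law pair ``(A_eq, b_eq)`` with
    ``A_eq @ x(t) == b_eq`` along any exact trajectory started at x0, or
    is None when the model has no stated balance.
    """

    phi: Optional[Callable] = None
    mass_balance: Optional[Callable] = None


# ---------------------------------------------------------------------------
# Enzyme kinetic model: x = (S, E, ES, P), theta = (k1, k2, k3)
# ---------------------------------------------------------------------------

ENZYME_PARAM_NAMES = ("k1", "k2", "k3")
ENZYME_STATE_NAMES = ("S", "E", "ES", "P")
ENZYME_NOMINAL = np.array([0.18, 0.20, 0.23])


def enzyme_rhs(state, params, u=None):
    """Derivatives of the enzyme scheme; accepts (4,) or (4, T) states."""
    state = np.asarray(state, dtype=float)
    if state.shape[0] != 4:
        raise ValueError(f"enzyme state must have 4 components, got {state.shape}")
    k1, k2, k3 = np.asarray(params, dtype=float)
    s, e, es, _ = state
    binding = k1 * e * s
    return np.stack(
        [
            -binding + k2 * es,
            -binding + (k2 + k3) * es,
            binding - (k2 + k3) * es,
            k3 * es + np.zeros_like(s),
        ]
    )


def enzyme_phi(state):
    """Regressor matrix Phi(x) with Phi(x) @ (k1,k2,k3) == enzyme_rhs(x)."""
    s, e, es, _ = np.asarray(state, dtype=float)
    z = 0.0
    return np.array(
        [
            [-s * e, es, z],
            [-s * e, es, es],
            [s * e, -es, -es],
            [z, z, es],
        ]
    )


def enzyme_mass_balance(x0):
    """Conservation laws: total enzyme E+ES and total material S+ES+P."""
    x0 = np.asarray(x0, dtype=float)
    a_eq = np.array([[0.0, 1.0, 1.0, 0.0], [1.0, 0.0, 1.0, 1.0]])
    return a_eq, a_eq @ x0


def _enzyme_jac_state(state, params):
    s, e, es, _ = np.asarray(state, dtype=float)
    k1, k2, k3 = np.asarray(params, dtype=float)
    return np.array(
        [
            [-k1 * e, -k1 * s, k2, 0.0],
            [-k1 * e, -k1 * s, k2 + k3, 0.0],
            [k1 * e, k1 * s, -(k2 + k3), 0.0],
            [0.0, 0.0, k3, 0.0],
        ]
    )


def _enzyme_jac_params(state, params):
    return enzyme_phi(state)


# Initial conditions are not tabulated in the benchmark description; these
# four give distinct mass-balance invariants and clearly excited transients.
ENZYME_INITIAL_STATES = (
    np.array([1.0, 0.5, 0.0, 0.0]),
    np.array([0.8, 0.6, 0.0, 0.0]),
    np.array([1.2, 0.4, 0.0, 0.0]),
    np.array([0.6, 0.8, 0.0, 0.0]),
)


# ---------------------------------------------------------------------------
# Mammalian G1/S transition network (9 states, 40 parameters incl. F_m)
# ---------------------------------------------------------------------------

G1S_STATE_NAMES = (
    "pRB", "E2F1", "CycDi", "CycDa", "AP1", "pRBp", "pRBpp", "CycEi", "CycEa",
)

G1S_PARAM_NAMES = (
    "k1", "k2", "k3", "k16", "k34", "k43", "k61", "k67", "k76",
    "k23", "k25", "k28", "k89", "k98", "a",
    "J11", "J12", "J15", "J18", "J61", "J62", "J65", "J68", "J13", "J63",
    "Km1", "Km2", "Km4", "Km9", "kp",
    "phi1", "phi2", "phi3", "phi4", "phi5", "phi6", "phi7", "phi8", "phi9",
    "Fm",
)

#: Published tables of this model sometimes label the CycE activation /
#: deactivation rates k_39 / k_96; structurally (mirroring the CycD module's
#: k34/k43) they are k89 and k98.
G1S_PARAM_ALIASES = {"k39": "k89", "k96": "k98", "Kp": "kp"}

G1S_NOMINAL = np.array(
    [
        1.0, 1.6, 0.05, 0.4, 0.04, 0.01, 0.3, 0.7, 0.1,
        0.3, 0.9, 0.06, 0.07, 0.01, 0.04,
        0.5, 5.0, 0.001, 0.6, 5.0, 8.0, 6.0, 7.0, 0.002, 2.0,
        0.5, 4.0, 0.3, 0.005, 0.05,
        0.005, 0.1, 0.023, 0.03, 0.01, 0.06, 0.04, 0.06, 0.05,
        # F_m: basal AP-1 production; no tabulated value, default k_p / 10.
        0.005,
    ]
)


def _build_g1s_functions():
    xs = sp.symbols("x1:10", positive=True)
    x1, x2, x3, x4, x5, x6, x7, x8, x9 = xs
    ths = sp.symbols(G1S_PARAM_NAMES, positive=True)
    (k1, k2, k3, k16, k34, k43, k61, k67, k76,
     k23, k25, k28, k89, k98, a,
     J11, J12, J15, J18, J61, J62, J65, J68, J13, J63,
     Km1, Km2, Km4, Km9, kp,
     p1, p2, p3, p4, p5, p6, p7, p8, p9,
     Fm) = ths

    f = sp.Matrix(
        [
            k1 * x2 / (Km1 + x2) * J11 / (J11 + x1) * J61 / (J61 + x6)
            - k16 * x1 * x4 + k61 * x6 - p1 * x1,
            kp
            + k2 * (a**2 + x2**2) / (Km2**2 + x2**2)
            * J12 / (J12 + x1) * J62 / (J62 + x6)
            - p2 * x2,
            k3 * x5
            + k23 * x2 * J13 / (J13 + x1) * J63 / (J63 + x6)
            + k43 * x4 - k34 * x3 * x4 / (Km4 + x4) - p3 * x3,
            k34 * x3 * x4 / (Km4 + x4) - k43 * x4 - p4 * x4,
            Fm + k25 * x2 * J15 / (J15 + x1) * J65 / (J65 + x6) - p5 * x5,
            k16 * x1 * x4 - k61 * x6 - k67 * x6 * x9 + k76 * x7 - p6 * x6,
            k67 * x6 * x9 - k76 * x7 - p7 * x7,
            k28 * x2 * J18 / (J18 + x1) * J68 / (J68 + x6)
            + k98 * x9 - k89 * x8 * x9 / (Km9 + x9) - p8 * x8,
            k89 * x8 * x9 / (Km9 + x9) - k98 * x9 - p9 * x9,
        ]
    )
    rhs_fn = sp.lambdify((xs, ths), f, modules="numpy")
    jac_x_fn = sp.lambdify((xs, ths), f.jacobian(xs), modules="numpy")
    jac_th_fn = sp.lambdify((xs, ths), f.jacobian(ths), modules="numpy")
    return rhs_fn, jac_x_fn, jac_th_fn


_G1S_RHS, _G1S_JAC_X, _G1S_JAC_TH = _build_g1s_functions()


def _check_g1s_params(params):
    params = np.asarray(params, dtype=float)
    if params.shape[-1] != len(G1S_PARAM_NAMES) and params.shape[0] != len(
        G1S_PARAM_NAMES
    ):
        raise ValueError(
            f"g1s parameter vector must have {len(G1S_PARAM_NAMES)} entries"
        )
    # Michaelis and J constants sit in denominators; zero or negative values
    # make the vector field singular on the positive orthant.
    names = G1S_PARAM_NAMES
    for i, name in enumerate(names):
        if (name.startswith("J") or name.startswith("Km")) and params[i] <= 0:
            raise ValueError(f"g1s constant {name} must be positive, got {params[i]}")
    return params


def g1s_rhs(state, params, u=None):
    """Derivatives of the G1/S network; accepts (9,) or (9, T) states."""
    state = np.asarray(state, dtype=float)
    if state.shape[0] != 9:
        raise ValueError(f"g1s state must have 9 components, got {state.shape}")
    params = _check_g1s_params(params)
    out = _G1S_RHS(tuple(state), tuple(params))
    out = np.asarray(out, dtype=float)
    # lambdified Matrix output is (9, 1) for vector states, (9, 1, T) stacked
    return out.reshape((9,) + state.shape[1:])


def _g1s_jac_state(state, params):
    return np.asarray(
        _G1S_JAC_X(tuple(np.asarray(state, float)), tuple(np.asarray(params, float))),
        dtype=float,
    )


def _g1s_jac_params(state, params):
    return np.asarray(
        _G1S_JAC_TH(tuple(np.asarray(state, float)), tuple(np.asarray(params, float))),
        dtype=float,
    )


# Four positive starting states spanning low and high E2F1/pRB regimes so the
# transition dynamics (and hence k1, k2) are well excited.
G1S_INITIAL_STATES = (
    np.array([1.0, 0.10, 0.10, 0.05, 0.10, 0.10, 0.05, 0.10, 0.05]),
    np.array([0.5, 0.20, 0.20, 0.10, 0.20, 0.20, 0.10, 0.20, 0.10]),
    np.array([1.5, 0.05, 0.05, 0.20, 0.30, 0.05, 0.20, 0.05, 0.20]),
    np.array([0.8, 0.30, 0.15, 0.15, 0.15, 0.30, 0.15, 0.15, 0.15]),
)


def _make_enzyme_model() -> LinearInParamsModel:
    return LinearInParamsModel(
        name="enzyme",
        state_names=ENZYME_STATE_NAMES,
        param_names=ENZYME_PARAM_NAMES,
        rhs=enzyme_rhs,
        nominal_params=ENZYME_NOMINAL.copy(),
        # the benchmark search region is [0, +inf)
        param_bounds=(np.zeros(3), np.full(3, np.inf)),
        default_initial_states=ENZYME_INITIAL_STATES,
        # 40 uniform samples over [0, 20] resolve the complex-equilibration
        # time 1/(k1*S + k2 + k3) ~ 1.6 while covering substantial turnover
        default_horizon=(0.0, 20.0),
        jac_state=_enzyme_jac_state,
        jac_params=_enzyme_jac_params,
        phi=enzyme_phi,
        mass_balance=enzyme_mass_balance,
    )


def _make_g1s_model() -> OdeModel:
    nominal = G1S_NOMINAL.copy()
    return OdeModel(
        name="g1s",
        state_names=G1S_STATE_NAMES,
        param_names=G1S_PARAM_NAMES,
        rhs=g1s_rhs,
        nominal_params=nominal,
        # evolutionary search region used for this benchmark: [0, 50 theta]
        param_bounds=(np.zeros(nominal.size), 50.0 * nominal),
        default_initial_states=G1S_INITIAL_STATES,
        default_horizon=(0.0, 200.0),
        jac_state=_g1s_jac_state,
        jac_params=_g1s_jac_params,
    )


_REGISTRY = {"enzyme": _make_enzyme_model, "g1s": _make_g1s_model}
_CACHE: dict = {}


def list_models() -> tuple:
    return tuple(sorted(_REGISTRY))


def get_model(name: str) -> OdeModel:
    """Look a benchmark model up by name ('enzyme' or 'g1s')."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown model {name!r}; registered models: {', '.join(list_models())}"
        )
    if name not in _CACHE:
        _CACHE[name] = _REGISTRY[name]()
    return _CACHE[name]
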