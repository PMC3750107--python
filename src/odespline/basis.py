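"""B-spline bases for trajectory approximation.

State trajectories x_i(t) of an ODE model are represented as spline
expansions ``x_i(t) = b_i(t)^T p_i`` where ``b_i`` is a vector of B-spline
basis functions defined by the Cox-de Boor recursion on a clamped knot
vector, and ``p_i`` are free coefficients.  Because the basis is fixed,
values and derivatives of the trajectory at any set of times are *linear*
in the coefficients; the evaluation matrices built here are the workhorse
of both the penalized smoother and the collocation estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "KnotVector",
    "SplineBasis",
    "BasisMatrices",
    "cox_de_boor",
    "uniform_knot_vector",
    "basis_matrices",
    "default_n_basis",
]


@dataclass(frozen=True)
class KnotVector:
    """A nondecreasing knot sequence together with the spline degree.

    Parameters
    ----------
    knots : array-like
        Nondecreasing real times ``tau_0 <= tau_1 <= ... <= tau_{L-1}``.
        For a clamped vector the first and last knots each repeat
        ``degree + 1`` times.
    degree : int
        Polynomial degree of the basis (cubic by default throughout the
        package).
    """

    knots: np.ndarray
    degree: int

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        object.__setattr__(self, "knots", knots)
        if self.degree < 0:
            raise ValueError("degree must be nonnegative")
        if knots.ndim != 1 or knots.size < self.degree + 2:
            raise ValueError(
                f"need at least degree + 2 = {self.degree + 2} knots, "
                f"got {knots.size}"
            )
        if np.any(np.diff(knots) < 0):
            raise ValueError("knots must be nondecreasing")

    @property
    def n_basis(self) -> int:
        """Number of basis functions (admissible indices of the recursion)."""
        return self.knots.size - self.degree - 1

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])


def cox_de_boor(knot_vector: KnotVector, m: int, degree: int, t: float) -> float:
    """Evaluate the single basis function ``b_{m,degree}(t)`` recursively.

    Degree 0 is the half-open indicator of the knot span
    ``[tau_m, tau_{m+1})``; higher degrees blend two lower-degree functions
    with the convention that any 0/0 weight is treated as 0.  Times outside
    the knot span return 0 (including the right endpoint, which under the
    half-open convention belongs to no span; the matrix builders below use
    the standard clamped convention there instead).

    Intended as the definitional reference; use :func:`basis_matrices` for
    bulk evaluation.
    """
    knots = knot_vector.knots
    L = knots.size
    if not 0 <= m <= L - degree - 2:
        raise IndexError(
            f"basis index m={m} out of range [0, {L - degree - 2}] "
            f"for degree {degree} on {L} knots"
        )
    if degree == 0:
        return 1.0 if knots[m] <= t < knots[m + 1] else 0.0
    left = 0.0
    denom = knots[m + degree] - knots[m]
    if denom > 0.0:
        left = (t - knots[m]) / denom * cox_de_boor(knot_vector, m, degree - 1, t)
    right = 0.0
    denom = knots[m + degree + 1] - knots[m + 1]
    if denom > 0.0:
        right = (
            (knots[m + degree + 1] - t)
            / denom
            * cox_de_boor(knot_vector, m + 1, degree - 1, t)
        )
    return left + right


def uniform_knot_vector(
    t0: float, tN: float, n_basis: int, degree: int = 3
) -> KnotVector:
    """Clamped knot vector with equally spaced interior knots on [t0, tN].

    Yields exactly ``n_basis`` basis functions; requires
    ``n_basis >= degree + 1`` (the single-span Bezier case).
    """
    if tN <= t0:
        raise ValueError(f"need tN > t0, got [{t0}, {tN}]")
    if n_basis < degree + 1:
        raise ValueError(
            f"n_basis={n_basis} too small: a degree-{degree} clamped basis "
            f"needs at least {degree + 1} basis functions"
        )
    breakpoints = np.linspace(t0, tN, n_basis - degree + 1)
    knots = np.concatenate(
        [np.full(degree, t0), breakpoints, np.full(degree, tN)]
    )
    return KnotVector(knots=knots, degree=degree)


def default_n_basis(n_samples: int, degree: int = 3, fraction: float = 1 / 3) -> int:
    """Default basis size: about a third of the sample count.

    Empirically a basis of N/3 to N/2 functions balances flexibility
    against noise amplification for N-point time courses; the default sits
    at the lower (smoother) end, clamped to the feasible range
    ``[degree + 1, n_samples]``.
    """
    return int(np.clip(round(n_samples * fraction), degree + 1, n_samples))


@dataclass(frozen=True)
class SplineBasis:
    """A fixed B-spline basis: knot vector plus cached scipy evaluators."""

    knot_vector: KnotVector
    _splines: tuple = field(repr=False, compare=False, default=())

    def __post_init__(self) -> None:
        kv = self.knot_vector
        splines = []
        eye = np.eye(kv.n_basis)
        for m in range(kv.n_basis):
            splines.append(BSpline(kv.knots, eye[m], kv.degree, extrapolate=False))
        object.__setattr__(self, "_splines", tuple(splines))

    @property
    def n_basis(self) -> int:
        return self.knot_vector.n_basis

    @property
    def degree(self) -> int:
        return self.knot_vector.degree

    @property
    def domain(self) -> tuple[float, float]:
        return self.knot_vector.domain

    def _check_times(self, times: np.ndarray) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        lo, hi = self.domain
        tol = 1e-12 * max(1.0, abs(hi - lo))
        if times.min() < lo - tol or times.max() > hi + tol:
            raise ValueError(
                f"evaluation times outside basis domain [{lo}, {hi}]"
            )
        return np.clip(times, lo, hi)

    def design_matrix(self, times: np.ndarray, deriv: int = 0) -> np.ndarray:
        """(len(times), n_basis) matrix of basis values or derivatives.

        Derivatives use the exact degree-lowering identity (via scipy's
        spline differentiation), never finite differences.  The right
        endpoint is evaluated as the limit from the left, the standard
        clamped-spline convention.
        """
        times = self._check_times(times)
        cols = []
        for spline in self._splines:
            s = spline.derivative(deriv) if deriv else spline
            vals = s(times)
            # scipy returns nan beyond the last knot for extrapolate=False;
            # clipping above makes the endpoint itself well defined.
            cols.append(np.nan_to_num(vals, nan=0.0))
        return np.column_stack(cols)


@dataclass(frozen=True)
class BasisMatrices:
    """Value and first-derivative evaluation matrices on a time grid."""

    B: np.ndarray
    dB: np.ndarray
    times: np.ndarray


def basis_matrices(basis: SplineBasis, times: np.ndarray) -> BasisMatrices:
    """Evaluate ``B[j, m] = b_m(t_j)`` and ``dB[j, m] = db_m/dt (t_j)``."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    return BasisMatrices(
        B=basis.design_matrix(times, deriv=0),
        dB=basis.design_matrix(times, deriv=1),
        times=times,
    )
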