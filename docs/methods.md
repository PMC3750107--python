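# Methods

## Problem

Given noisy multi-state time courses `y(t_j) = x(t_j) + noise` from a
kinetic ODE model `dx/dt = f(x, θ)` with known structure, estimate the
rate constants θ. Direct ("shooting") estimation integrates the ODE at
every candidate θ; the integrator dominates run time and the resulting
cost surface is a narrow curved ridge that traps optimizers. Both
estimators here avoid integration entirely by representing each state as
a B-spline expansion `x̂_i(t) = b_i(t)ᵀ p_i`, whose values and
derivatives at any time are linear in the coefficients `p_i`.

## Spline representation

Clamped uniform B-spline bases (Cox–de Boor recursion; degree 3 by
default) are used throughout. The cubic default is the field standard
compatible with a second-derivative roughness penalty; it is not varied
in the benchmarks. The number of basis functions per state defaults to
about N/3 for N samples (the range N/3–N/2 works well; more basis
functions fit sharper transients, fewer resist noise). Derivative
matrices come from the exact degree-lowering identity, never finite
differences. At the right endpoint the basis is evaluated as the limit
from the left (standard clamped convention); the literal recursion's
half-open degree-0 indicator is exposed separately as the definitional
reference. The basis count follows the standard convention (number of
admissible recursion indices, L − degree − 1 for L knots).

## Penalized smoothing (stage 1 of the LP route)

Spline coefficients are fit to one experiment's observations by
minimizing

    (1/(N+1)) Σ_j ‖y(t_j) − x̂(t_j)‖² + λ Σ_j ‖x̂^(m)(t_j)‖²

subject to optional linear mass-balance constraints `A_eq x̂(t_j) = b_eq`
at every sample time. With m ≤ degree this is a convex equality-
constrained QP solved exactly through its KKT system (the constraint
rows are rank-reduced implicitly by a least-squares solve; the fitted
trajectory is itself a spline, so satisfying the balance at N ≥ n_basis
sample times pins it along the whole interval). Defaults: m = 2 and a
noise-calibrated penalty λ = 0, 0.01, 0.03 at 0%, 5%, 10% relative
noise, linearly interpolated and capped at 0.05. The penalty sums
squared m-th derivatives at the sample times, as in the smoothing
criterion the benchmarks prescribe, rather than integrating them.

The smoothed value at t₀ is used downstream as the initial-state
estimate x̂₀; re-estimating x₀ inside the LP was tried and does not help
(it only absorbs offsets, while the dominant error is a slowly varying
drift).

## LP estimator (linear-in-parameter models)

For models `dx/dt = Φ(x) θ` the integrated dynamics are affine in θ:
`x(t_j) = Ψ_j θ + x₀` with `Ψ_j = ∫ Φ(x(t)) dt` from t₀ to t_j.
Replacing x by the smoothed spline makes Ψ̂_j computable once by
composite Simpson quadrature (each sampling interval refined 10-fold;
the spline is exactly evaluable anywhere, so refinement is essentially
free; a trapezoid fallback would lose ~2 digits). The weighted L1 misfit
between observations and `Ψ̂_j θ + x̂₀` is then minimized by the
standard slack-variable linear program (two-sided slack encoding of the
absolute value; solved with HiGHS). Weights default to 1. Parameter
bounds default to the benchmark's [0, ∞). Multiple experiments pool into
one LP with a shared θ and per-experiment Ψ̂ and x̂₀.

## Collocation NLP (general models)

The general estimator optimizes θ and all spline coefficients jointly:

    min_{θ,p}  Σ_e Σ_j (y − x̂)ᵀ W_j (y − x̂)
    s.t.       r_j = dx̂/dt(t_j) − f(x̂(t_j), θ) = 0 at every t_j,
               θ_L ≤ θ ≤ θ_U,

with every quantity an explicit algebraic function of (θ, p): the
objective gradient and the residual Jacobian are assembled in closed
form (model Jacobians ∂f/∂x and ∂f/∂θ are generated symbolically once
per model). Exactly zero residuals are unattainable with a finite basis,
so the local path minimizes `misfit + μ‖r‖²` by bounded Gauss–Newton
(scipy `least_squares`, TRF), with coefficients initialized from the
penalized smoother and μ ramped geometrically 10 → 100 → 1000. The ramp
stops when the residual norm reaches the spline discretization floor:
tightening μ far beyond that floor forces the trajectory to trade data
fidelity for a constraint the basis cannot represent and visibly biases
sloppy parameter directions (observed on the enzyme benchmark, where the
floor-level schedule recovers the LP solution to 0.2% but μ ≥ 1e5 drags
the estimate along the k1/k2 valley). For the enzyme cross-method check
a larger basis (about 2N/3) is used so the collocation floor sits below
the 2% comparison tolerance.

A global option is provided: a (μ, λ) evolution strategy with
stochastic ranking of (objective, Σ‖r_j‖²) pairs (comparison-by-
objective probability 0.45), log-normal self-adaptive step sizes,
parameters searched within their bounds and coefficients within a box
derived from the data range. It is seed-deterministic. Population 15/100
and 200 generations by default; the desk-scale benchmarks use the local
path, which is deterministic and orders of magnitude faster.

## Cost surfaces

For the two-parameter landscape comparison, the collocation cost at each
grid point minimizes `misfit + μ‖r‖²` (μ = 1000) over coefficients only,
every point cold-started from the same smoothed-data coefficients so the
surface is independent of sweep order; the direct cost integrates the
ODE from the true initial states (the only purpose for which the
estimator suite may invoke the simulator) and records the squared
misfit, with +inf sentinels for integration failures. Roughness is
compared by normalized total variation computed on
`log10(cost − min + δ)` (δ = 1e-6 of the finite range) rescaled to
[0, 1]: shooting surfaces span many orders of magnitude, and on a linear
scale a single 10⁹-to-0 cliff would dominate the normalization and make
the rest of the ridge look artificially flat.

## Benchmark models and study conditions

**Enzyme kinetics** (S + E ⇌ ES → E + P): four states, rates
(k1, k2, k3) = (0.18, 0.20, 0.23), linear in parameters, two conservation
laws (total enzyme, total substrate material). The artificial dataset is
four simulated courses of 40 uniform samples each. Initial conditions
(not tabulated in the benchmark description) are four substrate/enzyme
mixtures with no complex and no product, (1, 0.5, 0, 0) and variations,
giving distinct conservation totals. The horizon is [0, 20]: the
complex-equilibration time is 1/(k1·S + k2 + k3) ≈ 1.6, and 40 samples
over 20 time units let the N/3-basis spline resolve that transient
(about 3 samples per relaxation time) while still covering substantial
substrate turnover; over a [0, 50] horizon the transient falls inside a
single knot span and the spline bias alone costs 2–4% on the recovered
rates.

**G1/S transition network**: nine species, 39 tabulated constants plus
the basal AP-1 production rate F_m. F_m has no tabulated value; the
default 0.005 (k_p/10, the value in the model's original source) is a
package choice and F_m is excluded from recovery benchmarks. The
published parameter table labels the CycE activation/deactivation rates
k_39/k_96; structurally (mirroring the CycD module's k34/k43) these are
k89 = 0.07 and k98 = 0.01, and the parameter reader accepts the legacy
labels as aliases. Initial states (also untabulated) are four positive
mixtures spanning low and high E2F1/pRB regimes over a [0, 200] horizon,
which excite the G1/S switch so that k1 and k2 are identifiable.
Parameter bounds default to [0, 50·nominal], the search region used for
this benchmark.

**Noise model**: observed = clean · (1 + level·z), z i.i.d. standard
normal — multiplicative relative noise, so "10%" means the same thing
for states differing by orders of magnitude. An additive mode
(σ_i = level · per-state amplitude) is available behind a switch. The
generator is seed-deterministic, with per-experiment sub-seeds.

## Fitness and trials

The RSE `J = mean of ((x̂ − x)/x)²` is computed between the trajectory
re-simulated from the estimated parameters (true initial states,
high-accuracy integration) and the noise-free truth. Points where the
true state is numerically zero (|x| below 1e-8 of the state's maximum —
the enzyme complex and product at t₀) are excluded from both sum and
count; how the original benchmark handled those exact zeros is not
stated, so the exclusion rule is this package's choice, configurable.
The Monte-Carlo harness re-noises the data each trial with sub-seeds
derived from one base seed, records failures explicitly, and reports
per-parameter means and standard deviations. The default trial count is
200 (the headline statistics stabilize well before that; the original
study used 5,000, which the harness also supports).

## What the benchmarks do and do not show

The generator emulates idealized conditions: exact model structure,
uniform sampling, all states observed, Gaussian noise with known level.
Real data add model mismatch, partial observability and irregular
sampling; the estimators accept observation masks and any increasing
grid, but the reported recovery numbers do not speak to those regimes.

Two empirical properties of the enzyme benchmark deserve note. First,
at quasi-steady state the binding flux column of Φ is nearly collinear
with the dissociation columns, so the (k1, k2) direction is identified
only through the brief relaxation transient; noise that propagates into
the smoothed trajectory (and hence into Ψ̂) attenuates exactly that
direction, and at 10% relative noise the per-trial mean estimates of k1
and k2 sit far below nominal regardless of horizon, basis size, penalty
weight, or noise mode. This is a structural errors-in-variables effect
of the two-stage method, not a solver artifact: repeating the trials
with transition matrices built from noise-free trajectories (noise left
only in the LP's data term) removes the bias entirely. Second, the
attenuated direction is precisely the model's sloppy direction: the
trajectories re-simulated from the biased estimates still match the
truth to J ≈ 0.6% at 10% noise, so trajectory-level claims survive even
where parameter-level ones do not.

## Numerical choices and degenerate inputs

Simulation uses LSODA with rtol 1e-10/atol 1e-12 (analytic Jacobians).
Smoothing refuses rank-deficient normal equations (λ = 0 with more basis
functions than samples) and infeasible balance constraints with explicit
messages. The LP detects all-zero weights and contradictory bounds. The
collocation solver reports its μ schedule, function evaluations and a
convergence flag, and recomputes the final dynamics-residual norm
independently of the optimizer's bookkeeping. Datasets with fewer than
4 points are rejected (a cubic spline cannot be fit). Trial failures are
counted and excluded, never silent.

## Known limitations

- The LP route requires Φ(x) explicitly; no automatic detection of
  linearity in parameters.
- Parameter-level recovery under ≥5% noise is biased for near-QSS
  linear-in-parameter systems (above); trajectory-level accuracy is the
  meaningful metric there.
- The evolution strategy is a generic stochastic-ranking ES, not a tuned
  reimplementation of any specific published optimizer; full
  39-parameter G1/S searches are supported but take hours and are not
  exercised in the test suite (the tested surface is the 2-free-
  parameter configuration).
- Knot placement is uniform only; no adaptive or free-knot variants.
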