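# odespline

Spline-based parameter estimation for kinetic ODE models in systems
biology — without calling an ODE solver inside the optimization loop.

Fitting rate constants θ of a known-structure model
`dx/dt = f(x, θ)` to noisy time courses is usually done by shooting:
integrate the ODE at every candidate θ and compare. The integrator eats
most of the run time and the cost surface is a narrow curved ridge that
traps optimizers. `odespline` replaces the trajectory with a B-spline
expansion `x̂_i(t) = b_i(t)ᵀ p_i` and offers two integration-free
estimators:

- **LP route** (models linear in parameters, `dx/dt = Φ(x) θ`):
  smooth the data with a roughness-penalized, mass-balance-constrained
  spline QP; integrate Φ along the smoothed trajectory once to get
  transition matrices `Ψ̂_j = ∫ Φ(x̂) dt`, so predictions
  `Ψ̂_j θ + x̂₀` are affine in θ; minimize the weighted L1 misfit by a
  slack-variable linear program.
- **Collocation NLP** (general nonlinear models): optimize θ and the
  spline coefficients jointly, subject to algebraic dynamics residuals
  `dx̂/dt(t_j) = f(x̂(t_j), θ)` at the sample times, with closed-form
  gradients; solved by a ramped quadratic-penalty Gauss–Newton method,
  or by a stochastic-ranking evolution strategy for global search.

Two benchmark systems ship with the package: the classic enzyme
kinetic scheme S + E ⇌ ES → E + P (linear in its three rate constants,
with two conservation laws) and the nine-species mammalian G1/S
cell-cycle transition network (39 kinetic constants, Michaelis–Menten
and Hill-type regulation). A synthetic-data module simulates them and
adds multiplicative Gaussian noise at stated levels; a Monte-Carlo
harness produces per-parameter recovery statistics.

## Worked example

```python
import numpy as np
from odespline import (
    get_model, make_benchmark_dataset, estimate_linear,
    estimate_nonlinear, SmoothingConfig,
)

# Enzyme benchmark: 4 noise-free courses x 40 samples at rates
# (k1, k2, k3) = (0.18, 0.20, 0.23)
model = get_model("enzyme")
data = make_benchmark_dataset("enzyme", noise_level=0.0, seed=0)
fit = estimate_linear(model, data, config=SmoothingConfig(lam=0.0))
print(dict(zip(model.param_names, fit.theta_hat.round(5))))
# {'k1': 0.17988, 'k2': 0.19972, 'k3': 0.23002}

# G1/S network: recover k1 and k2 by collocation, all else at nominal
g1s = get_model("g1s")
data = make_benchmark_dataset("g1s", noise_level=0.0, seed=0)
fit = estimate_nonlinear(g1s, data, free_params=["k1", "k2"])
print(fit.theta_hat.round(4))   # [0.9936 1.5976]  (true: 1, 1.6)
print(round(fit.max_residual_norm, 4))  # 0.0062
```

The enzyme rates come back within 0.15% of the generating values; the
G1/S pair within 0.7%. `max_residual_norm` is the largest dynamics
residual of the fitted spline trajectory — how far the estimate is from
an exact solution of the model, independently recomputed after the
solve.

The same pipelines are scriptable from the shell:

```sh
odespline simulate --model enzyme --noise 0.1 --seed 1 --out d.tsv
odespline fit-lp   --data d.tsv --model enzyme --noise-level 0.1 --out params.tsv
odespline benchmark --model enzyme --noise 0.1 --trials 200 --seed 7 --out table.tsv
odespline cost-surface --data d.tsv --model g1s --params k1,k2 --formulation p3 --out surface.tsv
```

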