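# deltadisc

Optimal experimental designs for discriminating between two rival nonlinear
regression models, using a symmetric distance-based criterion with *flexible
nominal sets*.

## The problem

Suppose observations follow one of two candidate mean functions
η₀(θ₀, x) or η₁(θ₁, x) with independent homoscedastic errors, and an
experimenter must choose n design points from a finite design space X so that,
after the experiment, the correct model can be identified. Classical
T-optimality is asymmetric: it assumes one model is true. The criterion
implemented here treats both models symmetrically. For a design D it measures

δ_r(D) = min ‖η₀(θ₀, D) − η₁(θ₁, D)‖

over θ₀ and θ₁ ranging in *flexible nominal sets*: cuboids centred at nominal
parameter estimates with half-widths proportional to their standard errors,
dilated by a tuning parameter r ≥ 0. A δ_r-optimal design maximizes this
minimal distance. The distance is computed on models linearized at the
nominals, which turns each evaluation into a box-constrained linear
least-squares problem (the *response difference model* with regressor matrix
[F₀, −F₁]).

Key facts the package exploits and exposes:

- r = 0 recovers a simple sum of squared nominal mean differences; r = ∞ is an
  unconstrained least-squares residual. The optimal value o(r) = max_D δ_r(D)
  is nonincreasing and convex in r.
- There is a **set upper bound** r*: beyond it, enlarging the cuboids changes
  nothing. `set_upper_bound_search` finds it by chord extrapolation on o(r);
  `lp_set_upper_bound` computes (for the all-points design) the minimal r at
  which the linearized mean-value sets intersect, by linear programming —
  beyond that dilation every design has δ = 0.
- δ² is positively homogeneous under replication and concave over design
  measures, which the test suite verifies exactly.
- Monte-Carlo machinery (`hit_rate_study`) estimates the percentage of correct
  model choices by the likelihood-ratio rule (smaller residual sum of squares
  after fitting both models by bounded multistart least squares).

Two built-in problems are provided:

- `example1` — toy pair η₀ = θ₀x vs η₁ = exp(θ₁x) on a grid of [1, 2], with
  nominals θ̃₀ = e, θ̃₁ = 1 and unit cuboid half-widths;
- `enzyme` — competitive vs noncompetitive inhibition kinetics
  η = Vx₁/(K(1 + x₂/Kᵢ) + x₁) vs η = Vx₁/((K + x₁)(1 + x₂/Kᵢ)) on a grid of
  [0, 30] × [0, 40], with nominals and half-widths taken from least-squares
  estimates and standard errors of a dextromethorphan–sertraline assay.

## Worked example

```python
import numpy as np
from deltadisc import make_example1_problem, kl_exchange, set_upper_bound_search

problem = make_example1_problem(1.0, 2.0, 0.01)   # grid {1.00, 1.01, ..., 2.00}

# delta-optimal 6-point design with unconstrained parameter sets (r = infinity)
res = kl_exchange(problem, n=6, r=np.inf, n_starts=20, seed=0)
print("best design:", res.best_design.counting_view)
print(f"delta^2 at r=inf: {res.best_delta_sq:.6f}")

# smallest dilation r* beyond which enlarging the cuboids changes nothing
bound = set_upper_bound_search(problem, n=6, r_ini=0.3, q=1 + 1e-6,
                               search_params={"n_starts": 10, "seed": 0})
print(f"set upper bound r*: {bound.r_star:.4f} "
      f"({bound.n_design_computations} design computations)")
```

Output:

```
best design: [((1.0,), 2), ((1.53,), 3), ((2.0,), 1)]
delta^2 at r=inf: 0.026138
set upper bound r*: 0.6791 (13 design computations)
```

The same computations from the command line:

```bash
deltadisc design --problem example1 --n 6 --r inf --seed 0 --out design
deltadisc bound  --problem example1 --method search --n 6 --out bound.json
deltadisc bound  --problem enzyme   --method lp --out lp.json    # r* = 64.018
deltadisc evaluate --problem enzyme --auto-r 5 --n 6 -N 2000 --seed 0 --out hitrates
```

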