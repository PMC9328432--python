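# Methods

## Model and assumptions

Observations at design points x ∈ X (a finite design space) follow one of two
rival mean functions η₀(θ₀, x) or η₁(θ₁, x) with additive independent errors of
common standard deviation σ. Parameters are only trusted up to *flexible
nominal sets*: axis-aligned cuboids

Θₖ(r) = [θ̃ₖ − r·hₖ, θ̃ₖ + r·hₖ],  k = 0, 1,

centred at nominal values θ̃ₖ with half-widths hₖ (typically standard errors of
prior estimates) and a common dilation r ≥ 0. For an exact design
D = (x₁, …, xₙ) the discrimination criterion is the minimal Euclidean distance
between the two models' mean-value sets,

δ_r(D) = min { ‖η₀(θ₀, D) − η₁(θ₁, D)‖ : θₖ ∈ Θₖ(r) },

computed on the first-order Taylor expansions of both models at their
nominals. Writing Fₖ for the Jacobian of ηₖ at θ̃ₖ restricted to D and
aₖ = ηₖ(θ̃ₖ, D) − Fₖθ̃ₖ, the squared distance is the residual of a single
box-constrained linear least-squares problem in the stacked parameter
(θ₀, θ₁), with regressor matrix [F₀, −F₁] and artificial observations a₁ − a₀
(the *response difference model*). An equivalent quadratic-form representation
δ²(D | θ) = (θ − θ̃)ᵀM(θ − θ̃) + 2bᵀ(θ − θ̃) + c is kept as a cross-check; the
test suite verifies the two paths agree to 1e−9 on random inputs.

Assumptions: both models are differentiable in θ near the nominals; the
nominals satisfy the discriminability condition (the nominal means differ at
at least one design point — violation triggers a warning at problem
construction); errors are homoscedastic. The criterion itself is
variance-free; σ only enters the Monte-Carlo evaluation and the chi-square
lower bound on the probability of a correct decision,
P ≥ F_{χ²(n)}(δ²/(4σ²)).

## Components and parameter defaults

### Criterion evaluation (`criterion.py`)

Each evaluation solves the box-constrained least-squares problem with
`scipy.optimize.lsq_linear` (BVLS when the system is square-or-tall, TRF
otherwise), after eliminating coordinates whose bounds coincide (r = 0 makes
all of them coincide and is evaluated directly; r = ∞ uses an unconstrained
minimum-norm solve). The returned minimizer is clipped to the box and the
objective re-evaluated there, so the reported value is always attained by a
feasible point. A result below 1e−12 is flagged degenerate.

`exact_distance` additionally minimizes the *nonlinear* distance
‖η₀ − η₁‖ by bounded multistart `least_squares` with analytic Jacobians; it is
a diagnostic for the quality of the linearization, not part of the criterion.

### Design search (`designs.py`)

`kl_exchange` is a multistart exchange heuristic for exact designs: starting
from a random n-point design, it sweeps the trial slots in random order and
greedily replaces each point by the best candidate in the design space,
repeating until a full sweep makes no improvement; the best of `n_starts`
(default 20) seeded restarts is returned. Linearization tables are cached on
the problem at construction, so one design evaluation is a row-gather plus one
small `lsq_linear` call (≈ 0.4 ms for six points and six parameters).
`exhaustive_search` enumerates all multisets for small problems and is used by
the tests to certify the heuristic on 20 random small instances.

### Set upper bound (`bounds.py`)

`set_upper_bound_search` finds the dilation r* at which the optimal value
o(r) = max_D δ_r(D) reaches its unconstrained level o(∞). It exploits
convexity of o in r: from two visited points it extrapolates the chord to the
level o(∞) (a secant step), guarded by a 0.1 % minimum progress factor and a
doubling fallback, and stops once o(r) ≤ q·o(∞) with q = 1 + 1e−6. The
starting value defaults to r_ini = 0.3. o(0) is available in closed form
(n·max|Δη̃|² for the optimal r = 0 design), so the search needs only order-10
design computations. An earlier variant inflated the final chord by a safety
factor; pure chord extrapolation with the progress floor proved both cheaper
and tighter and is what ships.

`lp_set_upper_bound` computes, for the all-points design, the minimal r making
the linearized mean-value sets intersect — beyond it every design has δ = 0.
The LP minimizes r subject to equality of linearized responses at every grid
point and cuboid membership coupled to r; it is solved with HiGHS at
feasibility tolerances 1e−10, the equalities relaxed to ±1e−9 slack, and the
returned certificate re-verified (equality gap ≤ 1e−8 and cuboid containment)
before the status is reported `ok`. For conditionally linear models,
`conditionally_linear_feasible_point` constructs the closed-form feasible
point that zeroes the leading coefficients of both models (r = max over models
of θ̃₁/h₁), used as an independent cross-check; `zero_delta_check` verifies
δ = 0 on random designs beyond the bound.

### Monte-Carlo evaluation (`mc.py`)

`hit_rate_study` estimates the percentage of correct model choices by the
likelihood-ratio rule: simulate data from one model, fit both by bounded
multistart nonlinear least squares, choose the model with the smaller residual
sum of squares. Defaults: N = 10 000 replicates; generating parameters either
fixed at the nominals (c = 0) or drawn uniformly from nominal ± c·hₖ; error
SD σ = 0.3052 (twice the base estimate 0.1526 of the enzyme assay); fit starts
are the nominal plus 4 draws from the r = 1 cuboid (`n_starts=5` — doubling
the starts changed no decision in a 2 000-replicate check); fit boxes are the
model's admissible parameter region intersected with nominal ± 50·hₖ.

The synthetic data generator emulates assay noise in two ways. `normal` adds
i.i.d. N(0, σ²) errors. `lognormal_rescaled` emulates the positive,
right-skewed noise typical of concentration measurements: multiplicative
log-normal errors rescaled so that each observation's mean equals the model
mean *exactly* and its SD equals σ (sᵢ² = log(1 + σ²/ηᵢ²),
y = η·exp(ε − sᵢ²/2) with ε ~ N(0, sᵢ²)); it requires strictly positive model
means. Replicate RNG streams are keyed by (seed, design name, generating
model), so relabelling the two models permutes the result rows without
changing any hit rate — a symmetry the tests assert.

### Built-in problems (`models.py`)

`example1`: η₀ = θ₀x vs η₁ = exp(θ₁x), grid step 0.01 on [1, 2], nominals
e and 1, unit half-widths. `enzyme`: competitive vs noncompetitive inhibition,
nominals (7.298, 4.386, 2.582) and (8.696, 8.066, 12.057) with half-widths
(0.114, 0.233, 0.145) and (0.222, 0.488, 0.671) from least-squares fits to a
dextromethorphan–sertraline assay; default grid 61 × 41 over [0, 30] × [0, 40]
(substrate step 0.5, inhibitor step 1.0 — fine enough that the LP bound moves
by < 1 % under refinement). Parameter boxes keep V > 0, K ∈ (0, 60],
Kᵢ ∈ (0, 30]. All gradients are analytic and checked against central
differences.

## Numerical choices

- BVLS tolerance 1e−12; degenerate threshold 1e−12; LP feasibility 1e−10 with
  ±1e−9 equality slack (HiGHS rejects 1e−11); certificate re-verification at
  1e−8.
- All stochastic routines take explicit seeds; `scripts/acceptance.py` derives
  sub-seeds below 2³¹ from one master seed via `numpy.random.SeedSequence`.
- Exact-design objects canonicalize their point lists, so equal multisets
  compare equal and file round-trips are loss-free.

## Limitations

- The criterion is computed on linearized models; `exact_distance` quantifies
  the gap for a given design but no global guarantee is claimed.
- The exchange heuristic carries no optimality certificate beyond agreement
  with enumeration on small instances; increase `n_starts` for hard problems.
- The LP set upper bound applies the all-points design and is therefore an
  upper bound for every design, but the closed-form cross-check requires
  conditionally linear models.
- The chord-based bound search assumes o(r) is convex and strictly decreasing
  until it flattens; it raises an error when the models are indistinguishable
  (o(∞) = 0) rather than returning a bound.
- Monte-Carlo hit rates inherit binomial error (≈ 0.17 pt at N = 10 000 for
  rates near 98 %) plus design-search variation across seeds.
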