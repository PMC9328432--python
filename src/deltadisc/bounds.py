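"""Set upper bounds on the dilation parameter r.

Beyond some finite r* the flexible nominal sets are large enough that further
enlargement changes neither the optimal design nor the optimal criterion value
o(r) = max_D delta_r(D); any such r* is a *set upper bound*.  Two routes are
provided:

* an iterative search that exploits convexity and monotonicity of o(r) in r,
  extrapolating chords of the sampled curve down to the level o(inf) until the
  stopping rule o(r) <= q * o(inf) is met;
* a linear program over the all-points design: the minimal r for which the two
  linearized mean-value sets intersect at every design-space point.  When that
  LP is feasible, its optimum r* is a set upper bound valid for every design
  size, and o(r) = 0 for all r >= r*.  A closed-form feasible point exists
  whenever each model becomes linear after fixing a proper subset of its
  parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .criterion import _delta_sq_core
from .designs import kl_exchange
from .models import DiscriminationProblem

__all__ = [
    "BoundResult",
    "set_upper_bound_search",
    "lp_set_upper_bound",
    "conditionally_linear_feasible_point",
    "zero_delta_check",
]

#: Slack applied to the LP equality constraints (pair of inequalities) for
#: solver robustness; certificates are re-verified at 1e-8.
LP_EQUALITY_SLACK = 1e-9


@dataclass
class BoundResult:
    """A computed set upper bound with its audit trail."""

    r_star: float
    method: str                       # "search" | "lp"
    status: str                       # "ok" | "infeasible" | "failed"
    certificate: Optional[tuple[np.ndarray, np.ndarray]] = None
    trace: list = field(default_factory=list)
    n_design_computations: int = 0
    o_inf: Optional[float] = None

    def to_dict(self) -> dict:
        cert = None
        if self.certificate is not None:
            cert = [self.certificate[0].tolist(), self.certificate[1].tolist()]
        return {
            "r_star": self.r_star,
            "method": self.method,
            "status": self.status,
            "certificate": cert,
            "trace": self.trace,
            "n_design_computations": self.n_design_computations,
            "o_inf": self.o_inf,
        }


def set_upper_bound_search(
    problem: DiscriminationProblem,
    n: int,
    r_ini: float = 0.3,
    q: float = 1.0 + 1e-6,
    search_params: Optional[dict] = None,
    max_iter: int = 50,
) -> BoundResult:
    """Iteratively locate an r with o(r) <= q * o(inf).

    o(inf) is computed once by design search.  Starting from ``r_ini``, each
    iteration evaluates o(r) by design search; if the stopping rule holds the
    current r is returned.  Otherwise the chord through the last two sampled
    points of the (convex, nonincreasing) curve o(r) is extrapolated down to
    the level o(inf); by convexity the chord crossing never overshoots the
    true crossing, so the iteration approaches the bound from below, and a
    minimal relative step guarantees progress under heuristic noise in o(r).
    """
    if r_ini <= 0:
        raise ValueError("r_ini must be positive")
    if q <= 1:
        raise ValueError("q must exceed 1")
    params = dict(n_starts=10, seed=0)
    if search_params:
        params.update(search_params)

    trace = []
    res_inf = kl_exchange(problem, n, np.inf, **params)
    o_inf = np.sqrt(res_inf.best_delta_sq)
    n_comp = 1
    trace.append({"r": None, "o": float(o_inf), "note": "o(inf)"})
    if o_inf <= 0:
        raise ValueError(
            "o(inf) = 0: the linearized models are indistinguishable for every "
            "design, so r* = 0 trivially"
        )

    # o(0): delta_0^2(D) = sum of squared nominal mean differences, maximized
    # by n copies of the point with the largest |Delta eta| -- closed form.
    o_prev = float(np.sqrt(n * np.max(problem.delta_eta**2)))
    r_prev = 0.0
    trace.append({"r": 0.0, "o": o_prev, "note": "closed form"})

    r_cur = float(r_ini)
    for _ in range(max_iter):
        res = kl_exchange(problem, n, r_cur, **params)
        o_cur = np.sqrt(res.best_delta_sq)
        n_comp += 1
        trace.append({"r": r_cur, "o": float(o_cur)})
        if o_cur <= q * o_inf:
            return BoundResult(
                r_star=r_cur,
                method="search",
                status="ok",
                trace=trace,
                n_design_computations=n_comp,
                o_inf=float(o_inf),
            )
        # Chord through (r_prev, o_prev), (r_cur, o_cur) down to level o(inf).
        if o_prev - o_cur <= 0:
            r_next = 2.0 * r_cur
        else:
            r_next = r_cur + (o_cur - o_inf) * (r_cur - r_prev) / (o_prev - o_cur)
            r_next = max(r_next, r_cur * 1.001)
        r_prev, o_prev = r_cur, o_cur
        r_cur = float(r_next)
    return BoundResult(
        r_star=r_cur,
        method="search",
        status="failed",
        trace=trace,
        n_design_computations=n_comp,
        o_inf=float(o_inf),
    )


def lp_set_upper_bound(problem: DiscriminationProblem) -> BoundResult:
    """Minimal r for which the linearized mean-value sets intersect everywhere.

    Solves min r subject to F0 th0 + a0 = F1 th1 + a1 at every design-space
    point and |th_kj - nominal_kj| <= r * half_width_kj, r >= 0.  A feasible
    optimum is a set upper bound for all design sizes, with o(r) = 0 beyond it.
    """
    d = problem.n_points
    m = problem.dim_param
    rows = problem.G  # (d, 2m) = [grad0, -grad1]
    rhs = problem.z_tilde
    nv = 1 + 2 * m  # variables: r, theta0, theta1

    blocks, rhss = [], []
    # Equalities relaxed to two-sided inequalities with small slack.
    eq = np.column_stack([np.zeros(d), rows])
    blocks += [eq, -eq]
    rhss += [rhs + LP_EQUALITY_SLACK, -rhs + LP_EQUALITY_SLACK]
    # Cuboid membership coupled to r.
    box = np.zeros((4 * m, nv))
    bb = np.zeros(4 * m)
    nom, hw = problem.theta_stack, problem.hw_stack
    for j in range(2 * m):
        box[2 * j, 0] = -hw[j]
        box[2 * j, 1 + j] = 1.0
        bb[2 * j] = nom[j]
        box[2 * j + 1, 0] = -hw[j]
        box[2 * j + 1, 1 + j] = -1.0
        bb[2 * j + 1] = -nom[j]
    blocks.append(box)
    rhss.append(bb)

    A_ub = np.vstack(blocks)
    b_ub = np.concatenate(rhss)
    c = np.zeros(nv)
    c[0] = 1.0
    res = linprog(c, A_ub=A_ub, b_ub=b_ub,
                  bounds=[(0, None)] + [(None, None)] * (2 * m), method="highs",
                  options={"primal_feasibility_tolerance": 1e-10,
                           "dual_feasibility_tolerance": 1e-10})
    if res.status == 2:  # infeasible
        return BoundResult(r_star=np.inf, method="lp", status="infeasible",
                           trace=[{"lp_status": res.status, "message": res.message}])
    if not res.success:
        return BoundResult(r_star=np.inf, method="lp", status="failed",
                           trace=[{"lp_status": res.status, "message": res.message}])
    r_star = float(res.x[0])
    th0 = res.x[1:1 + m]
    th1 = res.x[1 + m:]
    # Re-verify the certificate.
    resp_gap = np.max(np.abs(rows @ res.x[1:] - rhs))
    in_cub = problem.nominal0.contains(th0, r_star, tol=1e-8) and \
        problem.nominal1.contains(th1, r_star, tol=1e-8)
    status = "ok" if (resp_gap <= 1e-8 and in_cub) else "failed"
    return BoundResult(
        r_star=r_star,
        method="lp",
        status=status,
        certificate=(th0, th1),
        trace=[{"lp_status": res.status, "max_equality_gap": float(resp_gap)}],
    )


def conditionally_linear_feasible_point(
    problem: DiscriminationProblem,
    linear_indices0: Sequence[int],
    linear_indices1: Sequence[int],
    tol: float = 1e-8,
) -> Optional[tuple[float, np.ndarray, np.ndarray]]:
    """Closed-form feasible point of the set-upper-bound LP.

    If model k is linear in the designated coefficient components once the
    remaining components are held at their nominal values, then zeroing those
    coefficients makes the linearized response vanish identically, giving an
    LP-feasible point.  Returns the smallest r whose cuboids contain both
    constructed parameter vectors (with the zero-response certificate), or
    ``None`` when the construction does not apply.
    """
    out = []
    for k, (nom_set, G, a) in enumerate(
        [(problem.nominal0, problem.G0, problem.a0),
         (problem.nominal1, problem.G1, problem.a1)]
    ):
        lin = np.zeros(problem.dim_param, dtype=bool)
        lin[list(linear_indices0 if k == 0 else linear_indices1)] = True
        theta_hat = np.where(lin, 0.0, nom_set.nominal)
        # Zero-response check: F_k theta_hat + a_k must vanish at every point.
        resp = G @ theta_hat + a
        scale = 1.0 + np.max(np.abs(G @ nom_set.nominal + a))
        if np.max(np.abs(resp)) > tol * scale:
            return None
        need = np.abs(theta_hat - nom_set.nominal)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(need > 0, need / nom_set.half_width, 0.0)
        if np.any(~np.isfinite(ratios)):
            return None  # zero half-width with nonzero required displacement
        out.append((float(np.max(ratios)), theta_hat))
    r = max(out[0][0], out[1][0])
    return r, out[0][1], out[1][1]


def zero_delta_check(
    problem: DiscriminationProblem,
    r: float,
    n_random_designs: int = 20,
    seed: Optional[int] = None,
    n: int = 6,
    tol: float = 1e-9,
) -> bool:
    """True iff delta_r^2 vanishes on a batch of random n-point designs."""
    if r < 0:
        raise ValueError("r must be nonnegative")
    rng = np.random.default_rng(seed)
    for _ in range(n_random_designs):
        idx = rng.integers(0, problem.n_points, size=n)
        if _delta_sq_core(problem, idx, float(r)).delta_sq > tol:
            return False
    return True
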