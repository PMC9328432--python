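"""Evaluation of the delta criterion for a fixed design.

Both models are linearized at their nominal values.  For a design
D = (x_1, ..., x_n) the squared criterion is

    delta_r^2(D) = min ||a0 + F0 th0 - a1 - F1 th1||^2

over th0, th1 ranging in the r-dilated nominal cuboids, where F_k stacks the
gradients of model k at its nominal and a_k = eta_k(nominal) - F_k nominal.
Equivalently, it is the restricted residual sum of squares of the *response
difference model* with regressor matrix [F0, -F1] and artificial observations
z~ = a1 - a0; with cuboid constraints this is a bounded-variable least-squares
(BVLS) problem, solved here with :func:`scipy.optimize.lsq_linear`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.optimize import least_squares, lsq_linear

from .models import DiscriminationProblem

__all__ = [
    "LinearizedPair",
    "QuadraticForm",
    "DeltaEvaluation",
    "linearize",
    "quadratic_form",
    "delta_sq_at",
    "delta_sq",
    "delta_sq_measure",
    "exact_distance",
    "correct_decision_lower_bound",
]

#: Objective tolerance for the box-constrained least-squares solver.
BVLS_TOL = 1e-12
#: delta^2 at or below this value is treated as degenerate (nonunique minimizer).
DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class LinearizedPair:
    """Gradient matrices and offsets of the two models along a design."""

    F0: np.ndarray  # (n, m)
    F1: np.ndarray  # (n, m)
    a0: np.ndarray  # (n,)
    a1: np.ndarray  # (n,)

    @property
    def z_tilde(self) -> np.ndarray:
        """Artificial observations of the response difference model."""
        return self.a1 - self.a0


@dataclass(frozen=True)
class QuadraticForm:
    """delta^2(D | theta) = (t-t~)' M (t-t~) + 2 b'(t-t~) + c with t = (th0, th1)."""

    M: np.ndarray  # (2m, 2m) information matrix of the response difference model
    b: np.ndarray  # (2m,)
    c: float       # sum of squared nominal mean differences

    def value(self, problem: DiscriminationProblem, theta0, theta1) -> float:
        d = np.concatenate([np.asarray(theta0, float), np.asarray(theta1, float)])
        d = d - problem.theta_stack
        return float(d @ self.M @ d + 2.0 * self.b @ d + self.c)


@dataclass(frozen=True)
class DeltaEvaluation:
    """Result of minimizing the linearized squared distance over the cuboids."""

    delta_sq: float
    minimizer: np.ndarray        # stacked (theta0, theta1)
    at_bound: np.ndarray         # per-coordinate active-face flags
    solver_status: str           # "converged" | "degenerate"
    r: float

    @property
    def delta(self) -> float:
        return float(np.sqrt(max(self.delta_sq, 0.0)))

    def to_dict(self) -> dict:
        return {
            "delta_sq": self.delta_sq,
            "delta": self.delta,
            "r": None if np.isinf(self.r) else self.r,
            "minimizer": self.minimizer.tolist(),
            "at_bound": self.at_bound.tolist(),
            "solver_status": self.solver_status,
        }


def linearize(problem: DiscriminationProblem, design) -> LinearizedPair:
    """Linearize both models at their nominals along the design's points."""
    idx = problem.point_indices(_design_points(design))
    return LinearizedPair(
        F0=problem.G0[idx].copy(),
        F1=problem.G1[idx].copy(),
        a0=problem.a0[idx].copy(),
        a1=problem.a1[idx].copy(),
    )


def quadratic_form(problem: DiscriminationProblem, design) -> QuadraticForm:
    idx = problem.point_indices(_design_points(design))
    return _quadratic_form_weighted(problem, idx, np.ones(len(idx)))


def _quadratic_form_weighted(problem, idx, w) -> QuadraticForm:
    G = problem.G[idx]
    de = problem.delta_eta[idx]
    M = G.T @ (G * w[:, None])
    b = G.T @ (w * de)
    c = float(np.sum(w * de**2))
    return QuadraticForm(M=M, b=b, c=c)


def _design_points(design):
    """Accept an ExactDesign, an array of points, or a list of points."""
    pts = getattr(design, "points", design)
    return np.asarray(pts, dtype=float)


def delta_sq_at(problem: DiscriminationProblem, design, theta0, theta1) -> float:
    """Squared linearized distance at a fixed parameter pair (no minimization)."""
    theta0 = np.asarray(theta0, dtype=float)
    theta1 = np.asarray(theta1, dtype=float)
    m = problem.dim_param
    if theta0.size != m or theta1.size != m:
        raise ValueError(f"parameter vectors must have length {m}")
    lin = linearize(problem, design)
    resid = lin.a0 + lin.F0 @ theta0 - lin.a1 - lin.F1 @ theta1
    return float(resid @ resid)


def _solve_box_lsq(A, z, lb, ub):
    """min ||A t - z||^2 over lb <= t <= ub; returns (t, status_converged).

    Coordinates with lb == ub are eliminated before calling the solver.
    """
    fixed = lb == ub
    t = np.where(fixed, lb, 0.0)
    if fixed.all():
        return t, True
    z_eff = z - A[:, fixed] @ lb[fixed] if fixed.any() else z
    Af = A[:, ~fixed]
    method = "bvls" if Af.shape[0] >= Af.shape[1] else "trf"
    res, ok = None, False
    try:
        res = lsq_linear(Af, z_eff, bounds=(lb[~fixed], ub[~fixed]),
                         method=method, tol=BVLS_TOL)
        ok = res.status >= 0 and np.all(np.isfinite(res.x))
    except (np.linalg.LinAlgError, ValueError):
        pass
    if not ok and method == "bvls":
        res = lsq_linear(Af, z_eff, bounds=(lb[~fixed], ub[~fixed]),
                         method="trf", tol=BVLS_TOL)
        ok = res.status >= 0
    t[~fixed] = res.x
    return t, ok


def _delta_sq_core(problem, idx, r, weights=None) -> DeltaEvaluation:
    """Minimize the weighted squared linearized distance over the r-cuboids."""
    if r < 0:
        raise ValueError("dilation r must be nonnegative")
    A = problem.G[idx]
    z = problem.z_tilde[idx]
    if weights is not None:
        sw = np.sqrt(weights)
        A = A * sw[:, None]
        z = z * sw
    nom = problem.theta_stack
    if r == 0:
        resid = A @ nom - z
        dsq = float(resid @ resid)
        return DeltaEvaluation(dsq, nom.copy(), np.zeros(nom.size, bool),
                               "degenerate" if dsq <= DEGENERATE_TOL else "converged",
                               0.0)
    if np.isinf(r):
        # Unconstrained: minimum-norm least-squares solution; delta^2 is
        # unique even when the stacked matrix is rank-deficient.
        t, *_ = np.linalg.lstsq(A, z, rcond=None)
        resid = A @ t - z
        dsq = float(resid @ resid)
        status = "degenerate" if dsq <= DEGENERATE_TOL else "converged"
        return DeltaEvaluation(dsq, t, np.zeros(t.size, bool), status, np.inf)

    lb, ub = problem.stacked_cuboid(r)
    t, ok = _solve_box_lsq(A, z, lb, ub)
    # Enforce cuboid membership exactly, then re-evaluate the objective.
    t = np.clip(t, lb, ub)
    resid = A @ t - z
    dsq = float(resid @ resid)
    scale = 1e-10 * (1.0 + np.abs(nom))
    at_bound = (np.abs(t - lb) <= scale) | (np.abs(t - ub) <= scale)
    status = "converged" if ok and dsq > DEGENERATE_TOL else "degenerate"
    return DeltaEvaluation(dsq, t, at_bound, status, float(r))


def delta_sq(problem: DiscriminationProblem, design, r: float) -> DeltaEvaluation:
    """Minimize the squared linearized distance over the r-dilated cuboids.

    ``r = 0`` evaluates at the nominals; ``r = inf`` solves the unconstrained
    least-squares problem; finite positive ``r`` uses bounded-variable least
    squares on the response difference model.
    """
    idx = problem.point_indices(_design_points(design))
    return _delta_sq_core(problem, idx, float(r))


def delta_sq_measure(problem: DiscriminationProblem, points, weights, r: float) -> float:
    """delta_r^2 for a nonnegative measure on the design space.

    Generalizes :func:`delta_sq` from counting measures (exact designs) to
    arbitrary nonnegative weights; used e.g. to examine concavity of the
    criterion over design measures.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    idx = problem.point_indices(np.asarray(points, dtype=float))
    return _delta_sq_core(problem, idx, float(r), weights=weights).delta_sq


def exact_distance(
    problem: DiscriminationProblem,
    design,
    r: float,
    n_starts: int = 10,
    seed: Optional[int] = None,
) -> float:
    """Nonlinearized minimum distance between the mean-value vectors.

    Minimizes ||(eta0(th0, x_i))_i - (eta1(th1, x_i))_i|| over the r-dilated
    cuboids by multistart bounded nonlinear least squares, initialized at the
    linearized minimizer plus random cuboid draws.  Serves as a validation
    oracle for the linearization, not as a design criterion.
    """
    if np.isinf(r):
        raise ValueError("exact_distance requires finite r")
    idx = problem.point_indices(_design_points(design))
    X = problem.design_space[idx]
    m = problem.dim_param

    def resid(t):
        return problem.model0.eta(t[:m], X) - problem.model1.eta(t[m:], X)

    def jac(t):
        return np.hstack([problem.model0.grad(t[:m], X),
                          -problem.model1.grad(t[m:], X)])

    lb, ub = problem.stacked_cuboid(r)
    # Keep strictly inside open parameter-box faces (e.g. positivity).
    box_lb = np.concatenate([problem.model0.param_box[:, 0],
                             problem.model1.param_box[:, 0]])
    box_ub = np.concatenate([problem.model0.param_box[:, 1],
                             problem.model1.param_box[:, 1]])
    eps = 1e-8 * (1.0 + np.abs(problem.theta_stack))
    lb = np.maximum(lb, box_lb + eps)
    ub = np.minimum(ub, box_ub)
    lb = np.minimum(lb, ub)  # guard against crossing after intersection

    rng = np.random.default_rng(seed)
    starts = [np.clip(_delta_sq_core(problem, idx, r).minimizer, lb, ub)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(lb, np.where(np.isfinite(ub), ub, lb + 1.0)))
    best = np.inf
    n_fail = 0
    for s in starts:
        if r == 0:
            best = min(best, float(np.linalg.norm(resid(s))))
            continue
        try:
            sol = least_squares(resid, s, jac=jac, bounds=(lb, ub))
            if sol.success:
                best = min(best, float(np.linalg.norm(sol.fun)))
            else:
                n_fail += 1
        except Exception:
            n_fail += 1
    if not np.isfinite(best):
        raise RuntimeError("all optimizer starts failed (degenerate)")
    return best


def correct_decision_lower_bound(delta_value: float, sigma: float, n: int) -> float:
    """Chi-square lower bound on the probability of a correct decision.

    The correct-decision probability under the likelihood-ratio rule is
    bounded below by P[||eps|| <= d/2] = P[chi2_n <= d^2 / (4 sigma^2)], where
    d is the distance between the two models' mean-value sets.  Here the
    linearized surrogate delta is plugged in for d, so the returned number is
    an approximation of the bound rather than a guaranteed bound.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if delta_value < 0:
        raise ValueError("delta_value must be nonnegative")
    return float(stats.chi2.cdf(delta_value**2 / (4.0 * sigma**2), df=n))
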