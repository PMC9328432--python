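"""Regression models, flexible nominal sets, and discrimination problems.

A discrimination problem pairs two rival nonlinear regression models
``y_i = eta_k(theta_k, x_i) + eps_i`` (k = 0, 1) that share the number of
parameters ``m``, together with nominal parameter values and cuboid
half-widths around them.  The cuboid dilated by a factor ``r`` is the
*flexible nominal set*: the region of parameter values the criterion has to
guard against when measuring how far apart the two mean-value surfaces are.

Two built-in problems are provided:

* ``example1`` -- the linear-vs-exponential toy pair eta0 = theta*x,
  eta1 = exp(theta*x) on a grid of the interval [1, 2];
* ``enzyme`` -- competitive vs noncompetitive inhibition kinetics, with
  nominal values and standard errors from an initial 120-run experiment on
  Dextrometorphan--Sertraline.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RegressionModel",
    "FlexibleNominalSet",
    "DiscriminationProblem",
    "make_example1_problem",
    "make_enzyme_problem",
    "check_gradient",
    "PROBLEMS",
    "ENZYME_SIGMA_HAT",
]

#: Residual standard deviation estimated from the encompassing enzyme model
#: fitted to the initial 120-observation experiment; simulation studies
#: inflate it (2x for the n=6 normal-error study, 5x for the log-normal one).
ENZYME_SIGMA_HAT = 0.1526


def _as_points(x) -> np.ndarray:
    """Coerce a point or a batch of points to a 2-d float array (npts, dim)."""
    a = np.atleast_1d(np.asarray(x, dtype=float))
    if a.ndim == 1:
        a = a[None, :]
    return a


@dataclass(frozen=True)
class RegressionModel:
    """A nonlinear regression mean function with its analytic gradient.

    ``mean(theta, X)`` and ``gradient(theta, X)`` are vectorized over design
    points: for ``X`` of shape (npts, dim_x) they return shapes (npts,) and
    (npts, m) respectively.
    """

    name: str
    mean: Callable[[np.ndarray, np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray, np.ndarray], np.ndarray]
    param_box: np.ndarray  # (m, 2) lower/upper bounds, +-inf allowed
    dim_param: int
    dim_x: int

    def __post_init__(self):
        box = np.asarray(self.param_box, dtype=float).reshape(self.dim_param, 2)
        object.__setattr__(self, "param_box", box)
        if np.any(box[:, 0] >= box[:, 1]):
            raise ValueError(f"model {self.name!r}: empty parameter box")

    def eta(self, theta, x) -> np.ndarray:
        """Mean responses at parameter ``theta`` over points ``x``."""
        theta = np.asarray(theta, dtype=float)
        return np.asarray(self.mean(theta, _as_points(x)), dtype=float)

    def grad(self, theta, x) -> np.ndarray:
        """Gradients (npts, m) of the mean in ``theta`` over points ``x``."""
        theta = np.asarray(theta, dtype=float)
        g = np.asarray(self.gradient(theta, _as_points(x)), dtype=float)
        return g.reshape(-1, self.dim_param)


@dataclass(frozen=True)
class FlexibleNominalSet:
    """A nominal parameter value with cuboid half-widths.

    ``cuboid(r)`` is the product of intervals [nominal_j - r*half_width_j,
    nominal_j + r*half_width_j]; r = 0 collapses to the nominal point and
    r = inf to all of parameter space.
    """

    nominal: np.ndarray
    half_width: np.ndarray

    def __post_init__(self):
        nom = np.asarray(self.nominal, dtype=float).ravel()
        hw = np.asarray(self.half_width, dtype=float).ravel()
        object.__setattr__(self, "nominal", nom)
        object.__setattr__(self, "half_width", hw)
        if nom.shape != hw.shape:
            raise ValueError("nominal and half_width must have equal length")
        if np.any(hw < 0) or not np.all(np.isfinite(hw)):
            raise ValueError("half-widths must be finite and nonnegative")

    @property
    def dim(self) -> int:
        return self.nominal.size

    def cuboid(self, r: float) -> tuple[np.ndarray, np.ndarray]:
        """Lower and upper bound vectors of the dilated cuboid."""
        if r < 0:
            raise ValueError("dilation r must be nonnegative")
        if np.isinf(r):
            full = np.full_like(self.nominal, np.inf)
            return -full, full
        return self.nominal - r * self.half_width, self.nominal + r * self.half_width

    def contains(self, theta, r: float, tol: float = 1e-10) -> bool:
        lb, ub = self.cuboid(r)
        theta = np.asarray(theta, dtype=float)
        scale = 1.0 + np.abs(self.nominal)
        return bool(np.all(theta >= lb - tol * scale) and np.all(theta <= ub + tol * scale))

    def sample(self, r: float, rng: np.random.Generator) -> np.ndarray:
        """Uniform draw from the dilated cuboid (r must be finite)."""
        lb, ub = self.cuboid(r)
        return rng.uniform(lb, ub)


class DiscriminationProblem:
    """Two rival models, their flexible nominal sets, and a finite design space.

    Linearizations of both models at the nominal values are precomputed over
    the whole design space once and cached; design evaluation then reduces to
    row indexing.
    """

    def __init__(
        self,
        model0: RegressionModel,
        model1: RegressionModel,
        nominal0: FlexibleNominalSet,
        nominal1: FlexibleNominalSet,
        design_space: Sequence,
    ):
        if model0.dim_param != model1.dim_param:
            raise ValueError("both models must have the same number of parameters")
        self.model0, self.model1 = model0, model1
        self.nominal0, self.nominal1 = nominal0, nominal1
        xs = _as_points(np.asarray(design_space, dtype=float))
        if xs.shape[0] == 0:
            raise ValueError("design space must be nonempty")
        if len({tuple(row) for row in xs}) != xs.shape[0]:
            raise ValueError("design space contains duplicate points")
        self.design_space = xs
        self._index = {tuple(row): i for i, row in enumerate(xs)}

        for k, (mod, nom) in enumerate(
            [(model0, nominal0), (model1, nominal1)]
        ):
            lb, ub = mod.param_box[:, 0], mod.param_box[:, 1]
            if not (np.all(nom.nominal > lb) and np.all(nom.nominal < ub)):
                raise ValueError(
                    f"nominal of model {k} must lie strictly inside its parameter box"
                )

        # Cached linearization tables at the nominal values.
        th0, th1 = nominal0.nominal, nominal1.nominal
        self.eta0 = model0.eta(th0, xs)
        self.eta1 = model1.eta(th1, xs)
        self.G0 = model0.grad(th0, xs)
        self.G1 = model1.grad(th1, xs)
        for name, arr in [("eta0", self.eta0), ("eta1", self.eta1),
                          ("grad0", self.G0), ("grad1", self.G1)]:
            if not np.all(np.isfinite(arr)):
                bad = int(np.argwhere(~np.isfinite(np.atleast_2d(arr).T))[0][-1])
                raise ValueError(
                    f"nonfinite {name} at design point {tuple(xs[bad])}"
                )
        self.delta_eta = self.eta0 - self.eta1
        # Offsets a_k per point and artificial observations z~ = a1 - a0.
        self.a0 = self.eta0 - self.G0 @ th0
        self.a1 = self.eta1 - self.G1 @ th1
        self.z_tilde = self.a1 - self.a0
        # Stacked response-difference regressors [grad0, -grad1] per point.
        self.G = np.hstack([self.G0, -self.G1])
        self.theta_stack = np.concatenate([th0, th1])
        self.hw_stack = np.concatenate([nominal0.half_width, nominal1.half_width])

        if np.max(np.abs(self.delta_eta)) == 0.0:
            warnings.warn(
                "discriminability condition violated: the nominal mean functions "
                "agree at every design point",
                UserWarning,
                stacklevel=2,
            )

    @property
    def dim_param(self) -> int:
        return self.model0.dim_param

    @property
    def n_points(self) -> int:
        return self.design_space.shape[0]

    def point_indices(self, points) -> np.ndarray:
        """Map design points to design-space row indices (error if missing)."""
        pts = _as_points(points)
        idx = np.empty(pts.shape[0], dtype=int)
        for i, row in enumerate(pts):
            key = tuple(row)
            if key not in self._index:
                raise ValueError(f"design point {key} is not in the design space")
            idx[i] = self._index[key]
        return idx

    def stacked_cuboid(self, r: float) -> tuple[np.ndarray, np.ndarray]:
        lb0, ub0 = self.nominal0.cuboid(r)
        lb1, ub1 = self.nominal1.cuboid(r)
        return np.concatenate([lb0, lb1]), np.concatenate([ub0, ub1])

    def content_hash(self) -> str:
        """Stable hash of the problem's defining quantities (for audit files)."""
        payload = {
            "model0": self.model0.name,
            "model1": self.model1.name,
            "nominal0": self.nominal0.nominal.tolist(),
            "half_width0": self.nominal0.half_width.tolist(),
            "nominal1": self.nominal1.nominal.tolist(),
            "half_width1": self.nominal1.half_width.tolist(),
            "design_space": np.round(self.design_space, 12).tolist(),
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Built-in models and problems
# ---------------------------------------------------------------------------

def _linear_mean(theta, X):
    return theta[0] * X[:, 0]


def _linear_grad(theta, X):
    return X[:, [0]]


def _exp_mean(theta, X):
    return np.exp(theta[0] * X[:, 0])


def _exp_grad(theta, X):
    return (X[:, 0] * np.exp(theta[0] * X[:, 0]))[:, None]


def _competitive_mean(theta, X):
    x1, x2 = X[:, 0], X[:, 1]
    return theta[0] * x1 / (theta[1] * (1.0 + x2 / theta[2]) + x1)


def _competitive_grad(theta, X):
    x1, x2 = X[:, 0], X[:, 1]
    u = 1.0 + x2 / theta[2]
    den = theta[1] * u + x1
    g1 = x1 / den
    g2 = -theta[0] * x1 * u / den**2
    g3 = theta[0] * x1 * theta[1] * x2 / (theta[2] ** 2 * den**2)
    return np.column_stack([g1, g2, g3])


def _noncompetitive_mean(theta, X):
    x1, x2 = X[:, 0], X[:, 1]
    return theta[0] * x1 / ((theta[1] + x1) * (1.0 + x2 / theta[2]))


def _noncompetitive_grad(theta, X):
    x1, x2 = X[:, 0], X[:, 1]
    A = theta[1] + x1
    B = 1.0 + x2 / theta[2]
    g1 = x1 / (A * B)
    g2 = -theta[0] * x1 / (A**2 * B)
    g3 = theta[0] * x1 * x2 / (A * B**2 * theta[2] ** 2)
    return np.column_stack([g1, g2, g3])


LINEAR_1D = RegressionModel(
    name="linear",
    mean=_linear_mean,
    gradient=_linear_grad,
    param_box=np.array([[-np.inf, np.inf]]),
    dim_param=1,
    dim_x=1,
)

EXPONENTIAL_1D = RegressionModel(
    name="exponential",
    mean=_exp_mean,
    gradient=_exp_grad,
    param_box=np.array([[-np.inf, np.inf]]),
    dim_param=1,
    dim_x=1,
)

_ENZYME_BOX = np.array([[0.0, np.inf], [0.0, 60.0], [0.0, 30.0]])

COMPETITIVE_INHIBITION = RegressionModel(
    name="competitive",
    mean=_competitive_mean,
    gradient=_competitive_grad,
    param_box=_ENZYME_BOX,
    dim_param=3,
    dim_x=2,
)

NONCOMPETITIVE_INHIBITION = RegressionModel(
    name="noncompetitive",
    mean=_noncompetitive_mean,
    gradient=_noncompetitive_grad,
    param_box=_ENZYME_BOX,
    dim_param=3,
    dim_x=2,
)

#: Nominal estimates (and standard errors, used as unit cuboid half-widths)
#: for the competitive and noncompetitive inhibition models, from the initial
#: 120-observation Dextrometorphan--Sertraline experiment.
ENZYME_NOMINAL0 = np.array([7.298, 4.386, 2.582])
ENZYME_SE0 = np.array([0.114, 0.233, 0.145])
ENZYME_NOMINAL1 = np.array([8.696, 8.066, 12.057])
ENZYME_SE1 = np.array([0.222, 0.488, 0.671])


def make_example1_problem(
    grid_start: float = 1.0, grid_end: float = 2.0, grid_step: float = 0.01
) -> DiscriminationProblem:
    """Linear-vs-exponential toy problem on a 1-d grid.

    Nominals are theta0 = e and theta1 = 1 (so the two means agree at x = 1),
    with unit cuboids [e-1, e+1] and [0, 2].
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    npts = int(round((grid_end - grid_start) / grid_step)) + 1
    grid = np.round(grid_start + grid_step * np.arange(npts), 12)[:, None]
    return DiscriminationProblem(
        LINEAR_1D,
        EXPONENTIAL_1D,
        FlexibleNominalSet(np.array([np.e]), np.array([1.0])),
        FlexibleNominalSet(np.array([1.0]), np.array([1.0])),
        grid,
    )


def make_enzyme_problem(
    grid_x1: Sequence[float] | None = None,
    grid_x2: Sequence[float] | None = None,
) -> DiscriminationProblem:
    """Competitive vs noncompetitive inhibition on a grid of [0,30] x [0,40].

    ``x1`` is the substrate concentration, ``x2`` the inhibitor concentration.
    The default grid uses step 0.5 in x1 and step 1.0 in x2 (61 x 41 points).
    """
    if grid_x1 is None:
        grid_x1 = np.round(0.5 * np.arange(61), 12)
    if grid_x2 is None:
        grid_x2 = np.round(1.0 * np.arange(41), 12)
    grid_x1 = np.asarray(grid_x1, dtype=float)
    grid_x2 = np.asarray(grid_x2, dtype=float)
    if grid_x1.min() < 0 or grid_x1.max() > 30 or grid_x2.min() < 0 or grid_x2.max() > 40:
        raise ValueError("grids must lie within [0,30] x [0,40]")
    pts = np.array([(a, b) for a in grid_x1 for b in grid_x2])
    return DiscriminationProblem(
        COMPETITIVE_INHIBITION,
        NONCOMPETITIVE_INHIBITION,
        FlexibleNominalSet(ENZYME_NOMINAL0, ENZYME_SE0),
        FlexibleNominalSet(ENZYME_NOMINAL1, ENZYME_SE1),
        pts,
    )


PROBLEMS: dict[str, Callable[..., DiscriminationProblem]] = {
    "example1": make_example1_problem,
    "enzyme": make_enzyme_problem,
}


def check_gradient(model: RegressionModel, theta, x, h: float = 1e-6) -> float:
    """Max abs deviation between the analytic gradient and central differences.

    Raises if the mean is nonfinite at a perturbed parameter value, which
    signals that ``theta`` is too close to the parameter box boundary for the
    chosen step ``h``.
    """
    theta = np.asarray(theta, dtype=float)
    pts = _as_points(x)
    analytic = model.grad(theta, pts)
    fd = np.empty_like(analytic)
    for j in range(model.dim_param):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        fp, fm = model.eta(tp, pts), model.eta(tm, pts)
        if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fm))):
            raise ValueError(
                f"mean of {model.name!r} nonfinite near theta={theta} "
                f"(component {j}); parameter box too tight for step h={h}"
            )
        fd[:, j] = (fp - fm) / (2.0 * h)
    return float(np.max(np.abs(analytic - fd)))
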