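import numpy as np
import pytest

from deltadisc import (
    DiscriminationProblem,
    FlexibleNominalSet,
    RegressionModel,
    make_example1_problem,
    make_enzyme_problem,
)


@pytest.fixture(scope="session")
def example1():
    """Full linear-vs-exponential problem on the 101-point grid of [1, 2]."""
    return make_example1_problem()


@pytest.fixture(scope="session")
def example1_tiny():
    """Three-point grid {1.0, 1.5, 2.0} for enumeration-sized tests."""
    return make_example1_problem(1.0, 2.0, 0.5)


@pytest.fixture(scope="session")
def enzyme_coarse():
    """Enzyme problem on a coarse 7 x 6 grid; fast but structurally faithful."""
    return make_enzyme_problem(np.linspace(0, 30, 7), np.linspace(0, 40, 6))


@pytest.fixture(scope="session")
def enzyme_full():
    """Enzyme problem on the default 61 x 41 grid."""
    return make_enzyme_problem()


def make_linear_model(name, weights, offset_coefs, dim_x=1):
    """Model with mean offset(x) + theta' f(x), f(x) = weights @ basis(x).

    basis(x) = (1, x, x^2, ...) of the first coordinate; the offset is a fixed
    polynomial, exercising a nonzero linearization intercept a_k.
    """
    weights = np.asarray(weights, float)
    offset_coefs = np.asarray(offset_coefs, float)
    m, nbasis = weights.shape

    def basis(X):
        x = X[:, 0]
        return np.vander(x, nbasis, increasing=True)

    def mean(theta, X):
        B = basis(X)
        return B @ offset_coefs + (B @ weights.T) @ theta

    def grad(theta, X):
        return basis(X) @ weights.T

    box = np.tile([-np.inf, np.inf], (m, 1))
    return RegressionModel(name=name, mean=mean, gradient=grad,
                           param_box=box, dim_param=m, dim_x=dim_x)


def random_linear_problem(rng, d=5, m=2, with_offset=True):
    """A random pair of (affine) linear models on a random 1-d design space.

    Linear models make the linearization exact, so brute-force and nonlinear
    oracles agree with the criterion to rounding error.
    """
    nbasis = m + 1
    w0 = rng.normal(size=(m, nbasis))
    w1 = rng.normal(size=(m, nbasis))
    off0 = rng.normal(size=nbasis) if with_offset else np.zeros(nbasis)
    off1 = rng.normal(size=nbasis) if with_offset else np.zeros(nbasis)
    model0 = make_linear_model("lin0", w0, off0)
    model1 = make_linear_model("lin1", w1, off1)
    nom0 = FlexibleNominalSet(rng.normal(size=m), rng.uniform(0.2, 1.5, size=m))
    nom1 = FlexibleNominalSet(rng.normal(size=m), rng.uniform(0.2, 1.5, size=m))
    xs = np.sort(rng.uniform(-2, 2, size=d))[:, None]
    return DiscriminationProblem(model0, model1, nom0, nom1, xs)
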