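"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: element integrals are
computed by symmetric Gaussian quadrature exact to polynomial degree 4,
dot products by naive left-to-right summation, linear systems by dense
factorization, and the well-mixed kinetics by an adaptive high-accuracy
ODE integrator.
"""

from __future__ import annotations

import numpy as np

# Degree-4 symmetric triangle quadrature (6 points, barycentric).
_QP = np.array([
    [0.445948490915965, 0.445948490915965, 0.108103018168070],
    [0.445948490915965, 0.108103018168070, 0.445948490915965],
    [0.108103018168070, 0.445948490915965, 0.445948490915965],
    [0.091576213509771, 0.091576213509771, 0.816847572980459],
    [0.091576213509771, 0.816847572980459, 0.091576213509771],
    [0.816847572980459, 0.091576213509771, 0.091576213509771],
])
_QW = np.array([0.223381589678011] * 3 + [0.109951743655322] * 3)


def _cross2(u, v):
    return u[0] * v[1] - u[1] * v[0]


def quad_mass(tri: np.ndarray) -> np.ndarray:
    """∫ φi φj over the triangle by degree-4 quadrature (exact for P1·P1)."""
    tri = np.asarray(tri, dtype=float)
    area = 0.5 * abs(_cross2(tri[1] - tri[0], tri[2] - tri[0]))
    out = np.zeros((3, 3))
    for bary, w in zip(_QP, _QW):
        out += w * np.outer(bary, bary)
    return area * out


def quad_stiffness(tri: np.ndarray) -> np.ndarray:
    """∫ ∇φi · ∇φj via quadrature of the (constant) hat-function gradients.

    Gradients are obtained by solving the linear interpolation system, not
    from the closed-form edge-vector formula under test.
    """
    tri = np.asarray(tri, dtype=float)
    area = 0.5 * abs(_cross2(tri[1] - tri[0], tri[2] - tri[0]))
    # φi(x, y) = a + b·x + c·y with φi(vertex j) = δij
    M = np.column_stack([np.ones(3), tri])
    grads = np.linalg.solve(M, np.eye(3))[1:, :].T  # (3, 2) rows = ∇φi
    out = np.zeros((3, 3))
    for _, w in zip(_QP, _QW):
        out += w * (grads @ grads.T)
    return area * out


def naive_dot(x: np.ndarray, y: np.ndarray) -> float:
    """Sequential left-to-right summation of the elementwise product."""
    total = 0.0
    for xi, yi in zip(np.asarray(x, float).ravel(), np.asarray(y, float).ravel()):
        total += xi * yi
    return total


def wellmixed_trajectory(n0, p0, params, t_eval):
    """High-accuracy adaptive integration of the well-mixed kinetics.

    Returns (N(t), P(t)) at the requested times; clamps at zero the same
    way the PDE scheme does (the exact flow never crosses zero except via
    the −ε term, which the clamp absorbs).
    """
    from scipy.integrate import solve_ivp

    def rhs(_, y):
        n, p = max(y[0], 0.0), max(y[1], 0.0)
        pred = params.cp * n * p / (1.0 + params.b * p)
        return [params.cr * n / (1.0 + params.b * n) - pred - params.eps,
                pred - params.eps]

    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), [n0, p0], t_eval=t_eval,
                    rtol=1e-10, atol=1e-12, method="RK45")
    return np.maximum(sol.y[0], 0.0), np.maximum(sol.y[1], 0.0)


def random_spd(m: int, rng: np.random.Generator) -> np.ndarray:
    """Dense SPD matrix via AᵀA + I."""
    A = rng.standard_normal((m, m))
    return A.T @ A + np.eye(m)
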