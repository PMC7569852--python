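"""Linear-algebra core: axpy, tree-reduction dot product, spmv, and CG.

The conjugate gradient method is assembled from exactly three primitives —
sparse matrix-vector products, vector additions (axpy), and dot products —
which is what makes the scheme friendly to massively parallel hardware.
The dot product uses a blocked stride-doubling pairwise reduction: within
blocks of ``block_size`` entries partial sums are combined pairwise
(stride 1, 2, 4, ...), then the per-block results are reduced the same way
across blocks.  The reduction order is fixed, so the result is
bit-identical across calls — an ordering contract, independent of how the
work is scheduled.  Arbitrary lengths (not powers of two, not multiples of
the block size) are handled by skipping out-of-range partners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ParameterError, SolverError

__all__ = ["SolveReport", "SolverSettings", "axpy", "tree_dot", "spmv",
           "conjugate_gradient"]

DEFAULT_BLOCK_SIZE = 1024


@dataclass(frozen=True)
class SolverSettings:
    """Conjugate-gradient configuration.

    ``rtol`` is the relative-residual stopping threshold (default 0.001);
    ``residual_reference`` selects what the residual is relative to: the
    right-hand side norm (``"rhs"``, the conventional reading) or the
    initial residual norm (``"initial"``).  ``max_iter`` defaults to the
    system dimension.  ``warm_start`` seeds each time step's solve with
    the previous solution.
    """

    rtol: float = 1e-3
    max_iter: int | None = None
    warm_start: bool = True
    block_size: int = DEFAULT_BLOCK_SIZE
    residual_reference: str = "rhs"

    def __post_init__(self):
        if self.rtol <= 0:
            raise ParameterError("rtol must be positive")
        if self.max_iter is not None and self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.block_size < 2:
            raise ParameterError("block_size must be >= 2")
        if self.residual_reference not in ("rhs", "initial"):
            raise ParameterError("residual_reference must be 'rhs' or 'initial'")


@dataclass
class SolveReport:
    """Per-solve diagnostics: iteration count and residual history."""

    iterations: int
    final_relative_residual: float
    residual_history: list[float] = field(default_factory=list)
    converged: bool = False


def axpy(X: np.ndarray, lam: float, Y: np.ndarray) -> np.ndarray:
    """Elementwise X + λ·Y."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ParameterError(f"length mismatch: {X.shape} vs {Y.shape}")
    return X + lam * Y


def tree_dot(X: np.ndarray, Y: np.ndarray, block_size: int = DEFAULT_BLOCK_SIZE) -> float:
    """Dot product via a deterministic blocked pairwise reduction."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ParameterError(f"length mismatch: {X.shape} vs {Y.shape}")
    n = X.size
    if n == 0:
        raise ParameterError("tree_dot requires vectors of length >= 1")
    z = (X * Y).ravel().copy()
    global_stride = 1
    while global_stride < n:
        _block_sum(z, global_stride, block_size, n)
        global_stride *= block_size
    return float(z[0])


def _block_sum(z: np.ndarray, alpha: int, block_size: int, n: int) -> None:
    # pairwise combine partial sums spaced alpha apart, within one block span
    stride = alpha
    while stride < block_size * alpha:
        i = np.arange(0, n - stride, 2 * stride)
        if i.size == 0:
            break
        z[i] += z[i + stride]
        stride *= 2


def _as_operator(A):
    """Accept SystemMatrix / SparseSymMatrix / scipy sparse / ndarray."""
    if hasattr(A, "matrix"):  # SystemMatrix
        A = A.matrix
    if hasattr(A, "csr"):  # SparseSymMatrix
        A = A.csr
    if sp.issparse(A):
        return A
    return np.asarray(A, dtype=float)


def spmv(A, x: np.ndarray) -> np.ndarray:
    """Sparse matrix-vector product using only stored nonzeros."""
    op = _as_operator(A)
    x = np.asarray(x, dtype=float)
    if op.shape[1] != x.size:
        raise ParameterError(f"dimension mismatch: {op.shape} @ {x.shape}")
    return np.asarray(op @ x, dtype=float)


def conjugate_gradient(
    A,
    b: np.ndarray,
    x0: np.ndarray | None = None,
    rtol: float = 1e-3,
    max_iter: int | None = None,
    settings: SolverSettings | None = None,
) -> tuple[np.ndarray, SolveReport]:
    """Solve A·x = b for symmetric positive definite A.

    Standard Hestenes-Stiefel recurrences built from :func:`spmv`,
    :func:`axpy` and :func:`tree_dot`, stopping when the relative residual
    drops below ``rtol`` or after ``max_iter`` iterations (default: the
    system dimension).  The residual is tracked by recurrence; on claimed
    convergence the true residual ‖b − Ax‖ is recomputed and, if it fails
    the test, the iteration restarts from the true residual.

    A zero right-hand side returns x = 0 immediately.  A search direction
    with pᵀAp ≤ 0 signals a non-SPD operator and raises
    :class:`~rdfem.errors.SolverError`.  Non-convergence at ``max_iter``
    is flagged in the report, never raised.
    """
    if settings is None:
        settings = SolverSettings(rtol=rtol, max_iter=max_iter)
    op = _as_operator(A)
    b = np.asarray(b, dtype=float)
    m = b.size
    if op.shape != (m, m):
        raise ParameterError(f"dimension mismatch: A is {op.shape}, b has length {m}")
    max_it = settings.max_iter if settings.max_iter is not None else m
    bs = settings.block_size

    bnorm = math.sqrt(tree_dot(b, b, bs))
    if bnorm == 0.0:
        return np.zeros(m), SolveReport(0, 0.0, [0.0], converged=True)

    x = np.zeros(m) if x0 is None else np.asarray(x0, dtype=float).copy()
    if x.size != m:
        raise ParameterError("x0 length does not match b")

    r = axpy(b, -1.0, spmv(op, x))
    rs = tree_dot(r, r, bs)
    ref = bnorm if settings.residual_reference == "rhs" else (math.sqrt(rs) or bnorm)
    history = [math.sqrt(rs) / ref]
    if history[0] <= settings.rtol:
        return x, SolveReport(0, history[0], history, converged=True)

    p = r.copy()
    iterations = 0
    converged = False
    while iterations < max_it:
        Ap = spmv(op, p)
        pAp = tree_dot(p, Ap, bs)
        if pAp <= 0.0:
            raise SolverError(
                f"pᵀAp = {pAp:.3e} <= 0 at iteration {iterations + 1}: "
                "operator is not symmetric positive definite"
            )
        alpha = rs / pAp
        x = axpy(x, alpha, p)
        r = axpy(r, -alpha, Ap)
        rs_new = tree_dot(r, r, bs)
        iterations += 1
        history.append(math.sqrt(rs_new) / ref)
        if history[-1] <= settings.rtol:
            # recurrence says converged; verify with the true residual
            r_true = axpy(b, -1.0, spmv(op, x))
            rs_true = tree_dot(r_true, r_true, bs)
            history[-1] = math.sqrt(rs_true) / ref
            if history[-1] <= settings.rtol:
                converged = True
                break
            r, rs = r_true, rs_true  # drifted: restart from the true residual
            p = r.copy()
            continue
        beta = rs_new / rs
        rs = rs_new
        p = axpy(r, beta, p)

    return x, SolveReport(iterations, history[-1], history, converged=converged)
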