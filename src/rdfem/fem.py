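"""P1 Galerkin assembly: damping (mass) and stiffness matrices.

The concentration fields are expanded on piece-wise linear hat functions
φi attached to the mesh nodes (φi = 1 at node i, 0 at every other node).
The Galerkin projection of the reaction-diffusion system then involves two
sparse symmetric matrices:

* the damping matrix  D_ij = ∫_Ω φi φj dΩ   (the basis Gram matrix), and
* the stiffness matrix S_ij = ∫_Ω ∇φi · ∇φj dΩ  (the discrete negative
  Laplacian under no-flux boundary conditions).

With Neumann (no-flux) walls the boundary integral in Green's first
identity vanishes, so no boundary terms are assembled.  Both integrals
have exact closed forms on straight triangles, used directly here;
numerical quadrature appears only in the test oracles.

Note that S annihilates constant fields (every row sums to zero), so it is
positive *semi*-definite; only the implicit-Euler system matrix A = D + τS
is strictly positive definite on a connected mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import GeometryError, ParameterError
from .meshing import TriMesh

__all__ = [
    "SparseSymMatrix",
    "SystemMatrix",
    "element_mass",
    "element_stiffness",
    "assemble",
    "system_matrix",
]

_SYM_RTOL = 1e-12


@dataclass(frozen=True)
class SparseSymMatrix:
    """Symmetric sparse matrix in compressed form (CSR under the hood)."""

    csr: sp.csr_matrix

    def __post_init__(self):
        m = self.csr
        if m.shape[0] != m.shape[1]:
            raise ParameterError(f"matrix must be square, got {m.shape}")
        asym = abs(m - m.T)
        scale = abs(m).max() or 1.0
        if asym.nnz and asym.max() > _SYM_RTOL * scale:
            raise ParameterError("matrix is not symmetric within 1e-12 relative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.csr.shape

    @property
    def dimension(self) -> int:
        return self.csr.shape[0]

    @property
    def nnz(self) -> int:
        return self.csr.nnz

    def to_triplets(self) -> np.ndarray:
        """(row, col, value) triplets in row-major order, zeros dropped."""
        coo = self.csr.tocoo()
        order = np.lexsort((coo.col, coo.row))
        return np.column_stack([coo.row[order], coo.col[order], coo.data[order]])

    def toarray(self) -> np.ndarray:
        return self.csr.toarray()


@dataclass(frozen=True)
class SystemMatrix:
    """The implicit-Euler diffusion operator A = D + τS, with its τ."""

    matrix: SparseSymMatrix
    tau: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def dimension(self) -> int:
        return self.matrix.dimension


def _triangle_geometry(tri_coords: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    p = np.asarray(tri_coords, dtype=float)
    if p.shape != (3, 2):
        raise ParameterError("tri_coords must be three 2-D points")
    # b_i = y_j - y_k, c_i = x_k - x_j with (i, j, k) cyclic
    b = np.array([p[1, 1] - p[2, 1], p[2, 1] - p[0, 1], p[0, 1] - p[1, 1]])
    c = np.array([p[2, 0] - p[1, 0], p[0, 0] - p[2, 0], p[1, 0] - p[0, 0]])
    area = 0.5 * (b[0] * c[1] - b[1] * c[0])
    if area <= 0:
        raise GeometryError("triangle is degenerate or wound clockwise")
    return area, b, c


def element_mass(tri_coords: np.ndarray) -> np.ndarray:
    """Exact P1 mass integrals ∫ φi φj over one triangle.

    Equals (area/12)·[[2,1,1],[1,2,1],[1,1,2]]; the nine entries sum to
    the triangle area because the hat functions partition unity.
    """
    area, _, _ = _triangle_geometry(tri_coords)
    return (area / 12.0) * (np.ones((3, 3)) + np.eye(3))


def element_stiffness(tri_coords: np.ndarray) -> np.ndarray:
    """Exact P1 stiffness integrals ∫ ∇φi · ∇φj over one triangle.

    The hat-function gradients are constant on the element, so
    S_ij = (b_i b_j + c_i c_j) / (4·area).  Rows sum to zero (the gradient
    of the constant 1 vanishes) and the matrix has rank 2.
    """
    area, b, c = _triangle_geometry(tri_coords)
    return (np.outer(b, b) + np.outer(c, c)) / (4.0 * area)


def assemble(mesh: TriMesh) -> tuple[SparseSymMatrix, SparseSymMatrix]:
    """Assemble global damping and stiffness matrices by scatter-add.

    Element contributions are accumulated in triplet form in triangle
    order and compressed, so assembly is bit-reproducible for a given
    mesh.  No boundary terms appear: the no-flux condition makes the
    boundary integral of Green's identity vanish identically.
    """
    p = mesh.nodes[mesh.triangles]  # (t, 3, 2)
    b = np.stack([p[:, 1, 1] - p[:, 2, 1],
                  p[:, 2, 1] - p[:, 0, 1],
                  p[:, 0, 1] - p[:, 1, 1]], axis=1)
    c = np.stack([p[:, 2, 0] - p[:, 1, 0],
                  p[:, 0, 0] - p[:, 2, 0],
                  p[:, 1, 0] - p[:, 0, 0]], axis=1)
    area = 0.5 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
    if np.any(area <= 0):
        raise GeometryError("mesh contains degenerate or clockwise triangles")

    mass_el = (area / 12.0)[:, None, None] * (np.ones((3, 3)) + np.eye(3))
    stiff_el = (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]) \
        / (4.0 * area)[:, None, None]

    rows = np.repeat(mesh.triangles, 3, axis=1).ravel()
    cols = np.tile(mesh.triangles, (1, 3)).ravel()
    m = mesh.n_nodes
    D = sp.coo_matrix((mass_el.ravel(), (rows, cols)), shape=(m, m)).tocsr()
    S = sp.coo_matrix((stiff_el.ravel(), (rows, cols)), shape=(m, m)).tocsr()
    return SparseSymMatrix(D), SparseSymMatrix(S)


def system_matrix(D: SparseSymMatrix, S: SparseSymMatrix, tau: float) -> SystemMatrix:
    """Form the implicit-Euler operator A = D + τS."""
    if D.shape != S.shape:
        raise ParameterError(f"dimension mismatch: D is {D.shape}, S is {S.shape}")
    if tau < 0:
        raise ParameterError("tau must be nonnegative")
    A = (D.csr + tau * S.csr).tocsr()
    return SystemMatrix(matrix=SparseSymMatrix(A), tau=float(tau))
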