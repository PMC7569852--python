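"""Structured triangulation of rasterized reactor geometries.

Every open pixel of a :class:`~rdfem.geometry.RasterMask` is split into
``s x s`` sub-squares and each sub-square into two right triangles, with
the diagonal orientation alternating in a criss-cross pattern to avoid a
preferred direction in the discrete Laplacian.  Nodes shared between
adjacent open pixels are merged, so the mesh is conforming.  ``s`` (the
``subdivision``) is the resolution knob: larger ``s`` means smaller cells,
playing the role a mesher's "maximum allowed cell size" plays for
unstructured meshes.

Coordinate convention: mesh coordinates are in pixel units with the y axis
pointing *up*, so "the bottom of the maze" (last image row) is at minimal
y.  Node ordering is lattice row-major (by y, then x) and fully
deterministic: the same mask and subdivision always produce a byte-identical
mesh.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import GeometryError, ParameterError
from .geometry import RasterMask

__all__ = ["TriMesh", "build_mesh", "mesh_total_area", "validate_mesh", "MeshReport"]


@dataclass(frozen=True)
class TriMesh:
    """Conforming triangle mesh of the reactor region Ω.

    Attributes
    ----------
    nodes:
        ``(m, 2)`` float array of node coordinates (pixel units, y-up).
    triangles:
        ``(t, 3)`` int array of counter-clockwise node triples.
    boundary_edges:
        ``(b, 2)`` int array; exactly the edges with one incident triangle
        (the reactor wall ω, where the no-flux condition applies).
    """

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_edges: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        u = p[:, 1] - p[:, 0]
        v = p[:, 2] - p[:, 0]
        return 0.5 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])


@dataclass
class MeshReport:
    """Outcome of :func:`validate_mesh`: pass/fail plus the first violation."""

    passed: bool
    first_violation: str | None = None
    details: dict = field(default_factory=dict)


def build_mesh(mask: RasterMask, subdivision: int = 1) -> TriMesh:
    """Triangulate the open pixels of ``mask`` at the given subdivision.

    Raises
    ------
    GeometryError
        If the mask has no open pixels or the open region is not a single
        4-connected component (multi-chamber reactors are refused).
    ParameterError
        If ``subdivision`` is not a positive integer.
    """
    if not isinstance(subdivision, (int, np.integer)) or subdivision < 1:
        raise ParameterError("subdivision must be an integer >= 1")
    if mask.n_open == 0:
        raise GeometryError("mask has no open pixels")
    if not mask.is_connected():
        raise GeometryError("open region is not a single connected reactor")

    s = int(subdivision)
    h, w = mask.cells.shape
    # sub-cell occupancy indexed [j, i] with j the y-up sub-row, i the x sub-col
    open_sub = np.repeat(np.repeat(mask.cells[::-1, :], s, axis=0), s, axis=1)
    js, is_ = np.nonzero(open_sub)

    L = w * s + 1  # lattice points per row
    ll = js * L + is_
    lr, ul, ur = ll + 1, ll + L, ll + L + 1

    even = (is_ + js) % 2 == 0
    t1 = np.where(even[:, None], np.stack([ll, lr, ur], axis=1),
                  np.stack([ll, lr, ul], axis=1))
    t2 = np.where(even[:, None], np.stack([ll, ur, ul], axis=1),
                  np.stack([lr, ur, ul], axis=1))
    tris_lattice = np.empty((2 * len(ll), 3), dtype=np.int64)
    tris_lattice[0::2] = t1
    tris_lattice[1::2] = t2

    used = np.unique(tris_lattice)
    triangles = np.searchsorted(used, tris_lattice).astype(np.int64)
    gx = used % L
    gy = used // L
    nodes = np.column_stack([gx / s, gy / s]).astype(float)

    boundary = _boundary_edges(triangles)
    return TriMesh(nodes=nodes, triangles=triangles, boundary_edges=boundary)


def _all_edges(triangles: np.ndarray) -> np.ndarray:
    e = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]],
                        triangles[:, [2, 0]]])
    return np.sort(e, axis=1)


def _boundary_edges(triangles: np.ndarray) -> np.ndarray:
    edges = _all_edges(triangles)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return uniq[counts == 1]


def mesh_total_area(mesh: TriMesh) -> float:
    """Total reactor area in pixel² (sum of triangle areas, compensated).

    For a pixel-subdivision mesh this equals the number of open pixels,
    independent of the subdivision level.
    """
    return math.fsum(mesh.signed_areas().tolist())


def validate_mesh(mesh: TriMesh) -> MeshReport:
    """Check all mesh invariants; report the first violation, never raise."""
    areas = mesh.signed_areas()
    if mesh.n_triangles == 0:
        return MeshReport(False, "mesh has no triangles")
    if np.any(areas <= 0):
        return MeshReport(False, "negative or zero signed area",
                          {"triangle": int(np.argmin(areas))})

    rounded = np.round(mesh.nodes / 1e-9).astype(np.int64)
    if np.unique(rounded, axis=0).shape[0] != mesh.n_nodes:
        return MeshReport(False, "duplicate nodes")

    edges = _all_edges(mesh.triangles)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    if counts.max(initial=0) > 2:
        return MeshReport(False, "edge shared by more than 2 triangles")

    expected_boundary = uniq[counts == 1]
    got = np.unique(np.sort(mesh.boundary_edges, axis=1), axis=0)
    if got.shape != expected_boundary.shape or not np.array_equal(got, expected_boundary):
        return MeshReport(False, "boundary_edges do not match edges with one incident triangle")

    graph = sp.coo_matrix(
        (np.ones(len(uniq)), (uniq[:, 0], uniq[:, 1])),
        shape=(mesh.n_nodes, mesh.n_nodes),
    )
    n_comp, _ = sp.csgraph.connected_components(graph, directed=False)
    if n_comp != 1:
        return MeshReport(False, "mesh is not edge-connected", {"components": int(n_comp)})

    return MeshReport(True)
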