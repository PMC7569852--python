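"""Readers and writers for on-disk artifacts.

Formats
-------
* Geometry: PNG and PGM rasters in (Pillow), PGM out — ASCII ``P2``, with
  0 = wall and 255 = open reactor.
* Matrices: a CSV triplet dialect — header ``row,col,value``, 0-based
  indices, full double precision (17 significant digits), preceded by a
  ``# dimension: m`` comment so the round-trip is lossless — plus standard
  Matrix Market (.mtx) for interoperability with 1-based ecosystems.
* Mesh: plain-text node file (``index,x,y``) and triangle file
  (``i,j,k``), plus Gmsh MSH 2.2 ASCII export.
* State: columnar text ``node_index N P`` at full precision.
* Rendering: one filled rectangle per node, prey on the red channel and
  predator on the blue channel, clipped to [0, 1]; deterministic output.

All parse errors carry file and line context; nothing is silently coerced.
"""

from __future__ import annotations

import dataclasses
import io as _io
import warnings
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import yaml
from PIL import Image

from .chemistry import ReactionParams
from .errors import ParameterError, ParseError, StateError
from .fem import SparseSymMatrix
from .geometry import RasterMask
from .meshing import TriMesh
from .simulation import SimulationConfig
from .solver import SolverSettings

__all__ = [
    "read_mask", "write_mask_pgm",
    "write_matrix_csv", "read_matrix_csv", "write_matrix_mm", "read_matrix_mm",
    "write_mesh", "read_mesh", "write_msh",
    "write_state", "read_state",
    "render_snapshot",
    "load_config", "save_config", "write_manifest",
]


# ---------------------------------------------------------------- geometry

def read_mask(path: str | Path, threshold: float = 0.5) -> RasterMask:
    """Read a PNG/PGM raster and binarize it into a reactor mask."""
    from .geometry import binarize

    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"), dtype=float)
    return binarize(arr, threshold)


def write_mask_pgm(mask: RasterMask, path: str | Path) -> None:
    """Write a mask as ASCII PGM: 0 = wall, 255 = open."""
    vals = np.where(mask.cells, 255, 0)
    lines = [f"P2", f"{mask.width} {mask.height}", "255"]
    lines += [" ".join(str(v) for v in row) for row in vals]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- matrices

def write_matrix_csv(M: SparseSymMatrix, path: str | Path) -> None:
    triplets = M.to_triplets()
    with open(path, "w") as fh:
        fh.write(f"# dimension: {M.dimension}\n")
        fh.write("row,col,value\n")
        for i, j, v in triplets:
            fh.write(f"{int(i)},{int(j)},{v:.17g}\n")


def read_matrix_csv(path: str | Path, allow_unsymmetric: bool = False) -> SparseSymMatrix:
    """Read the CSV triplet dialect back into a sparse symmetric matrix.

    Non-symmetric content raises unless ``allow_unsymmetric`` is set, in
    which case a warning is issued and the matrix is symmetrized as
    (M + Mᵀ)/2.
    """
    path = Path(path)
    rows, cols, vals = [], [], []
    dim = None
    with open(path) as fh:
        lineno = 0
        header_seen = False
        for raw in fh:
            lineno += 1
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "dimension:" in line:
                    try:
                        dim = int(line.split("dimension:")[1])
                    except ValueError:
                        raise ParseError("malformed dimension comment", str(path), lineno)
                continue
            if not header_seen:
                if line != "row,col,value":
                    raise ParseError(f"expected header 'row,col,value', got {line!r}",
                                     str(path), lineno)
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ParseError(f"expected 3 comma-separated fields, got {len(parts)}",
                                 str(path), lineno)
            try:
                rows.append(int(parts[0]))
                cols.append(int(parts[1]))
                vals.append(float(parts[2]))
            except ValueError as err:
                raise ParseError(f"unparsable triplet: {err}", str(path), lineno)
    if not header_seen:
        raise ParseError("missing header line", str(path))
    if not rows:
        raise ParseError("no triplets: empty matrix", str(path))
    if dim is None:
        dim = max(max(rows), max(cols)) + 1
    m = sp.coo_matrix((vals, (rows, cols)), shape=(dim, dim)).tocsr()
    return _check_symmetry(m, allow_unsymmetric, str(path))


def _check_symmetry(m: sp.csr_matrix, allow_unsymmetric: bool, origin: str) -> SparseSymMatrix:
    asym = abs(m - m.T)
    scale = abs(m).max() or 1.0
    if asym.nnz and asym.max() > 1e-12 * scale:
        if not allow_unsymmetric:
            raise ParseError(
                "matrix content is not symmetric; pass allow_unsymmetric=True "
                "to symmetrize explicitly", origin)
        warnings.warn(f"symmetrizing non-symmetric matrix from {origin}")
        m = ((m + m.T) * 0.5).tocsr()
    return SparseSymMatrix(m)


def write_matrix_mm(M: SparseSymMatrix, path: str | Path) -> None:
    sp_io = __import__("scipy.io", fromlist=["mmwrite"])
    sp_io.mmwrite(str(path), M.csr, symmetry="symmetric")


def read_matrix_mm(path: str | Path, allow_unsymmetric: bool = False) -> SparseSymMatrix:
    sp_io = __import__("scipy.io", fromlist=["mmread"])
    try:
        m = sp_io.mmread(str(path)).tocsr()
    except Exception as err:
        raise ParseError(f"unreadable Matrix Market file: {err}", str(path))
    return _check_symmetry(m, allow_unsymmetric, str(path))


# ---------------------------------------------------------------- mesh

def write_mesh(mesh: TriMesh, out_dir: str | Path) -> None:
    """Plain-text mesh export: nodes.txt (index,x,y) + triangles.txt (i,j,k)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "nodes.txt", "w") as fh:
        fh.write("index,x,y\n")
        for idx, (x, y) in enumerate(mesh.nodes):
            fh.write(f"{idx},{x:.17g},{y:.17g}\n")
    with open(out / "triangles.txt", "w") as fh:
        fh.write("i,j,k\n")
        for i, j, k in mesh.triangles:
            fh.write(f"{i},{j},{k}\n")


def read_mesh(in_dir: str | Path) -> TriMesh:
    in_dir = Path(in_dir)
    nodes = _read_csv_table(in_dir / "nodes.txt", "index,x,y", 3)
    tris = _read_csv_table(in_dir / "triangles.txt", "i,j,k", 3)
    node_arr = np.array([[r[1], r[2]] for r in nodes], dtype=float)
    tri_arr = np.array([[int(r[0]), int(r[1]), int(r[2])] for r in tris], dtype=np.int64)
    if tri_arr.size and tri_arr.max() >= len(node_arr):
        raise ParseError("triangle references a missing node", str(in_dir / "triangles.txt"))
    from .meshing import _boundary_edges
    return TriMesh(node_arr, tri_arr, _boundary_edges(tri_arr))


def _read_csv_table(path: Path, header: str, n_fields: int) -> list[list[float]]:
    rows = []
    with open(path) as fh:
        lineno = 0
        for raw in fh:
            lineno += 1
            line = raw.strip()
            if not line:
                continue
            if lineno == 1:
                if line != header:
                    raise ParseError(f"expected header {header!r}", str(path), lineno)
                continue
            parts = line.split(",")
            if len(parts) != n_fields:
                raise ParseError(f"expected {n_fields} fields", str(path), lineno)
            try:
                rows.append([float(p) for p in parts])
            except ValueError as err:
                raise ParseError(str(err), str(path), lineno)
    return rows


def write_msh(mesh: TriMesh, path: str | Path) -> None:
    """Gmsh MSH 2.2 ASCII export (1-based node and element indices)."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_nodes}\n")
        for idx, (x, y) in enumerate(mesh.nodes, start=1):
            fh.write(f"{idx} {x:.17g} {y:.17g} 0\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_triangles}\n")
        for eid, (i, j, k) in enumerate(mesh.triangles, start=1):
            fh.write(f"{eid} 2 2 0 1 {i + 1} {j + 1} {k + 1}\n")
        fh.write("$EndElements\n")


# ---------------------------------------------------------------- state

def write_state(N: np.ndarray, P: np.ndarray, path: str | Path) -> None:
    if N.shape != P.shape:
        raise StateError("N and P must have equal length")
    with open(path, "w") as fh:
        fh.write("node,N,P\n")
        for idx, (n, p) in enumerate(zip(N, P)):
            fh.write(f"{idx},{n:.17g},{p:.17g}\n")


def read_state(path: str | Path, n_nodes: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    rows = _read_csv_table(Path(path), "node,N,P", 3)
    if not rows:
        raise ParseError("state file has no rows", str(path))
    N = np.array([r[1] for r in rows])
    P = np.array([r[2] for r in rows])
    if n_nodes is not None and N.size != n_nodes:
        raise StateError(f"state has {N.size} nodes, mesh has {n_nodes}")
    if N.min() < 0 or P.min() < 0:
        raise StateError("negative concentration in state file")
    return N, P


# ---------------------------------------------------------------- rendering

def render_snapshot(
    mesh: TriMesh,
    N: np.ndarray,
    P: np.ndarray,
    path: str | Path,
    scale: int = 4,
) -> None:
    """Render prey (red) and predator (blue) as one rectangle per node.

    Each node paints a ``scale`` x ``scale`` pixel rectangle at its mesh
    location; values are clipped to [0, 1].  Output is a PNG whose bytes
    depend only on the inputs.
    """
    if N.size != mesh.n_nodes or P.size != mesh.n_nodes:
        raise StateError("field length does not match the mesh")
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    # node spacing in mesh units (pixel / subdivision)
    spacing = 1.0
    if mesh.n_nodes > 1:
        diffs = np.diff(np.unique(np.round(x / 1e-9) * 1e-9))
        spacing = float(diffs.min()) if diffs.size else 1.0
    w = int(round((x.max() - x.min()) / spacing)) + 1
    h = int(round((y.max() - y.min()) / spacing)) + 1
    img = np.zeros((h, w, 3), dtype=np.uint8)
    ix = np.round((x - x.min()) / spacing).astype(int)
    iy = np.round((y - y.min()) / spacing).astype(int)
    rr = h - 1 - iy  # y-up mesh coordinates back to image rows
    img[rr, ix, 0] = np.round(255 * np.clip(N, 0, 1)).astype(np.uint8)
    img[rr, ix, 2] = np.round(255 * np.clip(P, 0, 1)).astype(np.uint8)
    big = np.repeat(np.repeat(img, scale, axis=0), scale, axis=1)
    Image.fromarray(big, mode="RGB").save(path, format="PNG")


# ---------------------------------------------------------------- config

def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML run configuration.

    Recognized keys: ``tau``, ``n_steps``, ``order``, ``snapshot_stride``,
    a ``chemistry`` block (cr, cp, b, eps) and a ``solver`` block (rtol,
    max_iter, warm_start, block_size, residual_reference).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParseError("config must be a YAML mapping", str(path))
    try:
        params = ReactionParams(**raw.get("chemistry", {}))
        solver = SolverSettings(**raw.get("solver", {}))
        cfg = {k: v for k, v in raw.items() if k not in ("chemistry", "solver")}
        return SimulationConfig(params=params, solver=solver, **cfg)
    except (TypeError, ParameterError) as err:
        raise ParseError(f"bad config: {err}", str(path))


def save_config(config: SimulationConfig, path: str | Path) -> None:
    data = {
        "tau": config.tau,
        "n_steps": config.n_steps,
        "order": config.order,
        "snapshot_stride": config.snapshot_stride,
        "chemistry": dataclasses.asdict(config.params),
        "solver": dataclasses.asdict(config.solver),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_manifest(path: str | Path, config: SimulationConfig, mesh: TriMesh,
                   seeds: dict | None = None, files: list[str] | None = None) -> None:
    """Run manifest: everything needed to re-run the simulation bit-reproducibly."""
    from . import __version__

    data = {
        "package": {"name": "rdfem", "version": __version__},
        "config": {
            "tau": config.tau,
            "n_steps": config.n_steps,
            "order": config.order,
            "snapshot_stride": config.snapshot_stride,
            "chemistry": dataclasses.asdict(config.params),
            "solver": dataclasses.asdict(config.solver),
        },
        "mesh": {"n_nodes": mesh.n_nodes, "n_triangles": mesh.n_triangles},
        "seeds": seeds or {},
        "files": files or [],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
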