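"""Reactor geometries: synthetic mazes, binarized raster images, starting zones.

The reactor Ω is represented as a :class:`RasterMask` — a binary occupancy
grid in image convention (row 0 at the top; ``cells[r, c]`` is True where
the pixel belongs to the reactor interior, False on walls).  Maze-like
geometries with corridors, right-angle corners, junctions and cul-de-sacs
are generated with a recursive-backtracker ("perfect maze") algorithm, the
standard construction that guarantees every corridor cell is reachable and
that dead ends occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError

__all__ = ["RasterMask", "ZoneSpec", "generate_maze", "binarize", "starting_zone"]


@dataclass(frozen=True)
class RasterMask:
    """Binary occupancy grid defining the reactor region Ω.

    Attributes
    ----------
    cells:
        Boolean array of shape ``(height, width)``; True = inside the
        reactor, False = wall.  Row 0 is the top of the image.
    """

    cells: np.ndarray

    def __post_init__(self):
        cells = np.asarray(self.cells, dtype=bool)
        if cells.ndim != 2 or cells.size == 0:
            raise GeometryError("mask must be a non-empty 2-D boolean grid")
        object.__setattr__(self, "cells", cells)

    @property
    def height(self) -> int:
        return self.cells.shape[0]

    @property
    def width(self) -> int:
        return self.cells.shape[1]

    @property
    def n_open(self) -> int:
        return int(self.cells.sum())

    def is_connected(self) -> bool:
        """True if the open pixels form a single 4-connected component."""
        if self.n_open == 0:
            return False
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
        _, n_comp = ndimage.label(self.cells, structure=structure)
        return n_comp == 1


@dataclass(frozen=True)
class ZoneSpec:
    """Axis-aligned rectangle in pixel coordinates (image convention).

    ``rows`` and ``cols`` are half-open ``(start, stop)`` ranges; the zone
    is the set of open pixels inside the rectangle.  Used to place the
    initial-condition support ("starting area").
    """

    rows: tuple[int, int]
    cols: tuple[int, int]

    def pixel_mask(self, mask: RasterMask) -> np.ndarray:
        out = np.zeros_like(mask.cells)
        r0, r1 = self.rows
        c0, c1 = self.cols
        out[max(r0, 0):max(r1, 0), max(c0, 0):max(c1, 0)] = True
        return out & mask.cells


def generate_maze(
    n_cols: int, n_rows: int, corridor_px: int = 4, wall_px: int = 1, seed: int = 0
) -> RasterMask:
    """Generate a perfect maze as a binary raster.

    The maze is laid out on an ``n_cols`` x ``n_rows`` grid of corridor
    cells, each ``corridor_px`` pixels square, separated (and surrounded)
    by walls ``wall_px`` pixels thick.  Passages are carved with the
    recursive-backtracker algorithm: a depth-first walk over the cell grid
    whose spanning tree guarantees full connectivity, no loops, and dead
    ends whenever there are at least three cells.

    Parameters
    ----------
    n_cols, n_rows:
        Maze extent in corridor cells (>= 1).
    corridor_px:
        Corridor width in pixels (>= 1).
    wall_px:
        Wall thickness in pixels (>= 1).
    seed:
        Seeds the random walk; identical arguments give a bit-identical mask.
    """
    if n_cols < 1 or n_rows < 1 or corridor_px < 1 or wall_px < 1:
        raise ParameterError("maze dimensions and pixel sizes must be >= 1")

    rng = np.random.default_rng(seed)
    visited = np.zeros((n_rows, n_cols), dtype=bool)
    # carved[r, c, d] — passage open from cell (r, c) toward d: 0=N,1=E,2=S,3=W
    carved = np.zeros((n_rows, n_cols, 4), dtype=bool)
    moves = {0: (-1, 0), 1: (0, 1), 2: (1, 0), 3: (0, -1)}
    opposite = {0: 2, 1: 3, 2: 0, 3: 1}

    stack = [(0, 0)]
    visited[0, 0] = True
    while stack:
        r, c = stack[-1]
        options = []
        for d, (dr, dc) in moves.items():
            nr, nc = r + dr, c + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols and not visited[nr, nc]:
                options.append((d, nr, nc))
        if not options:
            stack.pop()
            continue
        d, nr, nc = options[rng.integers(len(options))]
        carved[r, c, d] = True
        carved[nr, nc, opposite[d]] = True
        visited[nr, nc] = True
        stack.append((nr, nc))

    pitch = corridor_px + wall_px
    h = n_rows * pitch + wall_px
    w = n_cols * pitch + wall_px
    cells = np.zeros((h, w), dtype=bool)
    for r in range(n_rows):
        for c in range(n_cols):
            y0 = wall_px + r * pitch
            x0 = wall_px + c * pitch
            cells[y0:y0 + corridor_px, x0:x0 + corridor_px] = True
            if carved[r, c, 1]:  # east passage
                cells[y0:y0 + corridor_px, x0 + corridor_px:x0 + pitch] = True
            if carved[r, c, 2]:  # south passage
                cells[y0 + corridor_px:y0 + pitch, x0:x0 + corridor_px] = True
    return RasterMask(cells)


def binarize(image: np.ndarray, threshold: float = 0.5) -> RasterMask:
    """Threshold a grayscale raster into a reactor mask.

    A pixel belongs to the reactor iff its intensity (normalized to [0, 1])
    exceeds ``threshold``: white = open interior, black = wall, the usual
    convention for maze images with dark walls.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:  # collapse RGB(A) to luma by plain averaging of color channels
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2 or arr.size == 0:
        raise GeometryError("image must be a non-empty 2-D grayscale raster")
    if arr.max() > 1.0:
        arr = arr / 255.0
    cells = arr > threshold
    if not cells.any():
        raise GeometryError("binarization produced an empty reactor (no open pixels)")
    return RasterMask(cells)


def default_zone(mask: RasterMask) -> ZoneSpec:
    """Bottom strip of height max(1, 5% of the image height)."""
    strip = max(1, int(0.05 * mask.height))
    return ZoneSpec(rows=(mask.height - strip, mask.height), cols=(0, mask.width))


def starting_zone(mask: RasterMask, spec: ZoneSpec | None = None) -> np.ndarray:
    """Pixel set where the initial concentrations are 1.

    Returns a boolean grid (same shape as the mask) that is True on the
    open pixels inside the zone.  Defaults to a strip along the bottom of
    the image, the conventional placement for the wave's starting area.
    """
    if spec is None:
        spec = default_zone(mask)
    zone = spec.pixel_mask(mask)
    if not zone.any():
        raise GeometryError("starting zone does not intersect the reactor")
    return zone
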