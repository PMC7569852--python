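import numpy as np
import pytest

import rdfem


def cross2(u, v):
    return u[0] * v[1] - u[1] * v[0]


@pytest.fixture(scope="session")
def single_pixel_mesh():
    return rdfem.build_mesh(rdfem.RasterMask(np.ones((1, 1), bool)), 1)


@pytest.fixture(scope="session")
def rect_mesh():
    """All-open 5x3 rectangle at subdivision 2 (simply connected)."""
    return rdfem.build_mesh(rdfem.RasterMask(np.ones((3, 5), bool)), 2)


@pytest.fixture(scope="session")
def maze_mesh():
    """Small maze mesh (~1k nodes) with corners, junctions and dead ends."""
    mask = rdfem.generate_maze(5, 5, 3, 1, seed=3)
    return rdfem.build_mesh(mask, 1)


@pytest.fixture(scope="session")
def maze_matrices(maze_mesh):
    return rdfem.assemble(maze_mesh)


@pytest.fixture(scope="session")
def rect_matrices(rect_mesh):
    return rdfem.assemble(rect_mesh)


def random_triangle(rng, min_area=0.05):
    """Random non-degenerate CCW triangle."""
    while True:
        p = rng.uniform(-5, 5, size=(3, 2))
        area = 0.5 * cross2(p[1] - p[0], p[2] - p[0])
        if area < 0:
            p = p[[0, 2, 1]]
            area = -area
        if area > min_area:
            return p
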