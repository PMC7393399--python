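import numpy as np
import pytest

import lesioncorr as lc


@pytest.fixture(scope="session")
def icosphere2():
    """Unit icosphere, 162 vertices."""
    return lc.make_icosphere(2, 1.0)


@pytest.fixture(scope="session")
def icosphere3():
    """Unit icosphere, 642 vertices."""
    return lc.make_icosphere(3, 1.0)


@pytest.fixture(scope="session")
def subject3():
    """Default synthetic subject at subdivision 3 (642 vertices/hemisphere)."""
    return lc.make_subject(11, subdivisions=3)


@pytest.fixture
def single_triangle():
    """Right triangle in the z=0 plane, area 1/2."""
    return lc.SurfaceMesh(
        np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
        np.array([[0, 1, 2]]),
    )


def equator_band_cycle(mesh):
    """A closed vertex cycle hugging the z=0 equator of an icosphere.

    Walks the adjacency graph greedily by angular position, staying among
    vertices whose |z| is minimal-ish; used as a known closed boundary.
    """
    graph = lc.AdjacencyGraph.from_mesh(mesh)
    v = mesh.vertex_coords
    start = int(np.argmin(np.abs(v[:, 2]) + np.abs(np.arctan2(v[:, 1], v[:, 0]))))
    cycle = [start]
    while True:
        u = cycle[-1]
        ang_u = np.arctan2(v[u, 1], v[u, 0])
        best, best_d = None, None
        for w in graph.nbrs(u):
            w = int(w)
            if len(cycle) > 2 and w == cycle[0]:
                return cycle
            if w in cycle:
                continue
            ang_w = np.arctan2(v[w, 1], v[w, 0])
            dang = (ang_w - ang_u) % (2 * np.pi)
            if not (0 < dang < np.pi / 2):
                continue
            score = abs(v[w, 2]) + 0.2 * dang
            if best is None or score < best_d:
                best, best_d = w, score
        assert best is not None, "failed to trace an equatorial cycle"
        cycle.append(best)
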