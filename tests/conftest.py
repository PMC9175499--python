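import numpy as np
import pytest

import p16foci as p


@pytest.fixture
def unit_square_region():
    return p.TissueRegion(outer_ring=[(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def annulus_region():
    """10×10 square with a central 4×4 hole."""
    return p.TissueRegion(
        outer_ring=[(0, 0), (10, 0), (10, 10), (0, 10)],
        holes=[[(3, 3), (7, 3), (7, 7), (3, 7)]],
    )


@pytest.fixture(scope="session")
def dsp_experiment():
    """Default-condition DSP experiment (1825 genes, 12/6/6 ROIs) + truth."""
    return p.gen_dsp(p.DSPSimSpec(seed=11))


@pytest.fixture(scope="session")
def study_cohort():
    return p.study_structure_cohort()


def random_simple_polygon(rng, n_vertices=8, radius=10.0):
    """Star-shaped (hence simple) polygon around a random center."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.2 * radius, radius, n_vertices)
    cx, cy = rng.uniform(-5, 5, 2)
    return [(cx + r * np.cos(a), cy + r * np.sin(a)) for r, a in zip(radii, angles)]


def winding_number_inside(point, ring):
    """Brute-force winding-number point-in-polygon (boundary not handled)."""
    x, y = point
    wn = 0
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if y1 <= y:
            if y2 > y and (x2 - x1) * (y - y1) - (x - x1) * (y2 - y1) > 0:
                wn += 1
        else:
            if y2 <= y and (x2 - x1) * (y - y1) - (x - x1) * (y2 - y1) < 0:
                wn -= 1
    return wn != 0
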