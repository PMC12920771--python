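import numpy as np
import pytest

from landgen.genio import GenotypeMatrix
from landgen.landscape import SiteLocations
from landgen.synth import make_barrier_raster, simulate_pairwise_response
from landgen.landscape import build_conductance, commute_matrix, pixel_graph


@pytest.fixture
def tiny_gm() -> GenotypeMatrix:
    """3 individuals, 2 populations, 2 loci — round-trip scale fixture."""
    inds = ["a1", "a2", "b1"]
    pops = {"a1": "A", "a2": "A", "b1": "B"}
    calls = np.array([
        [[1, 2], [3, 3]],
        [[2, 2], [0, 0]],
        [[1, 1], [3, 4]],
    ])
    return GenotypeMatrix(inds, pops, ["locA", "locB"], calls,
                          coords={"A": (500000.0, 4500000.0),
                                  "B": (503000.0, 4504000.0)})


@pytest.fixture
def oracle_pair_gm() -> GenotypeMatrix:
    """Two populations, one biallelic locus, n = 10 each.

    pop1: 10 x (1,2)  -> p = (0.5, 0.5), Ho = 1.0
    pop2: 8 x (1,1) + 2 x (1,2) -> p = (0.9, 0.1), Ho = 0.2
    """
    inds = [f"x{i}" for i in range(10)] + [f"y{i}" for i in range(10)]
    pops = {i: ("P1" if i.startswith("x") else "P2") for i in inds}
    calls = np.zeros((20, 1, 2), dtype=int)
    calls[:10] = [1, 2]
    calls[10:18] = [1, 1]
    calls[18:] = [1, 2]
    return GenotypeMatrix(inds, pops, ["loc"], calls)


def barrier_world(barrier_weight: float = 0.1, seed: int = 0,
                  size=(24, 32), band: int = 4, per_side: int = 4):
    """Two-class barrier landscape with *per_side* sites per side and an
    MLPE-noised response generated from the true commute distances."""
    raster = make_barrier_raster(size=size, band_width=band)
    rows = np.linspace(2, size[0] - 3, per_side).astype(int)
    left = [(int(r), 3) for r in rows]
    right = [(int(r), size[1] - 4) for r in rows]
    cells = left + right
    labels = [f"p{i+1}" for i in range(len(cells))]
    coords = {l: raster.cell_center(r, c) for l, (r, c) in zip(labels, cells)}
    sites = SiteLocations(labels=labels, cells=cells, coords=coords)
    weights = {1: 1.0, 2: barrier_weight}
    commute = commute_matrix(pixel_graph(build_conductance(raster, weights)),
                             sites)
    response = simulate_pairwise_response(commute, beta0=0.21, beta1=0.06,
                                          sigma=0.04, rho=0.3, seed=seed)
    return raster, sites, weights, commute, response


@pytest.fixture
def barrier_setup():
    return barrier_world()
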