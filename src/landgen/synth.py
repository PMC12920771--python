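"""Synthetic landscapes, sites, pairwise responses and genotypes.

Everything the analysis consumes can be generated here with known ground
truth, so every pipeline stage is testable without field data.  The
default scenario mirrors a plateau-scale study system: 14 populations of
20 diploids, 11 microsatellite loci, pairwise differentiation in roughly
the 0.04-0.42 band, and categorical rasters with contiguous patches.

Components
----------
* rasters: a Gaussian-smoothed white-noise field cut at equal quantiles
  into ``nclasses`` patchy classes (patchiness = blur kernel width, cells);
* sites: rejection-sampled cell centers with a minimum pairwise
  separation;
* pairwise responses: y = beta0 + beta1 z(D) + eps with eps drawn from the
  MLPE covariance sigma^2 C(rho) — exactly the model class the regression
  assumes;
* genotypes: a hierarchical F-model — ancestral allele frequencies per
  locus ~ Dirichlet(1), population frequencies ~ Dirichlet(p (1-F)/F),
  individuals drawn in Hardy-Weinberg proportions within populations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .differentiation import PairwiseMatrix
from .genio import ClassRaster, GenotypeMatrix
from .landscape import SiteLocations, build_conductance, commute_matrix, pixel_graph
from .mlpe import mlpe_correlation

__all__ = [
    "SyntheticScenario",
    "ScenarioData",
    "simulate_class_raster",
    "make_barrier_raster",
    "place_sites",
    "simulate_pairwise_response",
    "simulate_genotypes",
]


def simulate_class_raster(size: tuple[int, int], nclasses: int,
                          patchiness: float, seed: int,
                          cellsize: float = 100.0,
                          origin: tuple[float, float] = (500_000.0, 4_500_000.0),
                          ) -> ClassRaster:
    """Patchy categorical raster from a smoothed random field.

    White noise is blurred with a Gaussian kernel of width *patchiness*
    (cells) and cut at equal quantiles, so each class covers an equal share
    of cells in contiguous patches.  The default origin places the grid at
    plausible projected (UTM-like) coordinates.
    """
    if nclasses < 1:
        raise ValueError("nclasses must be >= 1")
    rng = np.random.default_rng(seed)
    field_vals = gaussian_filter(rng.standard_normal(size), sigma=patchiness)
    qs = np.quantile(field_vals, np.linspace(0, 1, nclasses + 1)[1:-1])
    data = np.searchsorted(qs, field_vals) + 1  # classes 1..nclasses
    return ClassRaster(data=data, mask=np.ones(size, dtype=bool),
                       cellsize=cellsize, xll=origin[0], yll=origin[1])


def make_barrier_raster(size: tuple[int, int] = (24, 32), band_width: int = 4,
                        cellsize: float = 100.0,
                        origin: tuple[float, float] = (500_000.0, 4_500_000.0),
                        ) -> ClassRaster:
    """Two-class fixture: matrix (class 1) split by a vertical barrier band
    (class 2) through the middle columns."""
    data = np.ones(size, dtype=np.int64)
    mid = size[1] // 2
    data[:, mid - band_width // 2: mid + (band_width + 1) // 2] = 2
    return ClassRaster(data=data, mask=np.ones(size, dtype=bool),
                       cellsize=cellsize, xll=origin[0], yll=origin[1])


def place_sites(raster: ClassRaster, n: int, min_sep: float, seed: int,
                max_rejects: int = 10_000) -> SiteLocations:
    """Rejection-sample *n* cell-center sites with pairwise distance
    >= *min_sep* (in cells) on non-nodata cells."""
    rng = np.random.default_rng(seed)
    valid = np.argwhere(raster.mask)
    cells: list[tuple[int, int]] = []
    rejects = 0
    while len(cells) < n:
        r, c = valid[rng.integers(0, len(valid))]
        if all(math.hypot(r - r0, c - c0) >= min_sep for r0, c0 in cells):
            cells.append((int(r), int(c)))
            rejects = 0
        else:
            rejects += 1
            if rejects >= max_rejects:
                raise RuntimeError(
                    f"could not place {n} sites with min_sep={min_sep} "
                    f"({max_rejects} consecutive rejections)"
                )
    labels = [f"p{i + 1}" for i in range(n)]
    coords = {l: raster.cell_center(r, c) for l, (r, c) in zip(labels, cells)}
    return SiteLocations(labels=labels, cells=cells, coords=coords)


def simulate_pairwise_response(D: PairwiseMatrix, beta0: float, beta1: float,
                               sigma: float, rho: float, seed: int
                               ) -> PairwiseMatrix:
    """Pairwise response linear in z-scored D with MLPE-correlated noise.

    y = beta0 + beta1 * z(D) + eps,  eps ~ N(0, sigma^2 C(rho)) with C the
    MLPE correlation of the population-pair incidence.  Returned as a
    PairwiseMatrix so it can stand in for a genetic-distance matrix.
    """
    pops = list(D.labels)
    pairs = list(itertools.combinations(pops, 2))
    d = D.upper_triangle()
    sd = d.std(ddof=0)
    z = (d - d.mean()) / sd if sd > 0 else np.zeros_like(d)
    Z = np.zeros((len(pairs), len(pops)))
    for r, (a, b) in enumerate(pairs):
        Z[r, pops.index(a)] = 1.0
        Z[r, pops.index(b)] = 1.0
    mean = beta0 + beta1 * z
    if sigma > 0:
        C = mlpe_correlation(Z, rho)
        L = np.linalg.cholesky(C)
        rng = np.random.default_rng(seed)
        eps = sigma * (L @ rng.standard_normal(len(pairs)))
    else:
        eps = np.zeros(len(pairs))
    return PairwiseMatrix.from_pairs(
        pops, {pair: v for pair, v in zip(pairs, mean + eps)}, kind="response")


def simulate_genotypes(npops: int, F, nloci: int, nalleles: int,
                       n_per_pop: int, seed: int,
                       pop_labels: list[str] | None = None,
                       coords: dict[str, tuple[float, float]] | None = None,
                       ) -> GenotypeMatrix:
    """Hierarchical F-model genotype simulator.

    *F* is a scalar or per-population vector of drift parameters in [0, 1):
    population allele frequencies are Dirichlet-distributed around shared
    ancestral frequencies (Dirichlet(1) per locus) with total concentration
    (1 - F_p) / F_p, and individuals are drawn as two independent alleles
    per locus (Hardy-Weinberg within populations).
    """
    F = np.broadcast_to(np.asarray(F, dtype=float), (npops,)).copy()
    if np.any((F < 0) | (F >= 1)):
        raise ValueError("F values must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    labels = pop_labels or [f"p{i + 1}" for i in range(npops)]
    individuals: list[str] = []
    populations: dict[str, str] = {}
    calls = np.zeros((npops * n_per_pop, nloci, 2), dtype=np.int64)
    anc = rng.dirichlet(np.ones(nalleles), size=nloci)  # (nloci, nalleles)
    for pi, pop in enumerate(labels):
        for li in range(nloci):
            fp = F[pi]
            if fp < 1e-9:
                p = anc[li]
            else:
                conc = anc[li] * (1.0 - fp) / fp
                p = rng.dirichlet(np.maximum(conc, 1e-8))
            draws = rng.choice(nalleles, size=(n_per_pop, 2), p=p) + 1
            rows = slice(pi * n_per_pop, (pi + 1) * n_per_pop)
            calls[rows, li] = draws
        for k in range(n_per_pop):
            ind = f"{pop}_i{k + 1}"
            individuals.append(ind)
            populations[ind] = pop
    return GenotypeMatrix(individuals=individuals, populations=populations,
                          loci=[f"L{j + 1}" for j in range(nloci)],
                          calls=calls, coords=dict(coords or {}))


# ---------------------------------------------------------------------------
# full scenarios
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScenario:
    """Ground-truth parameters for an end-to-end synthetic study.

    Defaults mirror the plateau-scale study conditions: 14 populations of
    20 diploids at 11 loci, a 100 x 100-cell landscape, response slope
    beta1 > 0 (differentiation increases with commute distance), MLPE
    rho = 0.3, and per-population drift mapped affinely from mean commute
    distance into ``f_range``.
    """

    seed: int = 0
    shape: tuple[int, int] = (100, 100)
    nclasses: int = 3
    patchiness: float = 8.0
    true_weights: dict[int, float] | None = None
    npops: int = 14
    min_sep: float = 8.0
    beta0: float = 0.21
    beta1: float = 0.06
    sigma: float = 0.04
    rho: float = 0.3
    nloci: int = 11
    nalleles: int = 10
    n_per_pop: int = 20
    f_range: tuple[float, float] = (0.02, 0.15)

    def default_weights(self) -> dict[int, float]:
        # class 1 permeable .. last class a strong barrier
        codes = list(range(1, self.nclasses + 1))
        if self.nclasses == 1:
            return {1: 1.0}
        levels = np.linspace(1.0, 0.1, self.nclasses)
        return {c: float(w) for c, w in zip(codes, levels)}

    def generate(self) -> "ScenarioData":
        weights = self.true_weights or self.default_weights()
        raster = simulate_class_raster(self.shape, self.nclasses,
                                       self.patchiness, seed=self.seed)
        sites = place_sites(raster, self.npops, self.min_sep,
                            seed=self.seed + 1)
        surface = build_conductance(raster, weights)
        commute = commute_matrix(pixel_graph(surface), sites)
        response = simulate_pairwise_response(
            commute, self.beta0, self.beta1, self.sigma, self.rho,
            seed=self.seed + 2)
        # per-population drift from mean commute distance to the others
        mean_commute = (commute.values.sum(axis=1)
                        / (commute.n - 1))
        lo, hi = mean_commute.min(), mean_commute.max()
        span = hi - lo if hi > lo else 1.0
        f_lo, f_hi = self.f_range
        F = f_lo + (mean_commute - lo) / span * (f_hi - f_lo)
        genotypes = simulate_genotypes(
            self.npops, F, self.nloci, self.nalleles, self.n_per_pop,
            seed=self.seed + 3, pop_labels=sites.labels, coords=sites.coords)
        return ScenarioData(scenario=self, raster=raster, sites=sites,
                            true_weights=weights, commute=commute,
                            response=response, F=F, genotypes=genotypes)


@dataclass
class ScenarioData:
    scenario: SyntheticScenario
    raster: ClassRaster
    sites: SiteLocations
    true_weights: dict[int, float]
    commute: PairwiseMatrix
    response: PairwiseMatrix
    F: np.ndarray
    genotypes: GenotypeMatrix
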