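"""Conductance surfaces, 8-neighbour pixel graphs and commute distances.

A categorical raster plus a per-class conductance weight vector (values in
[0, 1]) yields a per-cell conductance surface.  The surface induces a
weighted graph over non-nodata cells: 8-neighbour edges with conductance
w_ij = mean(c_i, c_j) / d_ij, where d_ij is 1 for rook moves and sqrt(2)
for diagonal moves (in cell units) — the diagonal geo-correction.

The commute distance between two sites is the expected round-trip time of
the random walk on that graph, C(i, j) = 2 W R_eff(i, j), with W the total
edge conductance and R_eff the effective resistance obtained from the graph
Laplacian.  C is invariant to globally rescaling all class weights, which
is why only weight *ratios* are identifiable downstream.

Weights below EPS = 1e-6 are clamped to EPS so that a zero weight models a
near-impermeable (not infinitely resistant, hence still connected) barrier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import factorized

from .genio import ClassRaster

__all__ = [
    "EPS",
    "ConductanceSurface",
    "PixelGraph",
    "SiteLocations",
    "DisconnectedError",
    "build_conductance",
    "pixel_graph",
    "commute_matrix",
    "snap_sites",
]

EPS = 1e-6  # conductance floor


class DisconnectedError(Exception):
    """Sites fall in different graph components (impermeable configuration)."""


@dataclass
class ConductanceSurface:
    raster: ClassRaster
    values: np.ndarray  # per-cell conductance in [EPS, 1]; nodata untouched


@dataclass
class SiteLocations:
    labels: list[str]
    cells: list[tuple[int, int]]     # (row, col) on the raster grid
    coords: dict[str, tuple[float, float]]

    def cell_of(self, label: str) -> tuple[int, int]:
        return self.cells[self.labels.index(label)]


def build_conductance(raster: ClassRaster, weights: dict[int, float]
                      ) -> ConductanceSurface:
    """Per-cell conductance from class codes, clamped to [EPS, 1]."""
    codes = raster.classes()
    unmapped = [int(c) for c in codes if int(c) not in weights]
    if unmapped:
        raise ValueError(f"no conductance weight for class codes {unmapped}")
    bad = {c: w for c, w in weights.items() if not (0.0 <= w <= 1.0)}
    if bad:
        raise ValueError(f"weights outside [0, 1]: {bad}")
    values = np.full(raster.shape, np.nan)
    for code in codes:
        values[raster.data == code] = np.clip(weights[int(code)], EPS, 1.0)
    values[~raster.mask] = np.nan
    return ConductanceSurface(raster=raster, values=values)


# ---------------------------------------------------------------------------
# pixel graph
# ---------------------------------------------------------------------------

# forward-neighbour offsets (each undirected edge appears once)
_OFFSETS = ((0, 1, 1.0), (1, 0, 1.0), (1, 1, math.sqrt(2.0)),
            (1, -1, math.sqrt(2.0)))


@dataclass
class PixelGraph:
    n_nodes: int
    node_ids: np.ndarray          # (nrows, ncols) int; -1 where nodata
    edges: np.ndarray             # (E, 2) node-index pairs
    conductances: np.ndarray      # (E,) edge conductances
    total_conductance: float      # W = sum of edge conductances

    def adjacency(self) -> csr_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = self.conductances
        a = coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        return a.tocsr()


def _grid_structure(mask: np.ndarray):
    """Node ids plus the (cell_i, cell_j, 1/d) arrays of all valid edges."""
    node_ids = np.full(mask.shape, -1, dtype=np.int64)
    node_ids[mask] = np.arange(int(mask.sum()))
    src: list[np.ndarray] = []
    dst: list[np.ndarray] = []
    inv_d: list[np.ndarray] = []
    nrows, ncols = mask.shape
    for dr, dc, d in _OFFSETS:
        r0 = slice(0, nrows - dr)
        r1 = slice(dr, nrows)
        if dc >= 0:
            c0, c1 = slice(0, ncols - dc), slice(dc, ncols)
        else:
            c0, c1 = slice(-dc, ncols), slice(0, ncols + dc)
        valid = mask[r0, c0] & mask[r1, c1]
        src.append(node_ids[r0, c0][valid])
        dst.append(node_ids[r1, c1][valid])
        inv_d.append(np.full(int(valid.sum()), 1.0 / d))
    return (node_ids, np.concatenate(src), np.concatenate(dst),
            np.concatenate(inv_d))


def pixel_graph(surface: ConductanceSurface) -> PixelGraph:
    """Weighted 8-neighbour graph over the non-nodata cells of a surface."""
    mask = surface.raster.mask
    if int(mask.sum()) < 2:
        raise ValueError("surface must have at least two non-nodata cells")
    node_ids, src, dst, inv_d = _grid_structure(mask)
    c = surface.values[mask]
    w = 0.5 * (c[src] + c[dst]) * inv_d
    return PixelGraph(
        n_nodes=int(mask.sum()),
        node_ids=node_ids,
        edges=np.column_stack([src, dst]),
        conductances=w,
        total_conductance=float(w.sum()),
    )


# ---------------------------------------------------------------------------
# commute distances via the graph Laplacian
# ---------------------------------------------------------------------------

def _site_nodes(graph: PixelGraph, sites: SiteLocations) -> np.ndarray:
    nodes = []
    for label, (r, c) in zip(sites.labels, sites.cells):
        nid = graph.node_ids[r, c]
        if nid < 0:
            raise ValueError(f"site {label!r} maps to a nodata cell")
        nodes.append(int(nid))
    return np.asarray(nodes)


def _resistance_submatrix(adj: csr_matrix, nodes: np.ndarray,
                          method: str) -> np.ndarray:
    """Effective resistances among *nodes* of a connected graph."""
    n = adj.shape[0]
    if method == "pinv":
        lap = np.diag(np.asarray(adj.sum(axis=1)).ravel()) - adj.toarray()
        # rcond must dominate the numerical error of the Laplacian's null
        # singular value, which np.linalg.pinv's default misses
        lplus = np.linalg.pinv(lap, hermitian=True, rcond=1e-8)
        d = lplus[np.ix_(nodes, nodes)]
        diag = np.diag(d)
        return diag[:, None] + diag[None, :] - 2 * d
    # sparse path: ground node 0 of the component, solve the reduced system
    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = (csr_matrix((deg, (np.arange(n), np.arange(n))), shape=(n, n))
           - adj).tocsc()
    ground = 0
    keep = np.arange(n) != ground
    reduced = lap[keep][:, keep]
    solve = factorized(reduced)
    pos = np.cumsum(keep) - 1  # node -> row in reduced system
    g = np.zeros((len(nodes), len(nodes)))
    cols = {}
    for a, node in enumerate(nodes):
        if node == ground:
            cols[a] = None
            continue
        e = np.zeros(n - 1)
        e[pos[node]] = 1.0
        cols[a] = solve(e)
    for a in range(len(nodes)):
        for b in range(len(nodes)):
            va = cols[a]
            g[a, b] = 0.0 if va is None or nodes[b] == ground else va[pos[nodes[b]]]
    diag = np.diag(g)
    return diag[:, None] + diag[None, :] - g - g.T


def commute_matrix(graph: PixelGraph, sites: SiteLocations,
                   method: str = "sparse",
                   return_resistance: bool = False):
    """Pairwise commute distances C = 2 W R_eff between site cells.

    ``method="pinv"`` uses the dense Laplacian pseudoinverse (small graphs
    and cross-checks); ``"sparse"`` solves the grounded Laplacian with a
    sparse LU factorization.  ``return_resistance=True`` yields raw
    effective resistances instead of commute times.
    """
    from .differentiation import PairwiseMatrix

    nodes = _site_nodes(graph, sites)
    adj = graph.adjacency()
    n_comp, comp = connected_components(adj, directed=False)
    site_comp = comp[nodes]
    if len(set(site_comp.tolist())) > 1:
        majority = np.bincount(site_comp).argmax()
        stranded = [l for l, c in zip(sites.labels, site_comp) if c != majority]
        raise DisconnectedError(
            f"sites {stranded} are disconnected from the rest (class weights "
            "describe an impermeable barrier)"
        )
    if n_comp > 1:
        keep = comp == site_comp[0]
        remap = np.cumsum(keep) - 1
        adj = adj[keep][:, keep]
        nodes = remap[nodes]
    if method not in {"sparse", "pinv"}:
        raise ValueError(f"unknown method {method!r}")
    reff = _resistance_submatrix(adj, nodes, method)
    reff = (reff + reff.T) / 2.0
    np.fill_diagonal(reff, 0.0)
    values = reff if return_resistance else 2.0 * graph.total_conductance * reff
    kind = "resistance" if return_resistance else "commute"
    return PairwiseMatrix(list(sites.labels), values, kind)


# ---------------------------------------------------------------------------
# site snapping
# ---------------------------------------------------------------------------

def snap_sites(raster: ClassRaster, coords: dict[str, tuple[float, float]],
               radius: int = 3) -> SiteLocations:
    """Assign each site its containing cell, nudging off nodata if needed.

    Sites on a nodata cell are moved to the nearest valid cell within
    *radius* cells; farther sites raise.  Two sites snapping to the same
    cell trigger a warning (their commute distance will be zero).
    """
    nrows, ncols = raster.shape
    cells: list[tuple[int, int]] = []
    for label, (x, y) in coords.items():
        r, c = raster.cell_of(x, y)
        r = min(max(r, 0), nrows - 1)
        c = min(max(c, 0), ncols - 1)
        if not raster.mask[r, c]:
            best = None
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrows and 0 <= cc < ncols and raster.mask[rr, cc]:
                        dist = math.hypot(dr, dc)
                        if best is None or dist < best[0]:
                            best = (dist, rr, cc)
            if best is None:
                raise ValueError(
                    f"site {label!r} is farther than {radius} cells from any "
                    "valid cell"
                )
            r, c = best[1], best[2]
        cells.append((r, c))
    if len(set(cells)) < len(cells):
        warnings.warn("multiple sites snap to the same raster cell; their "
                      "commute distance will be zero", stacklevel=2)
    return SiteLocations(labels=list(coords), cells=cells, coords=dict(coords))
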