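"""Pairwise population differentiation, geographic distances and Mantel tests.

Hedrick's G'ST and Jost's D are computed per population pair (k = 2) from
Nei-Chesser small-sample estimators of within- (H_S) and total- (H_T)
heterozygosity using the harmonic mean sample size.  Multi-locus values
aggregate across-locus means of H_S and H_T (not means of per-locus
ratios).  Negative estimates are reported as computed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, _check_projected

__all__ = [
    "PairwiseMatrix",
    "pairwise_differentiation",
    "differentiation_matrices",
    "matrix_correlation",
    "geo_distance_matrix",
    "mantel_test",
]


@dataclass
class PairwiseMatrix:
    """Symmetric labeled matrix over populations with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.labels)
        if len(set(self.labels)) != p:
            raise ValueError("pairwise matrix labels must be unique")
        if self.values.shape != (p, p):
            raise ValueError("values shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("pairwise matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("pairwise matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.labels, 2))

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def mean_offdiag(self) -> float:
        return float(self.upper_triangle().mean())

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def reorder(self, labels: list[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels
                     ).to_csv(path, index_label="population")

    @classmethod
    def from_csv(cls, path, kind: str = "generic") -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), kind)

    @classmethod
    def from_pairs(cls, labels: list[str], pair_values: dict, kind: str = "generic"):
        p = len(labels)
        values = np.zeros((p, p))
        for (a, b), v in pair_values.items():
            i, j = labels.index(a), labels.index(b)
            values[i, j] = values[j, i] = v
        return cls(list(labels), values, kind)


# ---------------------------------------------------------------------------
# Hedrick G'ST and Jost D (pairwise, Nei-Chesser estimators)
# ---------------------------------------------------------------------------

def _locus_hs_ht(calls_a: np.ndarray, calls_b: np.ndarray
                 ) -> tuple[float, float] | None:
    """Nei-Chesser (H_S, H_T) for one locus and two populations (k = 2)."""
    n1, n2 = calls_a.shape[0], calls_b.shape[0]
    if n1 == 0 or n2 == 0:
        return None
    alleles = np.unique(np.concatenate([calls_a.ravel(), calls_b.ravel()]))
    if len(alleles) < 2:
        return None  # not polymorphic in the pair
    idx = {a: i for i, a in enumerate(alleles)}

    def freqs(calls: np.ndarray) -> np.ndarray:
        p = np.zeros(len(alleles))
        vals, counts = np.unique(calls.ravel(), return_counts=True)
        for v, c in zip(vals, counts):
            p[idx[v]] = c
        return p / p.sum()

    p1, p2 = freqs(calls_a), freqs(calls_b)
    ho1 = float((calls_a[:, 0] != calls_a[:, 1]).mean())
    ho2 = float((calls_b[:, 0] != calls_b[:, 1]).mean())
    ho_bar = (ho1 + ho2) / 2.0
    n_tilde = 2.0 / (1.0 / n1 + 1.0 / n2)  # harmonic mean sample size
    x_bar = (np.sum(p1 ** 2) + np.sum(p2 ** 2)) / 2.0
    hs = n_tilde / (n_tilde - 1.0) * (1.0 - x_bar - ho_bar / (2.0 * n_tilde))
    p_bar = (p1 + p2) / 2.0
    k = 2.0
    ht = (1.0 - float(np.sum(p_bar ** 2))
          + hs / (k * n_tilde) - ho_bar / (2.0 * k * n_tilde))
    return float(hs), float(ht)


def _indices_from_hs_ht(hs: float, ht: float, k: float = 2.0
                        ) -> tuple[float, float]:
    """(Hedrick G'ST, Jost D) from mean H_S and H_T."""
    if ht <= 0:
        return float("nan"), float("nan")
    gst = (ht - hs) / ht
    gst_h = gst * (k - 1.0 + hs) / ((k - 1.0) * (1.0 - hs))
    d = (k / (k - 1.0)) * (ht - hs) / (1.0 - hs)
    return gst_h, d


def pairwise_differentiation(gm: GenotypeMatrix, pop_a: str, pop_b: str
                             ) -> tuple[float, float]:
    """Multi-locus (Hedrick G'ST, Jost D) for one population pair.

    Raises ValueError when the pair shares no polymorphic genotyped locus.
    """
    hs_list: list[float] = []
    ht_list: list[float] = []
    rows_a = gm.individuals_of(pop_a)
    rows_b = gm.individuals_of(pop_b)
    for j in range(gm.n_loci):
        ca = gm.calls[rows_a, j]
        ca = ca[ca[:, 0] != MISSING]
        cb = gm.calls[rows_b, j]
        cb = cb[cb[:, 0] != MISSING]
        res = _locus_hs_ht(ca, cb)
        if res is not None:
            hs_list.append(res[0])
            ht_list.append(res[1])
    if not hs_list:
        raise ValueError(
            f"populations {pop_a!r} and {pop_b!r} share no polymorphic locus"
        )
    return _indices_from_hs_ht(float(np.mean(hs_list)), float(np.mean(ht_list)))


def differentiation_matrices(gm: GenotypeMatrix,
                             populations: list[str] | None = None
                             ) -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """All-pairs Hedrick G'ST and Jost D matrices."""
    pops = populations if populations is not None else gm.pop_labels
    p = len(pops)
    gst = np.zeros((p, p))
    d = np.zeros((p, p))
    for i, j in itertools.combinations(range(p), 2):
        g, dj = pairwise_differentiation(gm, pops[i], pops[j])
        gst[i, j] = gst[j, i] = g
        d[i, j] = d[j, i] = dj
    return (PairwiseMatrix(list(pops), gst, "gst"),
            PairwiseMatrix(list(pops), d, "jost_d"))


# ---------------------------------------------------------------------------
# matrix correlation, geographic distance, Mantel
# ---------------------------------------------------------------------------

def matrix_correlation(m1: PairwiseMatrix, m2: PairwiseMatrix
                       ) -> tuple[float, float]:
    """Pearson r (and r^2) over the vectorized upper triangles."""
    if set(m1.labels) != set(m2.labels):
        raise ValueError("pairwise matrices have different label sets")
    m2 = m2.reorder(m1.labels)
    x, y = m1.upper_triangle(), m2.upper_triangle()
    if x.size < 3:
        raise ValueError("matrix correlation needs at least 3 pairs")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r * r


def geo_distance_matrix(coords: dict[str, tuple[float, float]],
                        labels: list[str] | None = None) -> PairwiseMatrix:
    """Euclidean distance matrix from projected coordinates (metres)."""
    labels = list(coords) if labels is None else list(labels)
    missing = [l for l in labels if l not in coords]
    if missing:
        raise ValueError(f"missing coordinates for populations: {missing}")
    _check_projected({l: coords[l] for l in labels})
    xy = np.array([coords[l] for l in labels], dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    return PairwiseMatrix(labels, np.sqrt((diff ** 2).sum(axis=2)), "geographic")


def mantel_test(m_gen: PairwiseMatrix, m_geo: PairwiseMatrix,
                nperm: int = 10_000, seed: int = 0,
                exact: bool | None = None) -> tuple[float, float]:
    """One-sided (greater) Mantel test between two pairwise matrices.

    The null is built by simultaneous row/column permutation of the second
    matrix.  For fewer than 4 populations (or ``exact=True``) all P!
    permutations are enumerated instead of sampled.
    """
    if set(m_gen.labels) != set(m_geo.labels):
        raise ValueError("Mantel matrices have different label sets")
    m_geo = m_geo.reorder(m_gen.labels)
    p = m_gen.n
    x = m_gen.upper_triangle()
    iu = np.triu_indices(p, k=1)
    y_full = m_geo.values

    def corr_with(perm: np.ndarray) -> float:
        y = y_full[np.ix_(perm, perm)][iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr_with(np.arange(p))
    if exact is None:
        exact = p < 4
        if p < 4:
            warnings.warn("fewer than 4 populations: enumerating all "
                          "permutations exactly", stacklevel=2)
    if exact:
        perms = list(itertools.permutations(range(p)))
        count = sum(corr_with(np.array(pm)) >= r_obs - 1e-12 for pm in perms)
        return r_obs, count / len(perms)
    rng = np.random.default_rng(seed)
    if nperm < 99:
        raise ValueError("nperm must be at least 99")
    k = 0
    for _ in range(nperm):
        if corr_with(rng.permutation(p)) >= r_obs - 1e-12:
            k += 1
    return r_obs, (1 + k) / (nperm + 1)
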