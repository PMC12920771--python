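"""Per-population diversity indices and Monte-Carlo HWE/LD tests.

Diversity indices follow standard microsatellite practice: mean alleles per
locus (Na), observed heterozygosity (Ho), unbiased expected heterozygosity
He = (2n/(2n-1))(1 - sum p^2), the inbreeding coefficient FIS = 1 - Ho/He
per polymorphic locus, and private-allele counts.  Standard errors are
across-locus (sd / sqrt(L)).

The Hardy-Weinberg test is an exact-conditional Monte-Carlo test: allele
counts are held fixed and the 2n-allele pool is randomly re-paired; the
ordering statistic is the conditional (Levene) probability of the genotype
table, which is robust for multi-allelic loci.  The linkage test permutes
one locus's genotypes across individuals and scores the two-locus genotype
contingency table with a G-statistic.  Monte-Carlo p-values use the
add-one rule p = (1 + k) / (N + 1), so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .genio import MISSING, GenotypeMatrix

__all__ = [
    "DiversitySummary",
    "TestResult",
    "allele_frequencies",
    "diversity_summary",
    "diversity_table",
    "hwe_test",
    "ld_test",
    "holm_correction",
]


@dataclass
class DiversitySummary:
    population: str
    n: int
    na: float
    na_se: float | None
    ho: float
    ho_se: float | None
    he: float
    he_se: float | None
    fis: float | None
    fis_se: float | None
    private_alleles: int
    hw_significant: int | None = None


@dataclass
class TestResult:
    population: str
    locus: str
    statistic: float | None
    p_value: float | None
    replicates: int
    testable: bool
    significant: bool | None = None


def allele_frequencies(gm: GenotypeMatrix, population: str, locus: str
                       ) -> dict[int, float] | None:
    """Allele frequencies from the 2n observed allele draws.

    Returns None (the "absent" flag) when the population has no genotyped
    individual at the locus; downstream statistics skip such loci.
    """
    calls = gm.pop_calls(population, locus)
    if calls.size == 0:
        return None
    alleles, counts = np.unique(calls.ravel(), return_counts=True)
    total = counts.sum()
    return {int(a): float(c) / total for a, c in zip(alleles, counts)}


def _locus_stats(calls: np.ndarray) -> tuple[int, float, float] | None:
    """(Na, Ho, He) for the non-missing calls of one population x locus."""
    n = calls.shape[0]
    if n == 0:
        return None
    na = len(np.unique(calls.ravel()))
    ho = float((calls[:, 0] != calls[:, 1]).mean())
    _, counts = np.unique(calls.ravel(), return_counts=True)
    p = counts / (2 * n)
    he = (2 * n) / (2 * n - 1) * (1.0 - float(np.sum(p ** 2))) if n > 1 else 0.0
    return na, ho, he


def _se(values: list[float]) -> float | None:
    if len(values) < 2:
        return None
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def diversity_summary(gm: GenotypeMatrix, population: str,
                      hw_significant: int | None = None) -> DiversitySummary:
    """Across-locus diversity summary for one population.

    FIS is averaged over polymorphic loci only (He > 0); monomorphic loci
    contribute Na=1, Ho=0, He=0 but no FIS term.  Private alleles are
    counted against every other population present in *gm* — pass an
    area-subset matrix to scope them within a study area.
    """
    rows = gm.individuals_of(population)
    na_l: list[float] = []
    ho_l: list[float] = []
    he_l: list[float] = []
    fis_l: list[float] = []
    for j, locus in enumerate(gm.loci):
        calls = gm.calls[rows, j]
        calls = calls[calls[:, 0] != MISSING]
        stats = _locus_stats(calls)
        if stats is None:
            continue
        na, ho, he = stats
        na_l.append(na)
        ho_l.append(ho)
        he_l.append(he)
        if he > 0:
            fis_l.append(1.0 - ho / he)

    # private alleles: observed here and in no other population
    pa = 0
    others = [p for p in gm.pop_labels if p != population]
    for j in range(gm.n_loci):
        own = gm.calls[rows, j]
        own_alleles = set(np.unique(own[own > MISSING]))
        if not own_alleles:
            continue
        elsewhere: set[int] = set()
        for other in others:
            oc = gm.calls[gm.individuals_of(other), j]
            elsewhere.update(np.unique(oc[oc > MISSING]).tolist())
        pa += len(own_alleles - elsewhere)

    return DiversitySummary(
        population=population,
        n=len(rows),
        na=float(np.mean(na_l)),
        na_se=_se(na_l),
        ho=float(np.mean(ho_l)),
        ho_se=_se(ho_l),
        he=float(np.mean(he_l)),
        he_se=_se(he_l),
        fis=float(np.mean(fis_l)) if fis_l else None,
        fis_se=_se(fis_l),
        private_alleles=pa,
        hw_significant=hw_significant,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact Monte-Carlo test
# ---------------------------------------------------------------------------

def _log_table_prob(pairs: np.ndarray) -> float:
    """Log conditional probability of a genotype table given allele counts.

    Levene's distribution: P = n! 2^h prod_a m_a! / ((2n)! prod_{a<=b} n_ab!)
    with h the number of heterozygotes.  Terms constant under re-pairing are
    kept so the value is a genuine probability (useful for exact checks).
    """
    n = pairs.shape[0]
    h = int((pairs[:, 0] != pairs[:, 1]).sum())
    _, allele_counts = np.unique(pairs.ravel(), return_counts=True)
    # genotype table counts
    _, geno_counts = np.unique(pairs, axis=0, return_counts=True)
    return float(
        gammaln(n + 1) + h * np.log(2.0) + gammaln(allele_counts + 1).sum()
        - gammaln(2 * n + 1) - gammaln(geno_counts + 1).sum()
    )


def hwe_test(gm: GenotypeMatrix, population: str, locus: str,
             nreps: int = 10_000, seed: int = 0) -> TestResult:
    """Monte-Carlo exact test of Hardy-Weinberg genotypic proportions.

    Conditional on observed allele counts: each replicate randomly re-pairs
    the pooled 2n alleles and p = (1 + #{replicates with table probability
    <= observed}) / (nreps + 1).
    """
    calls = gm.pop_calls(population, locus)
    if calls.shape[0] == 0 or len(np.unique(calls.ravel())) < 2:
        return TestResult(population, locus, None, None, nreps, testable=False)
    obs = _log_table_prob(calls)
    pool = calls.ravel().copy()
    rng = np.random.default_rng(seed)
    k = 0
    tol = 1e-12
    for _ in range(nreps):
        rng.shuffle(pool)
        rep = np.sort(pool.reshape(-1, 2), axis=1)
        if _log_table_prob(rep) <= obs + tol:
            k += 1
    p = (1 + k) / (nreps + 1)
    return TestResult(population, locus, obs, p, nreps, testable=True)


# ---------------------------------------------------------------------------
# linkage disequilibrium permutation test
# ---------------------------------------------------------------------------

def _g_statistic(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """G-statistic of the two-locus genotype contingency table."""
    na = codes_a.max() + 1
    nb = codes_b.max() + 1
    table = np.zeros((na, nb))
    np.add.at(table, (codes_a, codes_b), 1.0)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def ld_test(gm: GenotypeMatrix, population: str, locus_a: str, locus_b: str,
            nperm: int = 10_000, seed: int = 0) -> TestResult:
    """Permutation test of genotypic association between two loci.

    The null distribution is built by permuting one locus's genotypes across
    individuals (within the population), breaking any between-locus
    association while preserving single-locus genotype frequencies.
    """
    rows = gm.individuals_of(population)
    ja, jb = gm.locus_index(locus_a), gm.locus_index(locus_b)
    a = gm.calls[rows, ja]
    b = gm.calls[rows, jb]
    ok = (a[:, 0] != MISSING) & (b[:, 0] != MISSING)
    a, b = a[ok], b[ok]
    label = f"{locus_a}x{locus_b}"
    if a.shape[0] == 0:
        return TestResult(population, label, None, None, nperm, testable=False)

    def codes(pairs: np.ndarray) -> np.ndarray:
        _, inv = np.unique(pairs, axis=0, return_inverse=True)
        return inv

    ca, cb = codes(a), codes(b)
    if ca.max() == 0 or cb.max() == 0:  # monomorphic genotype column
        return TestResult(population, label, None, None, nperm, testable=False)
    obs = _g_statistic(ca, cb)
    rng = np.random.default_rng(seed)
    k = 0
    perm = cb.copy()
    for _ in range(nperm):
        rng.shuffle(perm)
        if _g_statistic(ca, perm) >= obs - 1e-12:
            k += 1
    p = (1 + k) / (nperm + 1)
    return TestResult(population, label, obs, p, nperm, testable=True)


# ---------------------------------------------------------------------------
# sequential Bonferroni (Holm)
# ---------------------------------------------------------------------------

def holm_correction(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down (sequential Bonferroni) significance flags.

    Sort p ascending, compare p_(i) with alpha/(m-i+1), stop at the first
    failure; returns flags in the original order.  Flags are always a
    superset of the plain Bonferroni flags at the same alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] < alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags


def diversity_table(gm: GenotypeMatrix, nreps: int = 10_000, seed: int = 0,
                    alpha: float = 0.05):
    """Per-population diversity summaries with Holm-corrected HWE counts.

    HWE tests are run for every (population, locus); the Holm correction is
    applied within each population across its loci, mirroring per-population
    multiple-test families.  Returns a pandas DataFrame in the conventional
    column order (population, N, Na, Ho, He, FIS, HW, PA).
    """
    import pandas as pd

    rows = []
    for pi, pop in enumerate(gm.pop_labels):
        results = [hwe_test(gm, pop, locus, nreps=nreps, seed=seed + 1000 * pi + j)
                   for j, locus in enumerate(gm.loci)]
        testable = [r for r in results if r.testable]
        flags = holm_correction([r.p_value for r in testable], alpha=alpha) \
            if testable else np.zeros(0, bool)
        summ = diversity_summary(gm, pop, hw_significant=int(flags.sum()))
        rows.append({
            "population": pop, "n": summ.n,
            "na": summ.na, "na_se": summ.na_se,
            "ho": summ.ho, "ho_se": summ.ho_se,
            "he": summ.he, "he_se": summ.he_se,
            "fis": summ.fis, "fis_se": summ.fis_se,
            "hw": summ.hw_significant, "pa": summ.private_alleles,
        })
    return pd.DataFrame(rows)
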