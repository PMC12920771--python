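"""Genetic-algorithm optimization of per-class conductance weights.

The optimizer searches weight vectors in [0, 1]^G (one gene per raster
class).  The fitness of a weight vector is the maximum log-likelihood of
the MLPE-GLS regression of pairwise genetic distance on the z-scored
commute distances that the weights induce — i.e. the landscape hypothesis
is scored by how well its resistance pattern explains genetic
differentiation.  Because commute distances are invariant to global weight
rescaling, only weight ratios are identified; reported weights are
normalized so the largest equals 1.

Operators: tournament selection (size 3), BLX-alpha blend crossover,
per-gene Gaussian mutation clipped to [0, 1], and elitism (which makes the
best-so-far fitness trace monotone).  A cache keyed by weights rounded to
3 decimals avoids recomputing commute matrices for near-identical vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .differentiation import PairwiseMatrix
from .genio import ClassRaster
from .landscape import (EPS, DisconnectedError, SiteLocations,
                        build_conductance, commute_matrix, pixel_graph)
from .mlpe import build_pair_design, fit_mlpe

__all__ = ["GAConfig", "OptimizationResult", "fitness", "optimize_weights"]


@dataclass
class GAConfig:
    pop_size: int = 50
    max_generations: int = 100
    patience: int = 20
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    mutation_sd: float = 0.15
    elite_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 10:
            raise ValueError("GA population size must be at least 10")
        for name in ("crossover_prob", "mutation_prob", "elite_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class OptimizationResult:
    weights: dict[int, float]         # normalized: max weight = 1
    fitness: float                    # MLPE log-likelihood at the optimum
    trace: list[float]                # best-so-far fitness per generation
    evaluations: int
    seed: int


def _commute_for_weights(weights: dict[int, float], raster: ClassRaster,
                         sites: SiteLocations) -> PairwiseMatrix:
    surface = build_conductance(raster, weights)
    graph = pixel_graph(surface)
    return commute_matrix(graph, sites)


def fitness(weights: dict[int, float], raster: ClassRaster,
            sites: SiteLocations, gst: PairwiseMatrix) -> float:
    """MLPE log-likelihood of gst ~ commute(weights); -inf if disconnected."""
    try:
        commute = _commute_for_weights(weights, raster, sites)
        design = build_pair_design(gst, {"commute": commute})
        return fit_mlpe(design, ["commute"]).loglik
    except DisconnectedError:
        return float("-inf")
    except ValueError:
        # constant commute predictor (e.g. uniform raster after clamping)
        # cannot be z-scored; score it as the null-model likelihood
        design = build_pair_design(gst, {})
        return fit_mlpe(design, []).loglik


class _Evaluator:
    """Cached fitness evaluation keyed by weights rounded to 3 decimals."""

    def __init__(self, raster: ClassRaster, sites: SiteLocations,
                 gst: PairwiseMatrix, codes: list[int]):
        self.raster = raster
        self.sites = sites
        self.gst = gst
        self.codes = codes
        self.cache: dict[tuple, float] = {}
        self.evaluations = 0

    def __call__(self, genes: np.ndarray) -> float:
        key = tuple(np.round(genes, 3))
        if key in self.cache:
            return self.cache[key]
        weights = {c: float(g) for c, g in zip(self.codes, genes)}
        value = fitness(weights, self.raster, self.sites, self.gst)
        self.cache[key] = value
        self.evaluations += 1
        return value


def optimize_weights(raster: ClassRaster, sites: SiteLocations,
                     gst: PairwiseMatrix,
                     config: GAConfig | None = None) -> OptimizationResult:
    """Optimize class conductance weights by a real-coded GA.

    Degenerate single-class rasters return normalized uniform weights with
    a warning (nothing to optimize: commute distances are then invariant to
    the single weight).  Raises if every evaluated configuration leaves the
    sites disconnected.
    """
    config = config or GAConfig()
    codes = [int(c) for c in raster.classes()]
    if len(codes) < 2:
        warnings.warn("raster has a single class; optimization is degenerate, "
                      "returning uniform weights", stacklevel=2)
        ev = _Evaluator(raster, sites, gst, codes)
        value = ev(np.ones(len(codes)))
        return OptimizationResult(weights={c: 1.0 for c in codes},
                                  fitness=value, trace=[value],
                                  evaluations=ev.evaluations, seed=config.seed)

    rng = np.random.default_rng(config.seed)
    n_genes = len(codes)
    ev = _Evaluator(raster, sites, gst, codes)
    pop = rng.uniform(0.0, 1.0, size=(config.pop_size, n_genes))
    fit = np.array([ev(ind) for ind in pop])
    if not np.isfinite(fit).any():
        raise DisconnectedError(
            "every evaluated weight configuration left the sites "
            "disconnected; check the raster or raise the conductance floor"
        )

    n_elite = max(1, int(round(config.elite_frac * config.pop_size)))
    best_idx = int(np.argmax(fit))
    best_genes, best_fit = pop[best_idx].copy(), float(fit[best_idx])
    trace = [best_fit]
    stagnant = 0

    def tournament() -> np.ndarray:
        idx = rng.integers(0, config.pop_size, size=3)
        return pop[idx[np.argmax(fit[idx])]]

    for _ in range(config.max_generations):
        elite_order = np.argsort(fit)[::-1][:n_elite]
        children = [pop[i].copy() for i in elite_order]
        while len(children) < config.pop_size:
            p1, p2 = tournament().copy(), tournament().copy()
            if rng.random() < config.crossover_prob:  # BLX-0.5 blend
                lo = np.minimum(p1, p2)
                hi = np.maximum(p1, p2)
                span = hi - lo
                c1 = rng.uniform(lo - 0.5 * span, hi + 0.5 * span)
                c2 = rng.uniform(lo - 0.5 * span, hi + 0.5 * span)
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                mutate = rng.random(n_genes) < config.mutation_prob
                child[mutate] += rng.normal(0.0, config.mutation_sd,
                                            size=int(mutate.sum()))
                children.append(np.clip(child, 0.0, 1.0))
        pop = np.array(children[:config.pop_size])
        fit = np.array([ev(ind) for ind in pop])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit + 1e-9:
            best_fit = float(fit[gen_best])
            best_genes = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
        trace.append(best_fit)
        if stagnant >= config.patience:
            break

    top = best_genes.max()
    normalized = best_genes / top if top > 0 else np.ones(n_genes)
    normalized = np.clip(normalized, EPS, 1.0)
    return OptimizationResult(
        weights={c: float(w) for c, w in zip(codes, normalized)},
        fitness=best_fit, trace=trace, evaluations=ev.evaluations,
        seed=config.seed,
    )
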