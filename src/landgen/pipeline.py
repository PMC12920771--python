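"""Pipeline orchestration: config, stages, report tables and run logs.

``run_pipeline`` chains the stages: read genotypes/sites -> diversity and
HWE/LD tests -> pairwise G'ST / Jost D and Mantel IBD -> per-hypothesis GA
optimization of conductance weights -> candidate model set (with the
collinearity screen) -> MLPE fits and the AICc model-selection table.
Every stochastic stage derives its seed from the run seed; outputs carry
the seed in the JSON manifest so runs are reproducible byte for byte.
"""

from __future__ import annotations

import itertools
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differentiation as diff
from . import genio, popgen_stats
from .gaopt import GAConfig, optimize_weights
from .genio import write_float_raster
from .landscape import build_conductance, snap_sites
from .mlpe import build_pair_design, collinearity_screen, fit_mlpe, model_table

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "candidate_model_set"]


class PipelineError(Exception):
    """A stage failed; partial outputs are retained in the output directory."""


@dataclass
class RunConfig:
    genotypes: str
    sites: str
    outdir: str
    format: str = "genepop"
    area: str | None = None
    rasters: dict[str, str] = field(default_factory=dict)
    exclude_loci: list[str] = field(default_factory=list)
    include_localities: bool = False
    pop_min_n: int = 10
    collinearity_threshold: float = 0.7
    supported_delta: float = 2.0
    hwe_reps: int = 10_000
    ld_perms: int = 10_000
    mantel_perms: int = 10_000
    run_ld: bool = False
    triples: list[list[str]] = field(default_factory=list)
    ga: GAConfig = field(default_factory=GAConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        ga = GAConfig(**raw.pop("ga", {}))
        cfg = cls(ga=ga, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for label, p in [("genotypes", self.genotypes), ("sites", self.sites)]:
            if not Path(p).exists():
                raise PipelineError(f"{label} path does not exist: {p}")
        for name, p in self.rasters.items():
            if not Path(p).exists():
                raise PipelineError(f"raster {name!r} path does not exist: {p}")


def candidate_model_set(hypotheses: list[str],
                        dropped_pairs: dict[tuple[str, str], float],
                        triples: list[tuple[str, ...]] | None = None,
                        ) -> list[tuple[str, ...]]:
    """Null + single-predictor + screened two-predictor (+ configured
    three-predictor) model formulas.

    *hypotheses* lists all predictor names (IBD plus the IBR surfaces);
    *dropped_pairs* comes from the collinearity screen.
    """
    def clashes(formula: tuple[str, ...]) -> bool:
        return any((a, b) in dropped_pairs or (b, a) in dropped_pairs
                   for a, b in itertools.combinations(formula, 2))

    models: list[tuple[str, ...]] = [()]
    models.extend((h,) for h in hypotheses)
    models.extend(f for f in itertools.combinations(hypotheses, 2)
                  if not clashes(f))
    for t in triples or []:
        t = tuple(t)
        if not clashes(t) and t not in models:
            models.append(t)
    return models


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle to ``config.outdir``.

    Returns a manifest dict (also written as ``manifest.json``).  On stage
    failure a :class:`PipelineError` is raised after logging; outputs of
    completed stages remain on disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.jsonl"
    manifest: dict = {"seed": config.seed, "stages": []}

    def log(stage: str, t0: float, **extra) -> None:
        rec = {"stage": stage, "seconds": round(time.time() - t0, 3),
               "seed": config.seed, **extra}
        manifest["stages"].append(rec)
        with open(log_path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")

    stage = "load"
    try:
        t0 = time.time()
        gm = genio.read_genotypes(config.genotypes, format=config.format,
                                  exclude_loci=config.exclude_loci)
        sites_df = genio.read_sites(config.sites, pop_min_n=config.pop_min_n)
        if config.area is not None:
            sites_df = sites_df[sites_df["area"] == config.area]
        pops = sites_df.loc[sites_df["role"] == "population", "site"].tolist()
        pops = [p for p in pops if p in gm.pop_labels]
        # sites entering the pairwise/Mantel analyses: populations only by
        # default, every genotyped site when include_localities is set
        if config.include_localities:
            analysis_sites = [s for s in sites_df["site"] if s in gm.pop_labels]
        else:
            analysis_sites = pops
        gm_pops = gm.subset_populations(analysis_sites)
        gm_pops.coords.update(genio.site_coords(sites_df, role=None))
        log(stage, t0, individuals=gm.n_individuals, loci=gm.n_loci,
            populations=len(pops), analysis_sites=len(analysis_sites))

        stage = "diversity"
        t0 = time.time()
        div = popgen_stats.diversity_table(gm.subset_populations(pops),
                                           nreps=config.hwe_reps,
                                           seed=config.seed)
        div.to_csv(outdir / "diversity.csv", index=False)
        log(stage, t0, rows=len(div))

        if config.run_ld:
            stage = "linkage"
            t0 = time.time()
            ld_rows = []
            for pi, pop in enumerate(pops):
                for la, lb in itertools.combinations(gm_pops.loci, 2):
                    res = popgen_stats.ld_test(
                        gm_pops, pop, la, lb, nperm=config.ld_perms,
                        seed=config.seed + 7919 * pi)
                    ld_rows.append({"population": pop, "pair": res.locus,
                                    "g": res.statistic, "p": res.p_value,
                                    "testable": res.testable})
            pd.DataFrame(ld_rows).to_csv(outdir / "linkage.csv", index=False)
            log(stage, t0, tests=len(ld_rows))

        stage = "differentiation"
        t0 = time.time()
        gst, jost = diff.differentiation_matrices(gm_pops, analysis_sites)
        gst.to_csv(outdir / "gst.csv")
        jost.to_csv(outdir / "jost_d.csv")
        coords = genio.site_coords(sites_df, role=None)
        geo = diff.geo_distance_matrix(
            {p: coords[p] for p in analysis_sites}, analysis_sites)
        geo.to_csv(outdir / "geographic.csv")
        r_gd, _ = diff.matrix_correlation(gst, jost)
        r_m, p_m = diff.mantel_test(gst, geo, nperm=config.mantel_perms,
                                    seed=config.seed)
        pd.DataFrame([{"area": config.area, "mantel_r": r_m, "mantel_p": p_m,
                       "gst_jost_r": r_gd, "nperm": config.mantel_perms,
                       "seed": config.seed}]
                     ).to_csv(outdir / "mantel.csv", index=False)
        log(stage, t0, mantel_r=r_m, mantel_p=p_m, gst_jost_r=r_gd)

        stage = "optimize"
        t0 = time.time()
        predictors = {"IBD": geo}
        for name, rpath in config.rasters.items():
            raster = genio.read_class_raster(rpath)
            site_locs = snap_sites(raster,
                                   {p: coords[p] for p in analysis_sites})
            ga_cfg = GAConfig(**{**config.ga.__dict__,
                                 "seed": config.seed
                                 + zlib.crc32(name.encode()) % 10_000})
            result = optimize_weights(raster, site_locs, gst, ga_cfg)
            pd.DataFrame(sorted(result.weights.items()),
                         columns=["class", "weight"]
                         ).to_csv(outdir / f"weights_{name}.csv", index=False)
            pd.DataFrame({"generation": range(len(result.trace)),
                          "best_loglik": result.trace}
                         ).to_csv(outdir / f"trace_{name}.csv", index=False)
            surface = build_conductance(raster, result.weights)
            write_float_raster(surface.values, raster,
                               outdir / f"conductance_{name}.asc")
            from .landscape import commute_matrix, pixel_graph
            commute = commute_matrix(pixel_graph(surface), site_locs)
            commute.to_csv(outdir / f"commute_{name}.csv")
            predictors[f"IBR{name}"] = commute
        log(stage, t0, hypotheses=list(config.rasters))

        stage = "select"
        t0 = time.time()
        design = build_pair_design(gst, predictors)
        names = list(predictors)
        _, dropped = collinearity_screen(
            design, [], threshold=config.collinearity_threshold)
        formulas = candidate_model_set(
            names, dropped, [tuple(t) for t in config.triples])
        fits = [fit_mlpe(design, list(f)) for f in formulas]
        table = model_table(fits, supported_delta=config.supported_delta)
        table.to_csv(outdir / "model_selection.csv", index=False)
        coef_rows = []
        for f in fits:
            for term, b, se, p in zip(["(Intercept)"] + f.terms, f.beta,
                                      f.beta_se, f.beta_p):
                coef_rows.append({"model": f.name, "term": term,
                                  "estimate": b, "se": se, "p": p,
                                  "rho": f.rho, "sigma2": f.sigma2})
        pd.DataFrame(coef_rows).to_csv(outdir / "coefficients.csv", index=False)
        pd.DataFrame([{"a": a, "b": b, "r": r} for (a, b), r in dropped.items()]
                     ).to_csv(outdir / "collinearity_dropped.csv", index=False)
        log(stage, t0, models=len(fits), best=table.iloc[0]["model"])

        manifest["best_model"] = str(table.iloc[0]["model"])
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except PipelineError:
        raise
    except Exception as exc:  # record the failing stage, keep partials
        rec = {"stage": stage, "error": str(exc)}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
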