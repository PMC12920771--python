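# landgen

Landscape genetics for codominant markers: from diploid microsatellite
genotypes and categorical landscape rasters to optimized conductance
surfaces, MLPE-GLS resistance models and AICc model selection.

`landgen` is aimed at population and conservation geneticists asking which
landscape features (rivers, roads, land cover, ridge lines, slope) act as
barriers or corridors for gene flow among sampled populations. Each
landscape hypothesis is a categorical raster; the package searches for
per-class conductance weights whose induced movement-cost pattern best
explains the observed genetic differentiation.

## What it computes

**Diversity and differentiation.** Per-population Na, Ho, unbiased
He = (2n/(2n−1))(1 − Σp²), F_IS = 1 − Ho/He, private alleles, exact-
conditional Monte-Carlo Hardy–Weinberg tests and genotypic linkage
permutation tests with sequential Bonferroni (Holm) correction. Pairwise
differentiation uses Nei–Chesser estimators of H_S and H_T (harmonic-mean
sample size, k = 2 per pair), from which

- Hedrick's G′_ST = G_ST (k − 1 + H_S) / ((k − 1)(1 − H_S)),
- Jost's D = (k/(k−1)) (H_T − H_S) / (1 − H_S),

plus Euclidean distance matrices and one-sided Mantel tests for isolation
by distance.

**Resistance surfaces.** A class raster plus weights w_c ∈ [0, 1] gives a
per-cell conductance surface (floor ε = 10⁻⁶). The surface induces an
8-neighbour pixel graph with edge conductance mean(c_i, c_j)/d_ij
(d = √2 on diagonals); between-site distances are commute times
C(i, j) = 2 W R_eff(i, j), with R_eff the effective resistance from the
graph Laplacian. C is invariant to global weight rescaling, so only
weight *ratios* are identified and reported weights are normalized to
max = 1.

**Model fitting and selection.** Pairwise responses are regressed on
z-scored distance predictors by maximum-likelihood GLS with the MLPE
correlation structure C = (1 − 2ρ)I + ρZZᵀ, which accounts for the
non-independence of pairs sharing a population. Candidate models (null,
single- and screened multi-predictor; predictors with |r| > 0.7 are never
combined) are ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with Akaike
weights; ΔAICc < 2 flags supported models.

**Optimization.** Class weights are fitted by a real-coded genetic
algorithm (tournament selection, blend crossover, Gaussian mutation,
elitism) whose fitness is the MLPE log-likelihood of
G′_ST ~ commute distance.

**Synthetic data.** A first-class generator produces patchy class rasters,
site layouts, MLPE-correlated pairwise responses and F-model genotypes
(population allele frequencies Dirichlet-distributed around ancestral
frequencies), so every stage is testable end to end with known truth.

## Worked example

```python
from landgen import (SyntheticScenario, differentiation_matrices, GAConfig,
                     optimize_weights, build_conductance, pixel_graph,
                     commute_matrix, geo_distance_matrix, build_pair_design,
                     fit_mlpe, model_table, mantel_test)

scenario = SyntheticScenario(seed=42, shape=(40, 40), npops=10,
                             nclasses=2, true_weights={1: 1.0, 2: 0.1})
data = scenario.generate()         # raster, sites, genotypes, truth

gst, jost = differentiation_matrices(data.genotypes)
print(f"mean pairwise G'ST: {gst.mean_offdiag():.3f}")

geo = geo_distance_matrix(data.sites.coords, gst.labels)
r, p = mantel_test(gst, geo, nperm=999, seed=0)
print(f"Mantel IBD: r = {r:.3f}, p = {p:.3f}")

result = optimize_weights(data.raster, data.sites, gst,
                          GAConfig(pop_size=20, max_generations=15, seed=0))
print("optimized weights:", {k: round(v, 2) for k, v in result.weights.items()})

commute = commute_matrix(
    pixel_graph(build_conductance(data.raster, result.weights)), data.sites)
design = build_pair_design(gst, {"IBD": geo, "IBR": commute})
fits = [fit_mlpe(design, t) for t in ([], ["IBD"], ["IBR"], ["IBD", "IBR"])]
print(model_table(fits).round(3).to_string(index=False))
```

Output:

```
mean pairwise G'ST: 0.214
Mantel IBD: r = 0.155, p = 0.196
optimized weights: {1: 1.0, 2: 0.0}
    model  df  logLik     AICc  dAICc  weight  supported
      IBR   4  75.832 -142.664  0.000   0.716       True
IBD + IBR   5  76.164 -140.789  1.875   0.280       True
     Null   3  69.055 -131.524 11.140   0.003      False
      IBD   4  69.085 -129.169 13.494   0.001      False
```

The genotypes were simulated with class 2 as a strong barrier (true
relative weight 0.1). The optimizer drives the class-2 weight to the floor
(printed 0.0 after rounding), the resistance model (IBR) carries 72% of
the Akaike weight and decisively beats the intercept-only null, while
plain geographic distance (IBD) explains nothing extra — exactly the
structure that was simulated. Field data run through the same stages with
the `landgen` CLI (`simulate`, `diversity`, `differentiation`, `optimize`,
`select`, `report`, `run --config config.yaml`).

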