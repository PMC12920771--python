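# Methods

This note documents the statistical models, estimators and numerical
choices implemented in `landgen`, the defaults and why they were chosen,
and what the synthetic-data generator does and does not emulate.

## Data model

Genotypes are diploid, codominant calls (microsatellite-style integer
allele codes) for individuals grouped into populations with projected
site coordinates (metres). A call with one missing allele is treated as
fully missing: the diploid call is the observational unit. Sites with
more than `pop_min_n` (default 10) genotyped individuals are "populations"
and enter pairwise analyses; smaller "localities" are retained for
completeness and can be switched into the pairwise/Mantel stage with
`include_localities`. Coordinates that fall inside lat/lon bounds are
rejected rather than silently treated as planar; the package requires a
single projected CRS and never reprojects.

## Diversity and testing

Per population and locus: Na (distinct alleles), Ho (fraction of
heterozygous calls) and He with the small-sample correction
(2n/(2n−1))(1 − Σp²). F_IS = 1 − Ho/He is averaged over polymorphic loci
only; monomorphic loci contribute Na = 1, Ho = He = 0 and no F_IS term.
Across-locus means carry across-locus standard errors (sd/√L); with a
single locus the SE is reported as unavailable. Private alleles are
counted against every other population in the supplied matrix, so the
caller scopes them (e.g. per study area) by subsetting.

The Hardy–Weinberg test conditions on observed allele counts: each
Monte-Carlo replicate re-pairs the pooled 2n alleles at random, and the
ordering statistic is the Levene conditional probability of the genotype
table — chosen over a chi-square ordering for multi-allelic robustness
with sparse genotype tables. The linkage test permutes one locus's
genotypes across individuals and scores the two-locus genotype table with
a G-statistic. Both use the add-one rule p = (1 + k)/(N + 1), so p is
never zero and the permutation floor is explicit. Multiple testing uses
Holm's step-down procedure (compare p_(i) with α/(m − i + 1), stop at the
first failure), whose rejections always contain the plain Bonferroni set.

Default replicate counts follow common practice for these tests (10,000);
they are configuration fields, and the bundled tests and acceptance runs
use smaller counts suited to their problem sizes.

## Pairwise differentiation

For each population pair (k = 2) and locus, H_S and H_T use the
Nei–Chesser small-sample estimators with harmonic-mean sample size ñ:

    H_S = ñ/(ñ−1) · (1 − mean_pop Σp² − H̄o/(2ñ))
    H_T = 1 − Σp̄² + H_S/(kñ) − H̄o/(2kñ)

Multi-locus values aggregate the across-locus *means* of H_S and H_T
rather than averaging per-locus ratios, which keeps low-information loci
from dominating. Hedrick's G′_ST and Jost's D follow from the aggregated
H_S and H_T. Negative estimates are reported as computed, not truncated.

Two estimator facts worth knowing (both verified in the test suite):

- the standardization inflates the magnitude of G_ST, so "G′_ST ≥ G_ST"
  holds only for non-negative estimates;
- the H_T correction assumes independent population samples. Feeding the
  same sample twice ("identical pools") leaves a systematic deficit of
  order −(1 − Σp²)/(4n) that the standardization amplifies; near-zero
  differentiation is recovered for independent samples from one pool.

Mantel tests correlate upper triangles under simultaneous row/column
permutation, one-sided (greater), since isolation by distance predicts a
positive correlation; 10,000 permutations by default, full enumeration
below 4 populations.

## Conductance, pixel graphs and commute distance

Class weights live in [0, 1]; values below ε = 10⁻⁶ are clamped so a
"zero" weight models a near-impermeable barrier without disconnecting the
graph. Edges join 8-neighbours with conductance mean(c_i, c_j)/d, where
d = 1 (rook) or √2 (diagonal) in cell units — the arithmetic mean with a
diagonal distance correction, matching common transition-surface
practice. The commute distance is the expected round-trip time
C = 2·W·R_eff (W = total edge conductance); a flag exposes raw effective
resistance instead.

R_eff is computed from the graph Laplacian two ways: a sparse LU on the
grounded Laplacian (default, scales to large grids) and a dense
pseudoinverse (small graphs and cross-checks). The dense path truncates
the Laplacian's null mode explicitly (hermitian SVD, rcond 10⁻⁸), because
the numerical null singular value of a graph Laplacian can sit well above
machine epsilon. Both paths agree to 10⁻⁸ on small graphs.

Because C is exactly invariant to scaling all weights by s (W scales by
s, R_eff by 1/s), only weight ratios are identified. All recovery claims
are therefore about rank order or ratios, and optimized weights are
normalized so the maximum is 1.

Sites snap to their containing cell, nudging to the nearest valid cell
within a 3-cell radius when they fall on nodata; sites sharing a cell get
a warning and a zero commute distance. Rasters are consumed at native
resolution as ESRI ASCII grids (integer class codes, nodata mask).

## MLPE-GLS and model selection

With y the upper triangle of the G′_ST matrix and Z the pair×population
incidence, the error correlation is C = (1 − 2ρ)I + ρZZᵀ, ρ ∈ [0, 0.5):
unit diagonal, ρ for pairs sharing one population, positive definite on
the whole range. Fits are full maximum likelihood: β and σ² in closed
form given ρ, ρ by bounded 1-D maximization of the profile likelihood
(the returned optimum is never below the ρ = 0 value, which reduces
exactly to the OLS ML log-likelihood). Coefficient p-values use the
normal approximation; negative pair dependence is not modelled.

Predictors are z-scored before fitting so coefficients are comparable
across hypotheses; log-likelihood and AICc are invariant to this choice.
The parameter count is k = fixed effects + σ² + ρ (3 for the null model,
4 with one predictor, 5 with two), which reproduces the published
df → AICc arithmetic to the printed precision at n = 21 and n = 91 pairs.
Formulas combining predictors with |r| > 0.7 (strict) are discarded
before fitting; model tables report ΔAICc relative to the best model,
Akaike weights, and a supported flag at ΔAICc < 2, with ties broken by
fewer parameters then name. The null (intercept-only) model is always
included.

## Genetic-algorithm optimization

Fitness of a weight vector is the MLPE log-likelihood of
G′_ST ~ z(commute); site disconnection yields −∞ rather than an error so
the GA can traverse near-barrier configurations. Operators: tournament
selection (size 3), BLX-0.5 blend crossover, per-gene Gaussian mutation
(sd 0.15, probability 0.1) clipped to [0, 1], and 10% elitism, which
makes the best-so-far trace monotone. Defaults (population 50, 100
generations, patience 20) finish a 100×100-cell, 15-site problem in
minutes; the bundled experiments use smaller budgets matched to their
grids. A cache keyed on weights rounded to 3 decimals avoids recomputing
commute matrices. The entire run is a deterministic function of inputs
and seed. When several landscape hypotheses are combined in one model,
each surface is optimized independently and the resulting commute
matrices enter the regression jointly.

## Synthetic data

The generator emulates a two-area microsatellite study system:
10–20 populations of ~20 diploids, 11 loci, patchy categorical rasters,
pairwise differentiation averaging ≈ 0.2 in a ≈ 0.05–0.45 band.

- Rasters: Gaussian-blurred white noise cut at equal quantiles → equal
  class shares in contiguous patches (plus a deterministic two-class
  corridor/barrier fixture).
- Responses: y = β₀ + β₁·z(D) + ε with ε ~ N(0, σ²C(ρ)) — exactly the
  regression's assumed model. Defaults β₀ = 0.21, β₁ = 0.06, σ = 0.04,
  ρ = 0.3 place the response in the observed differentiation band with
  moderate pair dependence.
- Genotypes: hierarchical F-model. Ancestral frequencies per locus are
  Dirichlet(1) over K alleles (K = 10 by default, giving ancestral
  E[He] = (K−1)/(K+1) ≈ 0.8 and within-population E[He] = (1−F)·He_anc,
  matching the observed 0.6–0.75 range); population frequencies are
  Dirichlet(p·(1−F_p)/F_p); individuals are drawn in Hardy–Weinberg
  proportions. In full scenarios F_p is an affine map of each
  population's mean commute distance into [0.02, 0.15], calibrated once
  so estimated pairwise G′_ST spans ≈ 0.05–0.45 with mean ≈ 0.2.

What this does *not* emulate: linkage, null alleles and genotyping error,
within-population spatial structure, non-equilibrium demography
(bottlenecks, recent barriers), anisotropic movement, and real GIS layer
geometry. Passing recovery tests therefore demonstrates correctness of
the estimators and the optimization chain under the assumed model class,
not robustness to those violations.

## Degenerate inputs and edge cases

Monomorphic loci are untestable for HWE/LD and excluded from F_IS and
pairwise indices; populations sharing no polymorphic locus have undefined
differentiation (flagged, not silently zero). Single-class rasters make
optimization degenerate: uniform weights are returned with a warning.
Disconnected site configurations name the stranded sites. AICc is
undefined (raises) for n ≤ k + 1. Mantel matrices smaller than 4
populations switch to exact enumeration with a warning.

## Known limitations

Pairwise indices use k = 2 per pair rather than a global estimate, so
values are not identical to global multi-population estimators. The GA
offers no convergence guarantee — recovery claims are statistical
(success rates across seeds). F_IS as 1 − Ho/He is one of several
conventions and is documented here precisely because conventions differ
across software. GeoTIFF input is not supported; convert layers to ESRI
ASCII grids.
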