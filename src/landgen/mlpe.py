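"""GLS regression with MLPE correlation and AICc model selection.

Responses are pairwise genetic distances over all P(P-1)/2 unordered
population pairs.  Pairs sharing a population are not independent; the
maximum-likelihood-population-effects (MLPE) structure models this with a
single correlation parameter rho:

    C = (1 - 2 rho) I + rho Z Z',   rho in [0, 0.5)

where Z is the pair x population incidence matrix (two ones per row), so
C has unit diagonal, rho for pairs sharing exactly one population and zero
otherwise.  Fits are by maximum likelihood with rho profiled out by 1-D
bounded optimization; beta and sigma^2 have closed forms given rho.

Model ranking uses AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1) with
k = #fixed effects + 2 (sigma^2 and rho), delta-AICc and Akaike weights;
models with delta < 2 are flagged as supported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .differentiation import PairwiseMatrix

__all__ = [
    "PairDesign",
    "MLPEFit",
    "mlpe_correlation",
    "build_pair_design",
    "fit_mlpe",
    "aicc",
    "model_table",
    "collinearity_screen",
]

RHO_MAX = 0.5 - 1e-6


@dataclass
class PairDesign:
    """Response and z-scored predictors over unordered population pairs."""

    populations: list[str]
    pairs: list[tuple[str, str]]
    y: np.ndarray
    predictors: pd.DataFrame          # z-scored columns
    Z: np.ndarray                     # (n_pairs, P) incidence

    @property
    def n(self) -> int:
        return len(self.pairs)


@dataclass
class MLPEFit:
    terms: list[str]                  # predictor names (without intercept)
    beta: np.ndarray                  # intercept first
    beta_se: np.ndarray
    beta_p: np.ndarray
    sigma2: float
    rho: float
    loglik: float
    n: int

    @property
    def k(self) -> int:
        """Parameter count: fixed effects + sigma^2 + rho."""
        return len(self.beta) + 2

    @property
    def name(self) -> str:
        return " + ".join(self.terms) if self.terms else "Null"


def mlpe_correlation(Z: np.ndarray, rho: float) -> np.ndarray:
    """MLPE correlation matrix C = (1 - 2 rho) I + rho Z Z'."""
    if not 0.0 <= rho < 0.5:
        raise ValueError(f"rho must lie in [0, 0.5), got {rho}")
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    return (1.0 - 2.0 * rho) * np.eye(n) + rho * (Z @ Z.T)


def build_pair_design(gst: PairwiseMatrix,
                      predictors: dict[str, PairwiseMatrix]) -> PairDesign:
    """Assemble the pairwise regression frame from labeled matrices.

    The response is the upper triangle of *gst*; each predictor matrix is
    reordered to the response's label order, vectorized, and z-scored
    (mean 0, sd 1) so coefficients are comparable across hypotheses.
    """
    pops = list(gst.labels)
    pairs = list(itertools.combinations(pops, 2))
    y = gst.upper_triangle()
    cols = {}
    for name, mat in predictors.items():
        if set(mat.labels) != set(pops):
            raise ValueError(f"predictor {name!r} has mismatched labels")
        v = mat.reorder(pops).upper_triangle()
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError(f"predictor {name!r} is constant over pairs")
        cols[name] = (v - v.mean()) / sd
    Z = np.zeros((len(pairs), len(pops)))
    for r, (a, b) in enumerate(pairs):
        Z[r, pops.index(a)] = 1.0
        Z[r, pops.index(b)] = 1.0
    return PairDesign(populations=pops, pairs=pairs, y=y,
                      predictors=pd.DataFrame(cols), Z=Z)


def _profile_loglik(y: np.ndarray, X: np.ndarray, Z: np.ndarray, rho: float):
    """(loglik, beta, sigma2, cov_unscaled) at a fixed rho."""
    n = len(y)
    C = mlpe_correlation(Z, rho)
    cf = cho_factor(C, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Ci_X = cho_solve(cf, X)
    Ci_y = cho_solve(cf, y)
    xtcx = X.T @ Ci_X
    try:
        xtcx_inv = np.linalg.inv(xtcx)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("rank-deficient design") from None
    beta = xtcx_inv @ (X.T @ Ci_y)
    resid = y - X @ beta
    sigma2 = float(resid @ cho_solve(cf, resid)) / n
    ll = -0.5 * n * math.log(2.0 * math.pi * sigma2) - 0.5 * logdet - 0.5 * n
    return ll, beta, sigma2, xtcx_inv


def fit_mlpe(design: PairDesign, terms: list[str] | tuple[str, ...] = ()
             ) -> MLPEFit:
    """ML fit of y ~ intercept + terms with MLPE correlation.

    rho is estimated by bounded maximization of the profile log-likelihood
    on [0, 0.5); the returned log-likelihood is never below the rho = 0
    (ordinary least squares) value.
    """
    terms = list(terms)
    unknown = [t for t in terms if t not in design.predictors.columns]
    if unknown:
        raise ValueError(f"unknown predictors {unknown}")
    X = np.column_stack(
        [np.ones(design.n)] + [design.predictors[t].to_numpy() for t in terms]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X[:, 1:].T) if len(terms) > 1 else None
        raise ValueError(
            f"rank-deficient design for terms {terms}"
            + (f" (|r| matrix:\n{corr})" if corr is not None else "")
        )
    if design.n <= X.shape[1] + 2:
        raise ValueError("too few pairs for the requested model")
    y, Z = design.y, design.Z

    res = minimize_scalar(
        lambda r: -_profile_loglik(y, X, Z, r)[0],
        bounds=(0.0, RHO_MAX), method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [0.0, float(res.x)]
    best_rho = max(candidates, key=lambda r: _profile_loglik(y, X, Z, r)[0])
    ll, beta, sigma2, cov_u = _profile_loglik(y, X, Z, best_rho)
    se = np.sqrt(np.diag(sigma2 * cov_u))
    z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    return MLPEFit(terms=terms, beta=beta, beta_se=se, beta_p=p,
                   sigma2=sigma2, rho=best_rho, loglik=float(ll), n=design.n)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def model_table(fits: list[MLPEFit], supported_delta: float = 2.0
                ) -> pd.DataFrame:
    """AICc ranking with delta-AICc, Akaike weights and support flags."""
    if not fits:
        raise ValueError("model_table needs at least one fit")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits have mixed n: {sorted(ns)}")
    rows = [{
        "model": f.name, "df": f.k, "logLik": f.loglik,
        "AICc": aicc(f.loglik, f.k, f.n),
    } for f in fits]
    df = pd.DataFrame(rows)
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    w = np.exp(-df["dAICc"] / 2.0)
    df["weight"] = w / w.sum()
    df["supported"] = df["dAICc"] < supported_delta
    df = df.sort_values(["AICc", "df", "model"], kind="stable")
    return df.reset_index(drop=True)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights from a vector of AICc values."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def collinearity_screen(design: PairDesign,
                        formulas: list[tuple[str, ...]],
                        threshold: float = 0.7):
    """Drop multi-predictor formulas containing a pair with |r| > threshold.

    Returns (retained formulas, dropped pairs with their r).  The
    comparison is a strict inequality: |r| exactly at the threshold is
    retained.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    names = list(design.predictors.columns)
    dropped_pairs: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(names, 2):
        r = float(np.corrcoef(design.predictors[a], design.predictors[b])[0, 1])
        if abs(r) > threshold:
            dropped_pairs[(a, b)] = r
    retained = []
    for formula in formulas:
        bad = any(
            (a, b) in dropped_pairs or (b, a) in dropped_pairs
            for a, b in itertools.combinations(formula, 2)
        )
        if not bad:
            retained.append(tuple(formula))
    return retained, dropped_pairs
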