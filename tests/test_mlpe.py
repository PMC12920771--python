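import itertools

import numpy as np
import pytest

from landgen.differentiation import PairwiseMatrix, geo_distance_matrix
from landgen.mlpe import (MLPEFit, aicc, akaike_weights, build_pair_design,
                          collinearity_screen, fit_mlpe, mlpe_correlation,
                          model_table, _profile_loglik)
from landgen.synth import simulate_pairwise_response


def _random_pm(rng, labels, kind="generic"):
    v = rng.random((len(labels), len(labels)))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return PairwiseMatrix(list(labels), v, kind)


def _design(rng, npops=8, extra=None):
    labels = [f"p{i}" for i in range(npops)]
    gst = _random_pm(rng, labels, "gst")
    preds = {"D": _random_pm(rng, labels)}
    preds.update(extra or {})
    return build_pair_design(gst, preds)


class TestCorrelationStructure:
    def test_rho_zero_is_identity(self):
        Z = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1]], float)
        np.testing.assert_allclose(mlpe_correlation(Z, 0.0), np.eye(3))

    def test_three_populations_all_offdiagonals_rho(self):
        # 3 pairs: each shares exactly one population with every other
        pops = ["a", "b", "c"]
        pairs = list(itertools.combinations(pops, 2))
        Z = np.zeros((3, 3))
        for r, (x, y) in enumerate(pairs):
            Z[r, pops.index(x)] = Z[r, pops.index(y)] = 1
        C = mlpe_correlation(Z, 0.3)
        np.testing.assert_allclose(np.diag(C), 1.0)
        off = C[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.3)

    def test_positive_definite_near_upper_bound(self):
        pops = [f"p{i}" for i in range(5)]
        pairs = list(itertools.combinations(pops, 2))
        Z = np.zeros((len(pairs), 5))
        for r, (x, y) in enumerate(pairs):
            Z[r, pops.index(x)] = Z[r, pops.index(y)] = 1
        C = mlpe_correlation(Z, 0.49)
        assert np.linalg.eigvalsh(C).min() > 0

    def test_positive_definite_for_any_layout(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @given(st.integers(min_value=3, max_value=8),
               st.floats(min_value=0.0, max_value=0.49))
        @settings(deadline=None, derandomize=True, max_examples=40)
        def check(npops, rho):
            pops = [f"p{i}" for i in range(npops)]
            pairs = list(itertools.combinations(pops, 2))
            Z = np.zeros((len(pairs), npops))
            for r, (x, y) in enumerate(pairs):
                Z[r, pops.index(x)] = Z[r, pops.index(y)] = 1
            assert np.linalg.eigvalsh(mlpe_correlation(Z, rho)).min() > 0

        check()

    def test_rho_out_of_range(self):
        Z = np.ones((3, 3))
        for bad in (-0.01, 0.5, 0.7):
            with pytest.raises(ValueError):
                mlpe_correlation(Z, bad)


class TestFit:
    def test_rho_zero_reduces_to_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        design = _design(rng)
        X = np.column_stack([np.ones(design.n),
                             design.predictors["D"].to_numpy()])
        ll, *_ = _profile_loglik(design.y, X, design.Z, 0.0)
        ols = sm.OLS(design.y, X).fit()
        assert ll == pytest.approx(ols.llf, abs=1e-8)

    def test_profile_matches_grid_search(self):
        rng = np.random.default_rng(1)
        labels = [f"p{i}" for i in range(10)]
        D = _random_pm(rng, labels)
        gst = simulate_pairwise_response(D, 0.2, 0.05, 0.03, 0.35, seed=2)
        design = build_pair_design(gst, {"D": D})
        fit = fit_mlpe(design, ["D"])
        X = np.column_stack([np.ones(design.n),
                             design.predictors["D"].to_numpy()])
        grid = np.linspace(0, 0.5 - 1e-6, 500)
        grid_best = max(_profile_loglik(design.y, X, design.Z, r)[0]
                        for r in grid)
        assert fit.loglik >= grid_best - 1e-9
        assert abs(fit.loglik - grid_best) < 1e-3

    def test_loglik_never_below_independence_fit(self):
        rng = np.random.default_rng(2)
        for k in range(10):
            design = _design(np.random.default_rng(k))
            fit = fit_mlpe(design, ["D"])
            X = np.column_stack([np.ones(design.n),
                                 design.predictors["D"].to_numpy()])
            ll0, *_ = _profile_loglik(design.y, X, design.Z, 0.0)
            assert fit.loglik >= ll0 - 1e-9

    def test_parameter_recovery(self):
        # modest replicate count; the full experiment runs in the
        # acceptance suite
        rng = np.random.default_rng(3)
        coords = {f"p{i}": (500000 + 2e4 * rng.random(),
                            4500000 + 2e4 * rng.random()) for i in range(15)}
        D = geo_distance_matrix(coords)
        rhos, betas = [], []
        for rep in range(50):
            y = simulate_pairwise_response(D, 0.21, -0.05, 0.05, 0.3,
                                           seed=1000 + rep)
            fit = fit_mlpe(build_pair_design(y, {"D": D}), ["D"])
            rhos.append(fit.rho)
            betas.append(fit.beta[1])
        assert np.mean(rhos) == pytest.approx(0.3, abs=0.06)
        assert np.mean(betas) == pytest.approx(-0.05, abs=0.01)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(4)
        labels = [f"p{i}" for i in range(8)]
        D = _random_pm(rng, labels)
        gst = _random_pm(rng, labels, "gst")
        dup = PairwiseMatrix(labels, D.values.copy())
        design = build_pair_design(gst, {"D": D, "Ddup": dup})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_mlpe(design, ["D", "Ddup"])

    def test_intercept_only_invariant_to_predictor_scaling(self):
        rng = np.random.default_rng(5)
        labels = [f"p{i}" for i in range(8)]
        gst = _random_pm(rng, labels, "gst")
        D = _random_pm(rng, labels)
        scaled = PairwiseMatrix(labels, 1000.0 * D.values)
        f1 = fit_mlpe(build_pair_design(gst, {"D": D}), [])
        f2 = fit_mlpe(build_pair_design(gst, {"D": scaled}), [])
        assert f1.beta[0] == pytest.approx(f2.beta[0])
        assert f1.loglik == pytest.approx(f2.loglik)


class TestAICc:
    def test_formula_values(self):
        assert aicc(30.21, 4, 21) == pytest.approx(-49.92, abs=0.01)
        assert aicc(146.18, 4, 91) == pytest.approx(-283.89, abs=0.01)

    def test_correction_vanishes_for_large_n(self):
        aic = -2 * 10.0 + 2 * 4
        assert abs(aicc(10.0, 4, 10 ** 6) - aic) < 1e-3

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(10.0, 4, 5)


class TestModelTable:
    def _fit(self, name_terms, ll, n=21):
        nterms = len(name_terms)
        return MLPEFit(terms=list(name_terms), beta=np.zeros(nterms + 1),
                       beta_se=np.ones(nterms + 1), beta_p=np.ones(nterms + 1),
                       sigma2=1.0, rho=0.0, loglik=ll, n=n)

    def test_single_model(self):
        t = model_table([self._fit(["a"], 10.0)])
        assert t["dAICc"].iloc[0] == 0.0
        assert t["weight"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_weights(self):
        w = akaike_weights([0.0, 2.0, 4.0])
        np.testing.assert_allclose(w, [0.66524, 0.24473, 0.09003], atol=1e-4)

    def test_weights_sum_to_one_and_sorted(self):
        fits = [self._fit(["a"], 10.0), self._fit([], 9.0),
                self._fit(["a", "b"], 11.0)]
        t = model_table(fits)
        assert t["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert t["AICc"].is_monotonic_increasing
        assert t["dAICc"].iloc[0] == 0.0

    def test_mixed_n_rejected(self):
        with pytest.raises(ValueError, match="mixed n"):
            model_table([self._fit(["a"], 10.0, n=21),
                         self._fit(["a"], 10.0, n=91)])


class TestCollinearityScreen:
    def _design_with_corr(self, r_target, npops=10, seed=0):
        """Design whose two predictors have a controlled correlation."""
        rng = np.random.default_rng(seed)
        labels = [f"p{i}" for i in range(npops)]
        gst = _random_pm(rng, labels, "gst")
        npairs = npops * (npops - 1) // 2
        z1 = rng.standard_normal(npairs)
        z2 = rng.standard_normal(npairs)
        z2 -= z2 @ z1 / (z1 @ z1) * z1
        v2 = r_target * z1 / z1.std() + np.sqrt(1 - r_target ** 2) * z2 / z2.std()
        iu = np.triu_indices(npops, k=1)

        def to_pm(vec):
            m = np.zeros((npops, npops))
            m[iu] = vec
            return PairwiseMatrix(labels, m + m.T)

        return build_pair_design(gst, {"A": to_pm(z1), "B": to_pm(v2)})

    def test_duplicate_predictor_dropped(self):
        design = self._design_with_corr(1.0)
        retained, dropped = collinearity_screen(
            design, [("A",), ("B",), ("A", "B")])
        assert ("A", "B") not in retained
        assert ("A",) in retained and ("B",) in retained
        assert ("A", "B") in dropped

    def test_threshold_is_strict_inequality(self):
        design = self._design_with_corr(0.7)
        r = abs(float(np.corrcoef(design.predictors["A"],
                                  design.predictors["B"])[0, 1]))
        retained, _ = collinearity_screen(design, [("A", "B")], threshold=r)
        assert ("A", "B") in retained  # |r| == threshold is kept

    def test_only_offending_combination_dropped(self):
        rng = np.random.default_rng(7)
        labels = [f"p{i}" for i in range(10)]
        gst = _random_pm(rng, labels, "gst")
        base = self._design_with_corr(0.9, seed=7)
        c = _random_pm(rng, labels)
        preds = {"A": _vec_to_pm(base.predictors["A"].to_numpy(), labels),
                 "B": _vec_to_pm(base.predictors["B"].to_numpy(), labels),
                 "C": c}
        design = build_pair_design(gst, preds)
        formulas = [("A", "B"), ("A", "C"), ("B", "C")]
        retained, dropped = collinearity_screen(design, formulas)
        assert ("A", "B") not in retained
        assert ("A", "C") in retained and ("B", "C") in retained


def _vec_to_mat(vec, labels):
    n = len(labels)
    m = np.zeros((n, n))
    m[np.triu_indices(n, k=1)] = vec
    return m + m.T


def _vec_to_pm(vec, labels):
    return PairwiseMatrix(list(labels), _vec_to_mat(np.asarray(vec), labels))
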