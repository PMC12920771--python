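import itertools

import numpy as np
import pytest
from scipy.stats import kstest, spearmanr

from landgen.differentiation import (PairwiseMatrix, differentiation_matrices,
                                     geo_distance_matrix, mantel_test,
                                     matrix_correlation,
                                     pairwise_differentiation)
from landgen.genio import GenotypeMatrix
from landgen.synth import simulate_genotypes


def _two_pop_gm(calls_a, calls_b) -> GenotypeMatrix:
    calls = np.concatenate([calls_a, calls_b])[:, None, :]
    inds = [f"i{k}" for k in range(len(calls))]
    pops = {ind: ("P1" if k < len(calls_a) else "P2")
            for k, ind in enumerate(inds)}
    return GenotypeMatrix(inds, pops, ["L1"], calls)


class TestPairwiseDifferentiation:
    def test_identical_pools_near_zero(self):
        """Two populations drawn from one allele pool are undifferentiated.

        Multi-locus (20 loci) so the near-unbiased per-locus estimates
        average out; the estimator assumes independent samples per
        population.
        """
        rng = np.random.default_rng(0)
        calls = rng.choice([1, 2, 3, 4], size=(2, 50, 20, 2))
        inds = [f"i{k}" for k in range(100)]
        pops = {ind: ("P1" if k < 50 else "P2") for k, ind in enumerate(inds)}
        gm = GenotypeMatrix(inds, pops, [f"L{j}" for j in range(20)],
                            calls.reshape(100, 20, 2))
        gst, d = pairwise_differentiation(gm, "P1", "P2")
        assert abs(gst) < 0.02 and abs(d) < 0.02

    def test_fixed_different_alleles_maximal(self):
        gm = _two_pop_gm(np.tile([1, 1], (100, 1)), np.tile([2, 2], (100, 1)))
        gst, d = pairwise_differentiation(gm, "P1", "P2")
        assert gst == pytest.approx(1.0, abs=0.02)
        assert d == pytest.approx(1.0, abs=0.02)

    def test_spreadsheet_oracle(self, oracle_pair_gm):
        """Hand computation of the full Nei-Chesser -> Hedrick/Jost chain.

        pop1: p=(0.5,0.5), Ho=1, n=10; pop2: p=(0.9,0.1), Ho=0.2, n=10.
        n~=10, Ho_bar=0.6, x_bar=0.66
        H_S = (10/9)(1 - 0.66 - 0.6/20)          = 0.3444444
        H_T = 1 - 0.58 + H_S/20 - 0.6/40         = 0.4222222
        G_ST = 0.0777778/0.4222222               = 0.1842105
        G'ST = G_ST (1 + H_S)/(1 - H_S)          = 0.3777778
        D    = 2*0.0777778/(1 - H_S)             = 0.2372881
        """
        gst, d = pairwise_differentiation(oracle_pair_gm, "P1", "P2")
        hs = (10 / 9) * (1 - 0.66 - 0.6 / 20)
        ht = 1 - 0.58 + hs / 20 - 0.6 / 40
        g = (ht - hs) / ht
        assert gst == pytest.approx(g * (1 + hs) / (1 - hs), abs=1e-12)
        assert d == pytest.approx(2 * (ht - hs) / (1 - hs), abs=1e-12)

    def test_symmetric_in_pop_order(self, oracle_pair_gm):
        assert pairwise_differentiation(oracle_pair_gm, "P1", "P2") == \
            pairwise_differentiation(oracle_pair_gm, "P2", "P1")

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.choice([1, 2, 3], size=(20, 2))
        b = rng.choice([1, 2, 3], size=(20, 2), p=[0.6, 0.3, 0.1])
        remap = np.vectorize({1: 11, 2: 5, 3: 77}.get)
        v1 = pairwise_differentiation(_two_pop_gm(a, b), "P1", "P2")
        v2 = pairwise_differentiation(_two_pop_gm(remap(a), remap(b)),
                                      "P1", "P2")
        assert v1 == pytest.approx(v2)

    def test_hedrick_at_least_gst_biallelic(self):
        # the standardization inflates |G_ST|: >= for non-negative
        # estimates; negative estimates are reported as computed
        rng = np.random.default_rng(4)
        seen_positive = 0
        for _ in range(20):
            p1, p2 = rng.uniform(0.1, 0.9, 2)
            a = rng.choice([1, 2], size=(30, 2), p=[p1, 1 - p1])
            b = rng.choice([1, 2], size=(30, 2), p=[p2, 1 - p2])
            from landgen.differentiation import _indices_from_hs_ht, _locus_hs_ht
            hs, ht = _locus_hs_ht(a, b)
            gst_raw = (ht - hs) / ht
            gst_h, _ = _indices_from_hs_ht(hs, ht)
            if gst_raw >= 0:
                seen_positive += 1
                assert gst_h >= gst_raw - 1e-12
        assert seen_positive >= 10

    def test_no_shared_polymorphic_locus(self):
        gm = _two_pop_gm(np.tile([1, 1], (5, 1)), np.tile([1, 1], (5, 1)))
        with pytest.raises(ValueError, match="polymorphic"):
            pairwise_differentiation(gm, "P1", "P2")


class TestMatrixCorrelation:
    def _mat(self, rng, labels):
        v = rng.random((len(labels), len(labels)))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        return PairwiseMatrix(labels, v)

    def test_self_and_negation(self):
        m = self._mat(np.random.default_rng(0), ["a", "b", "c", "d"])
        assert matrix_correlation(m, m)[0] == pytest.approx(1.0)
        neg = PairwiseMatrix(m.labels, -m.values)
        assert matrix_correlation(m, neg)[0] == pytest.approx(-1.0)

    def test_textbook_pearson_on_six_pairs(self):
        rng = np.random.default_rng(1)
        m1 = self._mat(rng, ["a", "b", "c", "d"])
        m2 = self._mat(rng, ["a", "b", "c", "d"])
        x, y = m1.upper_triangle(), m2.upper_triangle()
        r_direct = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        r, r2 = matrix_correlation(m1, m2)
        assert r == pytest.approx(r_direct)
        assert r2 == pytest.approx(r_direct ** 2)

    def test_label_order_independent(self):
        rng = np.random.default_rng(2)
        m1 = self._mat(rng, ["a", "b", "c", "d"])
        m2 = self._mat(rng, ["a", "b", "c", "d"])
        shuffled = m2.reorder(["c", "a", "d", "b"])
        assert matrix_correlation(m1, m2)[0] == pytest.approx(
            matrix_correlation(m1, shuffled)[0])

    def test_too_few_pairs(self):
        m = self._mat(np.random.default_rng(0), ["a", "b"])
        with pytest.raises(ValueError):
            matrix_correlation(m, m)


class TestGeoDistance:
    def test_three_four_five(self):
        m = geo_distance_matrix({"a": (500000.0, 4500000.0),
                                 "b": (503000.0, 4504000.0)})
        assert m.get("a", "b") == pytest.approx(5000.0)

    def test_identical_points(self):
        m = geo_distance_matrix({"a": (500000.0, 4500000.0),
                                 "b": (500000.0, 4500000.0)})
        assert m.get("a", "b") == 0.0

    def test_missing_coordinate_named(self):
        with pytest.raises(ValueError, match="b"):
            geo_distance_matrix({"a": (500000.0, 4500000.0)}, labels=["a", "b"])


class TestMantel:
    def test_perfect_correlation_at_floor(self):
        rng = np.random.default_rng(0)
        coords = {f"p{i}": (500000.0 + 1e4 * rng.random(),
                            4500000.0 + 1e4 * rng.random()) for i in range(7)}
        geo = geo_distance_matrix(coords)
        gen = PairwiseMatrix(geo.labels, 2.0 * geo.values)
        r, p = mantel_test(gen, geo, nperm=999, seed=1)
        assert r == pytest.approx(1.0)
        assert p <= 2 / 1000

    def test_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        labels = ["a", "b", "c", "d"]

        def sym(v):
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            return v

        m1 = PairwiseMatrix(labels, sym(rng.random((4, 4))))
        m2 = PairwiseMatrix(labels, sym(rng.random((4, 4))))
        r_obs, p = mantel_test(m1, m2, exact=True)
        # independent enumeration of the 24 relabelings
        iu = np.triu_indices(4, k=1)
        x = m1.values[iu]
        count = 0
        perms = list(itertools.permutations(range(4)))
        for pm in perms:
            y = m2.values[np.ix_(pm, pm)][iu]
            if np.corrcoef(x, y)[0, 1] >= r_obs - 1e-12:
                count += 1
        assert p == pytest.approx(count / len(perms))

    def test_small_matrix_warns_and_enumerates(self):
        labels = ["a", "b", "c"]
        v = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
        m = PairwiseMatrix(labels, v)
        with pytest.warns(UserWarning, match="enumerat"):
            mantel_test(m, m)

    def test_null_calibration(self):
        rng = np.random.default_rng(9)
        ps = []
        for k in range(150):
            def sym():
                v = rng.random((7, 7))
                v = (v + v.T) / 2
                np.fill_diagonal(v, 0)
                return v
            m1 = PairwiseMatrix([f"p{i}" for i in range(7)], sym())
            m2 = PairwiseMatrix([f"p{i}" for i in range(7)], sym())
            ps.append(mantel_test(m1, m2, nperm=99, seed=k)[1])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestPairwiseMatrixContainer:
    def test_rejects_asymmetry_and_diagonal(self):
        with pytest.raises(ValueError):
            PairwiseMatrix(["a", "b"], np.array([[0, 1.0], [2.0, 0]]))
        with pytest.raises(ValueError):
            PairwiseMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0]]))

    def test_csv_round_trip(self, tmp_path):
        m = PairwiseMatrix(["a", "b", "c"],
                           np.array([[0, 1.0, 2.0], [1.0, 0, 3.0],
                                     [2.0, 3.0, 0]]), kind="gst")
        path = tmp_path / "m.csv"
        m.to_csv(path)
        back = PairwiseMatrix.from_csv(path, kind="gst")
        assert back.labels == m.labels
        np.testing.assert_allclose(back.values, m.values)
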