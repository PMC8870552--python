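"""External prediction, harmonization, and the paired/rank-sum comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pwasforge import (
    GenotypeMatrix,
    compare_paired,
    evaluate_prediction,
    fst_performance_groups,
    predict_external,
    rank_sum_test,
)
from pwasforge.enet import PredictionModel


def _model(weights, positions, refs=None, alts=None):
    p = len(weights)
    refs = refs or ["A"] * p
    alts = alts or ["G"] * p
    return PredictionModel(
        aptamer="APT", gene="G", population="TRAIN", strategy="baseline",
        weights=pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(p)],
            "chrom": "1", "pos": positions,
            "ref_allele": refs, "eff_allele": alts,
            "weight": weights,
        }),
        cv_rho=0.5, cv_p=1e-4, lambda_=0.1, alpha=0.5, n_samples=100,
    )


def _cohort(dosages, positions, refs=None, alts=None):
    dosages = np.asarray(dosages, dtype=float)
    p = dosages.shape[1]
    refs = refs or ["A"] * p
    alts = alts or ["G"] * p
    return GenotypeMatrix(
        dosages=dosages,
        samples=pd.DataFrame({"sample_id": [f"S{i}" for i in range(len(dosages))],
                              "population": "TEST"}),
        variants=pd.DataFrame({
            "variant_id": [f"x{i}" for i in range(p)],
            "chrom": "1", "pos": positions, "ref": refs, "alt": alts, "r2": 1.0,
        }),
    )


class TestPredictExternal:
    def test_single_weight_linearity(self):
        g = _cohort([[0.0], [1.0], [2.0], [1.0]], [100])
        pred = predict_external(_model([0.7], [100]), g)
        assert np.allclose(pred, 0.7 * g.dosages[:, 0])

    def test_all_monomorphic_yields_no_prediction(self):
        g = _cohort([[2.0], [2.0], [2.0], [2.0]], [100])
        assert predict_external(_model([0.7], [100]), g) is None

    def test_swapped_alleles_flip_weight_sign(self):
        d = np.array([[0.0], [1.0], [2.0], [1.0]])
        g1 = _cohort(d, [100], refs=["A"], alts=["G"])
        g2 = _cohort(2.0 - d, [100], refs=["G"], alts=["A"])
        m = _model([0.7], [100])
        p1 = predict_external(m, g1)
        p2 = predict_external(m, g2)
        # identical up to the constant 2*w offset absorbed by correlation
        assert np.allclose(p1 - p1.mean(), p2 - p2.mean(), atol=1e-12)

    def test_allele_mismatch_dropped(self):
        g = _cohort([[0.0, 1.0], [1.0, 0.0], [2.0, 1.0]], [100, 200],
                    refs=["A", "A"], alts=["G", "C"])
        m = _model([0.5, 0.5], [100, 200])  # second variant alleles A/G vs A/C
        pred = predict_external(m, g)
        assert np.allclose(pred, 0.5 * g.dosages[:, 0])

    def test_invariant_to_variant_order(self):
        d = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0], [1.0, 2.0]])
        g1 = _cohort(d, [100, 200])
        g2 = _cohort(d[:, ::-1], [200, 100])
        m = _model([0.3, -0.4], [100, 200])
        assert np.allclose(predict_external(m, g1), predict_external(m, g2))


class TestEvaluatePrediction:
    def test_rank_formula_example(self):
        rho, _ = evaluate_prediction(np.array([3.0, 1, 2, 5, 4, 6, 7, 8, 9, 10]),
                                     np.arange(1.0, 11))
        d2 = 8  # sum of squared rank differences among first five
        assert rho == pytest.approx(1 - 6 * d2 / (10 * 99), abs=1e-12)

    def test_identity_gives_one(self):
        x = np.arange(10.0)
        rho, p = evaluate_prediction(x, x)
        assert rho == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-12

    def test_constant_prediction_reported_missing(self):
        rho, p = evaluate_prediction(np.ones(10), np.arange(10.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_independent_noise_rarely_correlated(self, rng):
        big = sum(abs(evaluate_prediction(rng.normal(size=1000),
                                          rng.normal(size=1000))[0]) > 0.1
                  for _ in range(40))
        assert big <= 2


def _signed_rank_oracle(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(p, 1.0)


def _rank_sum_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    obs = ranks[: len(x)].sum()
    sums = [sum(ranks[list(idx)])
            for idx in itertools.combinations(range(len(pooled)), len(x))]
    sums = np.array(sums)
    p = 2 * min((sums <= obs).mean(), (sums >= obs).mean())
    return min(p, 1.0)


class TestComparePaired:
    def test_exact_small_sample_example(self):
        # differences [1, 2, 3]: all-positive is 1 of 8 sign patterns
        p = compare_paired(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert p == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("n", range(4, 11))
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(size=n)
        while np.unique(np.abs(d)).size < n:  # tie-free magnitudes
            d = rng.normal(size=n)
        p = compare_paired(d, np.zeros(n))
        assert p == pytest.approx(_signed_rank_oracle(d), abs=1e-12)

    def test_identical_vectors_error(self):
        with pytest.raises(ValueError):
            compare_paired(np.ones(5), np.ones(5))

    def test_detects_systematic_shift(self, rng):
        hits = 0
        for _ in range(10):
            base = rng.normal(0, 0.1, size=100)
            p = compare_paired(base + 0.05 + 0.02 * rng.normal(size=100), base)
            hits += p < 0.05
        assert hits >= 8


class TestRankSum:
    def test_exact_small_group_example(self):
        assert rank_sum_test([1.0, 2.0], [3.0, 4.0]) == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (5, 5), (4, 6)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x, y = rng.normal(size=n1), rng.normal(size=n2)
        assert rank_sum_test(x, y) == pytest.approx(_rank_sum_oracle(x, y), abs=1e-12)


class TestFstPerformanceGroups:
    def _perf(self, rho_a, rho_b, fst_a, fst_b):
        rows = []
        for i, (ra, fa) in enumerate(zip(rho_a, fst_a)):
            rows.append({"aptamer": f"A{i}", "train_population": "P1",
                         "strategy": "baseline", "test_cohort": "ext",
                         "rho": ra, "p": 0.01, "n": 100, "mean_fst": fa})
        for i, (rb, fb) in enumerate(zip(rho_b, fst_b)):
            rows.append({"aptamer": f"A{i}", "train_population": "P2",
                         "strategy": "baseline", "test_cohort": "ext",
                         "rho": rb, "p": 0.01, "n": 100, "mean_fst": fb})
        return pd.DataFrame(rows)

    def test_groups_and_pvalue_computed(self, rng):
        # large-delta proteins have a big F_ST gap between their two models
        n = 30
        delta = np.concatenate([np.full(15, 0.3), np.full(15, 0.01)])
        fst_a = np.concatenate([rng.uniform(0.2, 0.3, 15), rng.uniform(0.08, 0.12, 15)])
        fst_b = np.concatenate([rng.uniform(0.0, 0.03, 15), rng.uniform(0.08, 0.12, 15)])
        perf = self._perf(0.5 + delta, np.full(n, 0.5), fst_a, fst_b)
        out = fst_performance_groups(perf, thresholds=(0.1,))
        assert out.loc[0, "n_large"] == 15
        assert out.loc[0, "mean_fst_large"] > out.loc[0, "mean_fst_small"]
        assert out.loc[0, "p"] < 0.01

    def test_identical_fst_not_significant(self):
        n = 20
        delta = np.linspace(0, 0.4, n)
        perf = self._perf(0.5 + delta, np.full(n, 0.5),
                          np.full(n, 0.1), np.full(n, 0.1))
        out = fst_performance_groups(perf, thresholds=(0.2,))
        assert out.loc[0, "p"] > 0.9

    def test_empty_group_skipped(self):
        perf = self._perf([0.5, 0.5], [0.5, 0.5], [0.1, 0.1], [0.1, 0.1])
        out = fst_performance_groups(perf, thresholds=(0.5,))
        assert out.empty
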