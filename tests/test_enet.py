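"""Penalty-factor elastic net: solver correctness, CV, PAV adjustment, IO."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pwasforge import (
    CovarianceBundle,
    classify_pav_impact,
    elastic_net_pf,
    nested_cv_evaluate,
    pav_adjust,
    train_final_model,
)
from pwasforge.enet import (
    PredictionModel,
    _kkt_violation,
    _standardize_design,
    read_covariances,
    read_model_db,
    spearman_test,
    write_covariances,
    write_model_db,
)


def _variants_frame(p):
    return pd.DataFrame({
        "variant_id": [f"1:{1000 + i}:A:G" for i in range(p)],
        "chrom": "1", "pos": np.arange(1000, 1000 + p),
        "ref": "A", "alt": "G",
    })


class TestSolver:
    def test_univariate_closed_form_soft_threshold(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.5, 0.5, -0.5, -1.5])  # x.y/n = 0.5
        w, _ = elastic_net_pf(x.reshape(-1, 1), y, np.array([1.0]),
                              alpha=0.5, lambda_=0.2)
        # S(0.5, 0.1) / (1 + 0.1) = 0.4 / 1.1
        assert w[0] == pytest.approx(0.4 / 1.1, abs=1e-9)

    def test_zero_penalty_factor_gives_ols(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.5, 0.5, -0.5, -1.5])
        w, _ = elastic_net_pf(x.reshape(-1, 1), y, np.array([0.0]),
                              alpha=0.5, lambda_=0.2)
        assert w[0] == pytest.approx(0.5, abs=1e-9)

    def test_lambda_zero_recovers_least_squares(self, rng):
        X = rng.normal(size=(60, 4))
        y = X @ [1.0, -0.5, 0.0, 0.2] + 0.1 * rng.normal(size=60)
        w, b0 = elastic_net_pf(X, y, np.ones(4), alpha=0.5, lambda_=0.0)
        ols = np.linalg.lstsq(np.column_stack([np.ones(60), X]), y, rcond=None)[0]
        assert np.allclose(w, ols[1:], atol=1e-6)
        assert b0 == pytest.approx(ols[0], abs=1e-6)

    @pytest.mark.parametrize("lam", [0.01, 0.1, 0.5])
    def test_kkt_conditions_hold_after_fit(self, rng, lam):
        n, p = 150, 10
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        y = X @ rng.normal(size=p) * 0.3 + rng.normal(size=n)
        pf = rng.uniform(0.2, 1.0, size=p)
        w, _ = elastic_net_pf(X, y, pf, alpha=0.5, lambda_=lam)
        Xs, _, sd = _standardize_design(X)
        C = Xs.T @ Xs / n
        c = Xs.T @ (y - y.mean()) / n
        assert _kkt_violation(C, c, w * sd, pf, 0.5, lam) < 1e-4

    def test_univariate_path_monotone_in_lambda(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = 0.8 * x + np.array([0.1, -0.1, 0.05, 0.0, -0.05, 0.0])
        lams = np.geomspace(2.0, 0.001, 30)
        betas = [abs(elastic_net_pf(x.reshape(-1, 1), y, np.ones(1), 0.5, l)[0][0])
                 for l in lams]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(betas, betas[1:]))


class TestNestedCv:
    def test_noise_free_signal_gives_perfect_rho(self, rng):
        n = 100
        X = rng.normal(size=(n, 3))
        y = X[:, 0].copy()
        rho, p = nested_cv_evaluate(X, y, np.ones(3), seed=1)
        assert rho > 0.98
        assert p < 1e-10

    def test_spearman_rank_formula_example(self):
        rho, _ = spearman_test(np.array([3, 1, 2, 5, 4]), np.array([1, 2, 3, 4, 5]))
        assert rho == pytest.approx(1 - 6 * 8 / (5 * 24), abs=1e-12)  # 0.6

    def test_constant_predictions_are_non_significant(self):
        rho, p = spearman_test(np.ones(30), np.arange(30.0))
        assert rho == 0.0 and p == 1.0

    def test_minimum_sample_size(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            nested_cv_evaluate(X, X[:, 0], np.ones(2))

    def test_seeded_folds_reproducible(self, rng):
        X = rng.binomial(2, 0.3, size=(80, 5)).astype(float)
        y = 0.5 * X[:, 1] + rng.normal(size=80)
        r1 = nested_cv_evaluate(X, y, np.ones(5), seed=7)
        r2 = nested_cv_evaluate(X, y, np.ones(5), seed=7)
        assert r1 == r2


class TestTrainFinalModel:
    def test_causal_variant_dominates_weights(self, rng):
        n, p = 500, 8
        X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        y = 1.0 * X[:, 3] + 0.3 * rng.normal(size=n)
        model, cov = train_final_model(X, y, np.ones(p), _variants_frame(p),
                                       aptamer="APT", gene="G")
        assert model is not None
        w = model.weights.set_index("variant_id")["weight"]
        top = w.abs().idxmax()
        assert top == "1:1003:A:G"
        assert cov.shape[0] == len(model.weights)

    def test_hand_computed_covariance(self):
        s1 = np.array([0.0, 1.0, 2.0, 1.0])
        s2 = np.array([0.0, 1.0, 1.0, 2.0])
        cov = np.cov(np.column_stack([s1, s2]), rowvar=False, ddof=1)
        assert cov[0, 1] == pytest.approx(1 / 3)
        assert cov[0, 0] == pytest.approx(2 / 3)
        assert cov[1, 1] == pytest.approx(2 / 3)

    def test_weak_model_suppressed(self, rng):
        n, p = 100, 5
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        y = rng.normal(size=n)  # pure noise -> cv rho ~ 0
        model, cov = train_final_model(X, y, np.ones(p), _variants_frame(p),
                                       aptamer="APT", gene="G")
        assert model is None and cov is None


class TestPavAdjust:
    def test_no_pavs_returns_unchanged(self, rng):
        y = rng.normal(size=20)
        out, k, flag = pav_adjust(y, None)
        assert np.array_equal(out, y) and k == 0 and flag == "unadjusted"

    def test_constant_pav_matrix_treated_as_absent(self, rng):
        y = rng.normal(size=20)
        out, k, flag = pav_adjust(y, np.ones((20, 2)))
        assert flag == "unadjusted" and k == 0

    def test_single_pav_uses_one_pc(self, rng):
        pav = rng.binomial(2, 0.4, size=50).astype(float)
        y = 0.8 * pav + rng.normal(size=50)
        out, k, flag = pav_adjust(y, pav)
        assert k == 1 and flag == "adjusted"
        assert abs(np.corrcoef(out, pav)[0, 1]) < 1e-8

    def test_pc_count_covers_95_percent_variance(self, rng):
        # two independent strong axes -> 2 PCs needed
        a = rng.binomial(2, 0.5, size=100).astype(float)
        b = rng.binomial(2, 0.5, size=100).astype(float)
        P = np.column_stack([a, b])
        _, k, _ = pav_adjust(rng.normal(size=100), P)
        assert k == 2


class TestClassifyPavImpact:
    def _model(self, rho, p=1e-4):
        return PredictionModel("A", "G", "ALL", "baseline",
                               pd.DataFrame({"variant_id": ["v"], "chrom": ["1"],
                                             "pos": [1], "ref_allele": ["A"],
                                             "eff_allele": ["G"], "weight": [1.0]}),
                               cv_rho=rho, cv_p=p, lambda_=0.1, alpha=0.5,
                               n_samples=100)

    def test_no_pav_category(self):
        m = self._model(0.5)
        assert classify_pav_impact(m, m, had_pavs=False) == "unadjusted"

    def test_marginal_reduction(self):
        assert classify_pav_impact(self._model(0.50), self._model(0.45)) == "marginal"

    def test_large_but_retained(self):
        assert classify_pav_impact(self._model(0.50), self._model(0.35)) == "large_retained"

    def test_lost_significance(self):
        assert classify_pav_impact(self._model(0.50), self._model(0.08)) == "lost_significance"
        assert classify_pav_impact(self._model(0.50), None) == "lost_significance"

    def test_requires_significant_before(self):
        with pytest.raises(ValueError):
            classify_pav_impact(self._model(0.05), None)


class TestSerialization:
    def test_model_db_round_trip(self, rng, tmp_path):
        n, p = 200, 6
        X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        y = X[:, 1] + 0.4 * rng.normal(size=n)
        model, cov = train_final_model(X, y, np.ones(p), _variants_frame(p),
                                       aptamer="APT_1", gene="GENE_1",
                                       population="EUR", strategy="baseline")
        path = tmp_path / "models.db"
        write_model_db([model], str(path))
        back = read_model_db(str(path))
        assert len(back) == 1
        m = back[0]
        assert m.aptamer == "APT_1" and m.gene == "GENE_1"
        assert m.cv_rho == pytest.approx(model.cv_rho)
        assert np.allclose(m.weights["weight"], model.weights["weight"])
        assert list(m.weights["pos"]) == list(model.weights["pos"])

    def test_covariance_round_trip(self, tmp_path):
        bundle = CovarianceBundle()
        mat = np.array([[0.5, 0.25], [0.25, 0.5]])
        bundle.add("APT_1", ["v1", "v2"], mat)
        path = tmp_path / "cov.txt.gz"
        write_covariances(bundle, str(path))
        back = read_covariances(str(path))
        assert np.allclose(back.submatrix("APT_1", ["v1", "v2"]), mat, atol=1e-9)
        assert np.allclose(back.submatrix("APT_1", ["v2"]), [[0.5]])

    def test_bundle_validates_shape_and_diagonal(self):
        bundle = CovarianceBundle()
        with pytest.raises(ValueError):
            bundle.add("A", ["v1"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            bundle.add("A", ["v1"], np.array([[0.0]]))
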