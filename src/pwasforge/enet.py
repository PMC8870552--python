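"""Penalty-factor elastic net with nested cross-validation.

The fit minimizes

    (1/2n) ||y - X b||^2 + lambda * sum_j pf_j [ alpha |b_j|
                                                 + (1-alpha)/2 b_j^2 ]

by cyclic coordinate descent on standardized columns; pf_j in [0, 1] is a
per-variant penalty factor (1 - PIP from fine-mapping; pf = 0 exempts the
variant from penalization entirely, so it always enters the model).  The
coordinate update is b_j <- S(rho_j, lambda alpha pf_j) / (1 + lambda
(1-alpha) pf_j) with S the soft-threshold operator and rho_j the partial
residual correlation.

Performance is the Spearman correlation between out-of-fold predictions
and observations from nested cross-validation: 5 outer folds, with lambda
chosen per outer fold by 10-fold inner CV over a 100-point log-spaced
path.  A model is kept only when cross-validated rho > 0.1 and p < 0.05.
"""

from __future__ import annotations

import gzip
import logging
import sqlite3
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

logger = logging.getLogger("pwasforge")

try:  # compiled kernel when numba is available; pure python otherwise
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

RHO_MIN = 0.1
P_MAX = 0.05
MAX_SWEEPS = 100_000
CD_TOL = 1e-7


@dataclass
class PredictionModel:
    """A trained per-aptamer SNP weight set with CV performance."""

    aptamer: str
    gene: str
    population: str
    strategy: str
    weights: pd.DataFrame  # variant_id, chrom, pos, ref_allele, eff_allele, weight
    cv_rho: float
    cv_p: float
    lambda_: float
    alpha: float
    n_samples: int

    @property
    def significant(self) -> bool:
        return self.cv_rho > RHO_MIN and self.cv_p < P_MAX


@dataclass
class CovarianceBundle:
    """Training-sample dosage covariances for each model's variants."""

    entries: dict[str, tuple[list[str], np.ndarray]] = field(default_factory=dict)

    def add(self, key: str, variant_ids: list[str], matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(variant_ids), len(variant_ids)):
            raise ValueError("covariance shape mismatch")
        if np.any(np.diag(matrix) <= 0):
            raise ValueError("covariance diagonal must be positive")
        self.entries[key] = (list(variant_ids), matrix)

    def submatrix(self, key: str, variant_ids: list[str]) -> np.ndarray:
        ids, mat = self.entries[key]
        pos = {v: i for i, v in enumerate(ids)}
        idx = [pos[v] for v in variant_ids]
        return mat[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# Coordinate descent
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cd_solve(C, c, pf, alpha, lam, beta, tol, max_sweeps):  # pragma: no cover
    p = c.shape[0]
    for sweep in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            rho = c[j] - np.dot(C[j], beta) + C[j, j] * beta[j]
            thr = lam * alpha * pf[j]
            if rho > thr:
                bj = (rho - thr) / (C[j, j] + lam * (1.0 - alpha) * pf[j])
            elif rho < -thr:
                bj = (rho + thr) / (C[j, j] + lam * (1.0 - alpha) * pf[j])
            else:
                bj = 0.0
            d = bj - beta[j]
            if d != 0.0:
                beta[j] = bj
                if abs(d) > delta:
                    delta = abs(d)
        if delta < tol:
            return sweep + 1
    return -1


def _solve_path(C, c, pf, alpha, lambdas):
    """Warm-started solutions along a decreasing lambda path (std scale)."""
    p = c.shape[0]
    betas = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        sweeps = _cd_solve(C, c, pf, alpha, lam, beta, CD_TOL, MAX_SWEEPS)
        if sweeps < 0:
            raise RuntimeError(
                f"coordinate descent failed to converge at lambda={lam:.4g} "
                f"(p={p}, alpha={alpha}, max |beta|={np.abs(beta).max():.3g})"
            )
        betas[i] = beta
    return betas


def _lambda_path(c, pf, alpha, n_lambda=100, min_ratio=0.01):
    pen = pf > 0
    if pen.any() and alpha > 0:
        lam_max = np.max(np.abs(c[pen]) / (alpha * pf[pen]))
    else:
        lam_max = np.max(np.abs(c)) if c.size else 1.0
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _standardize_design(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def elastic_net_pf(X: np.ndarray, y: np.ndarray, penalties: np.ndarray,
                   alpha: float = 0.5, lambda_: float = 0.1):
    """Single penalty-factor elastic-net fit; weights on the dosage scale.

    Returns (weights, intercept).  Raises on non-convergence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    pf = np.asarray(penalties, dtype=float)
    if pf.shape[0] != X.shape[1]:
        raise ValueError("one penalty factor per column required")
    Xs, mean, sd = _standardize_design(X)
    yc = y - y.mean()
    n = y.size
    C = Xs.T @ Xs / n
    c = Xs.T @ yc / n
    beta = np.zeros(X.shape[1])
    sweeps = _cd_solve(C, c, pf, alpha, lambda_, beta, CD_TOL, MAX_SWEEPS)
    if sweeps < 0:
        raise RuntimeError(f"no convergence at lambda={lambda_}")
    w = beta / sd
    intercept = y.mean() - float(w @ mean)
    return w, intercept


def _kkt_violation(C, c, beta, pf, alpha, lam):
    """Max violation of the subgradient conditions (standardized scale)."""
    grad = c - C @ beta
    viol = 0.0
    for j in range(beta.size):
        if beta[j] == 0:
            viol = max(viol, abs(grad[j]) - lam * alpha * pf[j])
        else:
            target = lam * alpha * pf[j] * np.sign(beta[j]) + lam * (1 - alpha) * pf[j] * beta[j]
            viol = max(viol, abs(grad[j] - target))
    return viol


def spearman_test(predicted: np.ndarray, observed: np.ndarray):
    """Spearman rho with a two-sided t-approximation p-value (df = n-2)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = predicted.size
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        return 0.0, 1.0
    rho = stats.spearmanr(predicted, observed).statistic
    if not np.isfinite(rho):
        return 0.0, 1.0
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return float(rho), float(p)


def _inner_cv_lambda(X, y, pf, alpha, inner_folds, seed, n_lambda, min_ratio):
    """Pick lambda minimizing inner-CV mean squared error along the path."""
    Xs_all, _, _ = _standardize_design(X)
    c_all = Xs_all.T @ (y - y.mean()) / y.size
    lambdas = _lambda_path(c_all, pf, alpha, n_lambda, min_ratio)
    n = y.size
    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    sse = np.zeros(len(lambdas))
    for tr, te in kf.split(X):
        Xs, mean, sd = _standardize_design(X[tr])
        yc = y[tr] - y[tr].mean()
        C = Xs.T @ Xs / tr.size
        c = Xs.T @ yc / tr.size
        betas = _solve_path(C, c, pf, alpha, lambdas)
        W = betas / sd[None, :]
        preds = (X[te] - mean) @ W.T + y[tr].mean()
        sse += ((preds - y[te][:, None]) ** 2).sum(axis=0)
    return lambdas, lambdas[int(np.argmin(sse))]


def nested_cv_evaluate(X: np.ndarray, y: np.ndarray, penalties: np.ndarray,
                       alpha: float = 0.5, outer_folds: int = 5,
                       inner_folds: int = 10, seed: int = 42, *,
                       n_lambda: int = 100, lambda_min_ratio: float = 0.01):
    """Nested-CV Spearman rho and p for one protein's design.

    Outer folds give out-of-fold predictions; the inner loop chooses the
    MSE-minimizing lambda on a log-spaced path per outer fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    pf = np.asarray(penalties, dtype=float)
    if y.size < 25:
        raise ValueError("need at least 25 samples for nested CV")
    oof = np.empty_like(y)
    kf = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    for f, (tr, te) in enumerate(kf.split(X)):
        _, lam = _inner_cv_lambda(X[tr], y[tr], pf, alpha, inner_folds,
                                  seed + 1 + f, n_lambda, lambda_min_ratio)
        w, b0 = elastic_net_pf(X[tr], y[tr], pf, alpha, lam)
        oof[te] = X[te] @ w + b0
    return spearman_test(oof, y)


def train_final_model(X: np.ndarray, y: np.ndarray, penalties: np.ndarray,
                      variants: pd.DataFrame, *, aptamer: str, gene: str,
                      population: str = "ALL", strategy: str = "baseline",
                      alpha: float = 0.5, seed: int = 42,
                      inner_folds: int = 10, outer_folds: int = 5,
                      n_lambda: int = 100, lambda_min_ratio: float = 0.01,
                      check_kkt: bool = True):
    """Nested-CV evaluation, final all-data fit, and LD covariance.

    Returns (PredictionModel, covariance ndarray over nonzero-weight
    variants) or (None, None) when the model fails the rho > 0.1, p < 0.05
    filter or retains no nonzero weight.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    pf = np.asarray(penalties, dtype=float)
    rho, p = nested_cv_evaluate(X, y, pf, alpha, outer_folds, inner_folds, seed,
                                n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    if not (rho > RHO_MIN and p < P_MAX):
        logger.debug("%s/%s %s: suppressed (rho=%.3f p=%.3g)", aptamer, gene, strategy, rho, p)
        return None, None
    _, lam = _inner_cv_lambda(X, y, pf, alpha, inner_folds, seed, n_lambda,
                              lambda_min_ratio)
    w, b0 = elastic_net_pf(X, y, pf, alpha, lam)
    if check_kkt:
        Xs, _, sd = _standardize_design(X)
        C = Xs.T @ Xs / y.size
        c = Xs.T @ (y - y.mean()) / y.size
        viol = _kkt_violation(C, c, w * sd, pf, alpha, lam)
        if viol > 1e-4:
            raise RuntimeError(f"KKT violation {viol:.2e} for {aptamer}/{gene}")
    nz = np.flatnonzero(w != 0)
    if nz.size == 0:
        logger.info("%s/%s %s: all weights zero at lambda=%.3g", aptamer, gene, strategy, lam)
        return None, None
    weights = pd.DataFrame({
        "variant_id": variants["variant_id"].to_numpy()[nz],
        "chrom": variants["chrom"].to_numpy()[nz],
        "pos": variants["pos"].to_numpy()[nz],
        "ref_allele": variants["ref"].to_numpy()[nz],
        "eff_allele": variants["alt"].to_numpy()[nz],
        "weight": w[nz],
    })
    cov = np.cov(X[:, nz], rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    model = PredictionModel(
        aptamer=aptamer, gene=gene, population=population, strategy=strategy,
        weights=weights, cv_rho=rho, cv_p=p, lambda_=float(lam), alpha=alpha,
        n_samples=y.size,
    )
    return model, cov


# ---------------------------------------------------------------------------
# Protein-altering-variant adjustment
# ---------------------------------------------------------------------------

def pav_adjust(y: np.ndarray, pav_genotypes: np.ndarray | None):
    """Residualize abundance on the PCs of the PAV genotype matrix.

    The number of PCs is the smallest count explaining >= 95% of the PAV
    matrix variance.  Returns (adjusted y, n_pcs_used, flag) with flag
    "unadjusted" when there is no informative PAV.
    """
    y = np.asarray(y, dtype=float)
    if pav_genotypes is None or np.size(pav_genotypes) == 0:
        return y.copy(), 0, "unadjusted"
    P = np.atleast_2d(np.asarray(pav_genotypes, dtype=float))
    if P.shape[0] != y.size:
        P = P.T
    P = P[:, P.std(axis=0) > 0]
    if P.shape[1] == 0:
        return y.copy(), 0, "unadjusted"
    Pc = P - P.mean(axis=0)
    U, s, _ = np.linalg.svd(Pc, full_matrices=False)
    ev = s**2
    frac = np.cumsum(ev) / ev.sum()
    n_pcs = int(np.searchsorted(frac, 0.95 - 1e-12) + 1)
    scores = U[:, :n_pcs] * s[:n_pcs]
    from .phenoprep import residualize
    return residualize(y, scores), n_pcs, "adjusted"


def classify_pav_impact(before: PredictionModel, after: PredictionModel | None,
                        had_pavs: bool = True) -> str:
    """Categorize the effect of PAV adjustment on one model.

    Categories: "unadjusted" (no PAV in the cis window), "marginal"
    (delta rho < 0.1, still significant), "large_retained" (delta rho >=
    0.1, still significant), "lost_significance".
    """
    if not before.significant:
        raise ValueError("classification requires a significant pre-adjustment model")
    if not had_pavs:
        return "unadjusted"
    if after is None or not after.significant:
        return "lost_significance"
    delta = before.cv_rho - after.cv_rho
    return "marginal" if delta < 0.1 else "large_retained"


# ---------------------------------------------------------------------------
# Serialization (PredictDB convention)
# ---------------------------------------------------------------------------

def _var_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}_{pos}_{ref}_{alt}_b38"


def write_model_db(models: list[PredictionModel], path: str) -> None:
    """Single-file relational model bundle: tables ``weights`` and ``extra``."""
    con = sqlite3.connect(path)
    try:
        con.execute("DROP TABLE IF EXISTS weights")
        con.execute("DROP TABLE IF EXISTS extra")
        con.execute(
            "CREATE TABLE weights (gene TEXT, rsid TEXT, varID TEXT, "
            "ref_allele TEXT, eff_allele TEXT, weight REAL)"
        )
        con.execute(
            "CREATE TABLE extra (gene TEXT, genename TEXT, n_snps_in_model INTEGER, "
            "pred_perf_rho REAL, pred_perf_pval REAL, strategy TEXT, population TEXT, "
            "alpha REAL, lambda REAL, n_samples INTEGER)"
        )
        for m in models:
            for w in m.weights.itertuples(index=False):
                con.execute(
                    "INSERT INTO weights VALUES (?,?,?,?,?,?)",
                    (m.aptamer, w.variant_id,
                     _var_id(w.chrom, w.pos, w.ref_allele, w.eff_allele),
                     w.ref_allele, w.eff_allele, float(w.weight)),
                )
            con.execute(
                "INSERT INTO extra VALUES (?,?,?,?,?,?,?,?,?,?)",
                (m.aptamer, m.gene, len(m.weights), m.cv_rho, m.cv_p,
                 m.strategy, m.population, m.alpha, m.lambda_, m.n_samples),
            )
        con.commit()
    finally:
        con.close()


def read_model_db(path: str) -> list[PredictionModel]:
    con = sqlite3.connect(path)
    try:
        weights = pd.read_sql_query("SELECT * FROM weights", con)
        extra = pd.read_sql_query("SELECT * FROM extra", con)
    finally:
        con.close()
    extra = extra.rename(columns={"lambda": "lambda_"})
    models = []
    for row in extra.itertuples(index=False):
        wsub = weights[weights["gene"] == row.gene]
        parts = wsub["varID"].str.split("_", expand=True)
        models.append(PredictionModel(
            aptamer=row.gene, gene=row.genename, population=row.population,
            strategy=row.strategy,
            weights=pd.DataFrame({
                "variant_id": wsub["rsid"].to_numpy(),
                "chrom": parts[0].to_numpy(),
                "pos": parts[1].astype(int).to_numpy(),
                "ref_allele": wsub["ref_allele"].to_numpy(),
                "eff_allele": wsub["eff_allele"].to_numpy(),
                "weight": wsub["weight"].to_numpy(),
            }),
            cv_rho=row.pred_perf_rho, cv_p=row.pred_perf_pval,
            lambda_=row.lambda_, alpha=row.alpha,
            n_samples=row.n_samples,
        ))
    return models


def write_covariances(bundle: CovarianceBundle, path: str) -> None:
    """Gzipped whitespace text: GENE RSID1 RSID2 VALUE (upper triangle)."""
    with gzip.open(path, "wt") as fh:
        fh.write("GENE RSID1 RSID2 VALUE\n")
        for key, (ids, mat) in bundle.entries.items():
            for i in range(len(ids)):
                for j in range(i, len(ids)):
                    fh.write(f"{key} {ids[i]} {ids[j]} {mat[i, j]:.6g}\n")


def read_covariances(path: str) -> CovarianceBundle:
    df = pd.read_csv(path, sep=r"\s+")
    bundle = CovarianceBundle()
    for key, grp in df.groupby("GENE", sort=False):
        ids = list(pd.unique(pd.concat([grp["RSID1"], grp["RSID2"]])))
        pos = {v: i for i, v in enumerate(ids)}
        mat = np.zeros((len(ids), len(ids)))
        for r in grp.itertuples(index=False):
            i, j = pos[r.RSID1], pos[r.RSID2]
            mat[i, j] = mat[j, i] = r.VALUE
        bundle.add(key, ids, mat)
    return bundle
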