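"""Per-locus Bayesian fine-mapping by exhaustive model enumeration.

Each cis locus is fine-mapped by enumerating all variant subsets up to
size K, scoring each subset with a Zellner g-prior Bayes factor against
the intercept-only model, and combining with an independent Bernoulli
inclusion prior pi per variant.  Posterior inclusion probabilities (PIPs)
are the summed normalized posteriors of the models containing each
variant.  Correlated variants are then grouped into LD signal clusters
(greedy seeding by descending PIP, membership at r^2 >= cluster_r2), and
1 - PIP penalty factors are exported for the elastic net.

For a subset S of k standardized columns with coefficient of
determination R^2, the log Bayes factor is

    log BF = ((n-1-k)/2) log(1+g) - ((n-1)/2) log(1 + g (1-R^2)),

with g = n by default (unit-information prior).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger("pwasforge")


@dataclass
class FineMapResult:
    """Fine-mapping output for one aptamer-gene locus."""

    locus: str
    variant_ids: list[str]
    pip: np.ndarray
    cluster_id: np.ndarray          # 1-based cluster label per variant
    cluster_pip: np.ndarray         # summed PIP of the variant's cluster
    prior_pi: float
    K: int
    r2_matrix: np.ndarray           # squared correlation between variants
    top_models: list[tuple[tuple[int, ...], float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus": self.locus, "variant_id": self.variant_ids,
            "pip": self.pip, "cluster_id": self.cluster_id,
            "cluster_pip": self.cluster_pip, "prior": self.prior_pi,
        })


def _standardize(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    M = M - M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    return M / sd


def _dedupe_subset(C: np.ndarray, subset: tuple[int, ...]) -> list[int]:
    """Drop columns perfectly collinear (within the subset) with an earlier one."""
    kept: list[int] = []
    for j in subset:
        if not kept:
            kept.append(j)
            continue
        Ckk = C[np.ix_(kept, kept)]
        ckj = C[kept, j]
        try:
            coef = np.linalg.solve(Ckk, ckj)
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(Ckk, ckj, rcond=None)[0]
        resid_var = C[j, j] - ckj @ coef
        if resid_var < 1e-10:
            logger.debug("dropping collinear column %d from subset %s", j, subset)
            continue
        kept.append(j)
    return kept


def _subset_r2(C: np.ndarray, c: np.ndarray, subset: list[int]) -> float:
    Css = C[np.ix_(subset, subset)]
    cs = c[subset]
    try:
        coef = np.linalg.solve(Css, cs)
    except np.linalg.LinAlgError:
        coef = np.linalg.lstsq(Css, cs, rcond=None)[0]
    return float(np.clip(cs @ coef, 0.0, 1.0 - 1e-12))


def log_bf_from_r2(r2: float, n: int, k: int, g: float) -> float:
    return 0.5 * (n - 1 - k) * math.log1p(g) - 0.5 * (n - 1) * math.log1p(g * (1.0 - r2))


def model_log_bf(y: np.ndarray, X_subset: np.ndarray, g_prior: float | None = None) -> float:
    """Zellner g-prior log Bayes factor of one subset vs the null model.

    Columns are standardized internally; perfectly collinear duplicates are
    dropped (smallest index retained) before computing k and R^2.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X_subset, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, k = X.shape
    if k < 1:
        raise ValueError("subset must contain at least one column")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    g = float(g_prior) if g_prior is not None else float(n)
    Xs = _standardize(X)
    ys = (y - y.mean())
    sd = ys.std()
    ys = ys / (sd if sd > 0 else 1.0)
    C = (Xs.T @ Xs) / n
    c = (Xs.T @ ys) / n
    kept = _dedupe_subset(C, tuple(range(k)))
    r2 = _subset_r2(C, c, kept)
    return log_bf_from_r2(r2, n, len(kept), g)


def _candidate_sets(p: int, K: int, max_models: int, marginal: np.ndarray):
    """All subsets of size <= K, restricted to the strongest marginal
    variants when full enumeration would exceed max_models."""
    def n_models(m: int) -> int:
        return sum(math.comb(m, k) for k in range(1, K + 1))

    if n_models(p) <= max_models:
        active = list(range(p))
    else:
        m = p
        while m > 1 and n_models(m) > max_models:
            m -= 1
        order = np.argsort(-np.abs(marginal))
        active = sorted(order[:m].tolist())
        logger.info("enumeration capped: using top %d of %d variants", m, p)
    for k in range(1, K + 1):
        yield from itertools.combinations(active, k)


def enumerate_posteriors(y: np.ndarray, X_locus: np.ndarray,
                         prior_pi: float | None = None, K: int = 3, *,
                         locus: str = "locus", variant_ids: list[str] | None = None,
                         positions: np.ndarray | None = None,
                         cluster_r2: float = 0.25, g_prior: float | None = None,
                         max_models: int = 200_000, allow_greedy: bool = True,
                         ) -> FineMapResult:
    """Exhaustive Bayesian fine-mapping of one locus.

    posterior(model) is proportional to BF(model) * pi^|model| *
    (1-pi)^(p-|model|) over all models of size <= K plus the null model.
    Default pi = 1/p (one causal variant expected per locus); default
    g = n.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X_locus, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X_locus must be (n_samples, p)")
    n, p = X.shape
    if p == 0:
        raise ValueError("locus has no variants")
    if K < 1:
        raise ValueError("K must be >= 1")
    pi = float(prior_pi) if prior_pi is not None else 1.0 / p
    if not (0 < pi < 1):
        raise ValueError("prior_pi must be in (0, 1)")
    g = float(g_prior) if g_prior is not None else float(n)
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(p)]
    if positions is None:
        positions = np.arange(p)

    Xs = _standardize(X)
    ys = y - y.mean()
    sd = ys.std()
    ys = ys / (sd if sd > 0 else 1.0)
    C = (Xs.T @ Xs) / n
    c = (Xs.T @ ys) / n

    total = sum(math.comb(p, k) for k in range(1, K + 1))
    if total > max_models and not allow_greedy:
        raise ValueError(
            f"{total} models exceed cap {max_models}; reduce the locus or enable greedy"
        )

    log_pi, log_1mpi = math.log(pi), math.log(1.0 - pi)
    subsets: list[tuple[int, ...]] = [()]
    log_post = [p * log_1mpi]  # null model, BF = 1
    for subset in _candidate_sets(p, K, max_models, c):
        kept = _dedupe_subset(C, subset)
        r2 = _subset_r2(C, c, kept)
        lbf = log_bf_from_r2(r2, n, len(kept), g)
        subsets.append(subset)
        log_post.append(lbf + len(subset) * log_pi + (p - len(subset)) * log_1mpi)

    log_post = np.asarray(log_post)
    log_norm = logsumexp(log_post)
    post = np.exp(log_post - log_norm)

    pip = np.zeros(p)
    for subset, w in zip(subsets, post):
        for j in subset:
            pip[j] += w
    pip = np.clip(pip, 0.0, 1.0)

    order = np.argsort(-post)[:50]
    top_models = [(subsets[i], float(log_post[i] - log_norm)) for i in order]

    with np.errstate(invalid="ignore"):
        r2_matrix = C**2 / np.outer(np.diag(C), np.diag(C))
    cluster_id, cluster_pip = _assign_clusters(pip, r2_matrix, positions, cluster_r2)

    return FineMapResult(
        locus=locus, variant_ids=list(variant_ids), pip=pip,
        cluster_id=cluster_id, cluster_pip=cluster_pip, prior_pi=pi, K=K,
        r2_matrix=r2_matrix, top_models=top_models,
    )


def _assign_clusters(pip: np.ndarray, r2: np.ndarray, positions: np.ndarray,
                     cluster_r2: float):
    """Greedy LD clusters: seeds in descending PIP (position breaks ties),
    members join the seed at r^2 >= cluster_r2; each variant joins one
    cluster."""
    p = pip.size
    order = sorted(range(p), key=lambda j: (-pip[j], positions[j]))
    cluster_id = np.zeros(p, dtype=int)
    next_id = 1
    for seed in order:
        if cluster_id[seed]:
            continue
        members = [j for j in range(p)
                   if not cluster_id[j] and (j == seed or r2[seed, j] >= cluster_r2)]
        for j in members:
            cluster_id[j] = next_id
        next_id += 1
    cluster_pip = np.array([pip[cluster_id == cid].sum() for cid in cluster_id])
    return cluster_id, cluster_pip


def penalty_factors(fm: FineMapResult, pip_threshold: float = 0.001,
                    cluster_filter: bool = False) -> dict[str, float]:
    """1 - PIP penalty factors for the eligible variants of a locus.

    Eligibility: PIP > pip_threshold; with cluster_filter, only the
    highest-PIP variant of each cluster remains.  Ineligible variants are
    excluded from the elastic-net design entirely.
    """
    eligible = {j for j in range(len(fm.pip)) if fm.pip[j] > pip_threshold}
    if cluster_filter:
        best_by_cluster: dict[int, int] = {}
        for j in eligible:
            cid = int(fm.cluster_id[j])
            if cid not in best_by_cluster or fm.pip[j] > fm.pip[best_by_cluster[cid]]:
                best_by_cluster[cid] = j
        eligible = set(best_by_cluster.values())
    if not eligible:
        logger.info("locus %s: no variant passes PIP > %s", fm.locus, pip_threshold)
    return {fm.variant_ids[j]: float(1.0 - fm.pip[j]) for j in sorted(eligible)}
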