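"""Approximate-Bayes-factor colocalization of pQTL and GWAS signals.

Each variant gets a Wakefield approximate Bayes factor per trait from its
z-score and standard error under a normal effect prior; the five standard
hypotheses (no signal / trait-1 only / trait-2 only / two distinct causal
variants / one shared causal variant) are enumerated under a
one-causal-variant-per-trait assumption and normalized to posterior
probabilities P0..P4.  P4 > 0.5 is read as colocalized, P3 > 0.5 as
independent signals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger("pwasforge")


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities for one locus/trait pair."""

    aptamer: str
    gene: str
    trait: str
    p0: float
    p1: float
    p2: float
    p3: float
    p4: float
    n_snps: int
    top_variant: str | None = None

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2, self.p3, self.p4])

    @property
    def colocalized(self) -> bool:
        return self.p4 > 0.5


def wakefield_abf(z, se, prior_sd: float = 0.15):
    """Log approximate Bayes factor for one association (vectorized).

    With V = se^2, W = prior_sd^2 and r = W/(W+V):
    log ABF = 0.5 log(1-r) + z^2 r / 2.
    """
    z = np.asarray(z, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    V = se**2
    W = prior_sd**2
    r = W / (W + V)
    out = 0.5 * np.log1p(-r) + z**2 * r / 2.0
    return out if out.ndim else float(out)


def coloc_posteriors(abf1: np.ndarray, abf2: np.ndarray, p1: float = 1e-4,
                     p2: float = 1e-4, p12: float = 1e-5, *,
                     aptamer: str = "", gene: str = "", trait: str = "",
                     variant_ids: list[str] | None = None) -> ColocResult:
    """Combine per-variant log ABFs of two traits into P0..P4.

    Both vectors must be over the identical (harmonized) variant set.  All
    sums are computed in log space; no overflow up to |z| ~ 50.
    """
    a1 = np.asarray(abf1, dtype=float)
    a2 = np.asarray(abf2, dtype=float)
    if a1.size != a2.size or a1.size == 0:
        raise ValueError("need identical, non-empty variant sets")
    l_s1 = logsumexp(a1)
    l_s2 = logsumexp(a2)
    l_s12 = logsumexp(a1 + a2)

    log_l0 = 0.0
    log_l1 = math.log(p1) + l_s1
    log_l2 = math.log(p2) + l_s2
    log_l4 = math.log(p12) + l_s12
    # sum over distinct pairs = S1*S2 - S12, in log space
    gap = l_s12 - (l_s1 + l_s2)
    if gap >= -1e-12:  # single variant (or numerically no distinct pair)
        log_l3 = -np.inf
    else:
        log_l3 = math.log(p1) + math.log(p2) + l_s1 + l_s2 + math.log1p(-math.exp(gap))

    logs = np.array([log_l0, log_l1, log_l2, log_l3, log_l4])
    norm = logsumexp(logs[np.isfinite(logs)])
    post = np.exp(np.where(np.isfinite(logs), logs - norm, -np.inf))
    top = None
    if variant_ids is not None:
        top = variant_ids[int(np.argmax(a1 + a2))]
    return ColocResult(aptamer=aptamer, gene=gene, trait=trait,
                       p0=float(post[0]), p1=float(post[1]), p2=float(post[2]),
                       p3=float(post[3]), p4=float(post[4]),
                       n_snps=int(a1.size), top_variant=top)


def colocalize(pqtl_table: pd.DataFrame, gwas, aptamer: str, gene: str, *,
               prior_sd_pqtl: float = 0.15, prior_sd_gwas: float = 0.15,
               p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
               ) -> ColocResult:
    """Colocalize one aptamer-gene locus with one GWAS.

    Variants are matched by id between the locus's pQTL rows and the GWAS
    summary table; the pQTL side uses its in-sample t and se, the GWAS
    side its z and se.
    """
    sub = pqtl_table[(pqtl_table["aptamer_id"] == aptamer)
                     & (pqtl_table["gene_id"] == gene)]
    gt = gwas.table.set_index("snp")
    shared = [v for v in sub["variant_id"] if v in gt.index]
    if not shared:
        raise ValueError(f"no shared variants for {aptamer}/{gene} vs {gwas.trait}")
    sub = sub.set_index("variant_id").loc[shared]
    gsub = gt.loc[shared]
    ok = (sub["se"].to_numpy() > 0) & (gsub["se"].to_numpy() > 0)
    if not ok.all():
        logger.info("%s/%s: dropped %d variants with nonpositive se",
                    aptamer, gene, int((~ok).sum()))
    sub, gsub = sub[ok], gsub[ok]
    shared = [s for s, k in zip(shared, ok) if k]
    a1 = wakefield_abf(sub["t"].to_numpy(), sub["se"].to_numpy(), prior_sd_pqtl)
    a2 = wakefield_abf(gsub["z"].to_numpy(), gsub["se"].to_numpy(), prior_sd_gwas)
    return coloc_posteriors(a1, a2, p1, p2, p12, aptamer=aptamer, gene=gene,
                            trait=gwas.trait, variant_ids=shared)


def coloc_results_to_frame(results: list[ColocResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "aptamer": r.aptamer, "gene": r.gene, "trait": r.trait,
        "P0": r.p0, "P1": r.p1, "P2": r.p2, "P3": r.p3, "P4": r.p4,
        "n_snps": r.n_snps, "top_variant": r.top_variant,
    } for r in results])
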