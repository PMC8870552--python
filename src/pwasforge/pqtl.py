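"""Cis-pQTL association scans with Benjamini-Hochberg FDR control.

For each aptamer-gene pair, every variant within 1 Mb of the gene's TSS is
tested by simple linear regression of the adjusted aptamer level on the
dosage (covariates are already regressed out of the response upstream).
Aptamers that map to several genes are scanned once per gene with
identical response values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genio import AptamerAnnotation, GenotypeMatrix
from .phenoprep import AbundanceMatrix

logger = logging.getLogger("pwasforge")


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def marginal_regression(y: np.ndarray, X: np.ndarray):
    """Vectorized per-column simple OLS: beta, se, t, p (df = n-2)."""
    n = y.size
    xbar = X.mean(axis=0)
    ybar = y.mean()
    sxx = (X * X).sum(axis=0) - n * xbar**2
    sxy = y @ X - n * xbar * ybar
    syy = float(y @ y - n * ybar**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        rss = np.maximum(syy - beta**2 * sxx, 0.0)
        se = np.sqrt(np.where(sxx > 0, rss / (n - 2) / np.where(sxx > 0, sxx, 1.0), np.inf))
    t = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return beta, se, t, np.clip(p, np.finfo(float).tiny, 1.0)


def map_cis_pqtl(g: GenotypeMatrix, a: AbundanceMatrix, ann: AptamerAnnotation,
                 population: str = "ALL") -> pd.DataFrame:
    """Scan every aptamer-gene cis window; returns the pooled pQTL table.

    Output columns: aptamer_id, gene_id, variant_id, chrom, pos, ref, alt,
    beta, se, t, p, q, population.  q is BH-FDR pooled across all tests in
    the scan.
    """
    if a.stage != "adjusted":
        raise ValueError("abundance must be at the adjusted stage")
    sample_order = a.values.index
    idx = g.samples.set_index("sample_id").index
    if not sample_order.equals(pd.Index(idx)):
        # align genotype rows to abundance rows
        pos_of = {s: i for i, s in enumerate(g.samples["sample_id"])}
        try:
            row_idx = np.array([pos_of[s] for s in sample_order])
        except KeyError as e:
            raise ValueError(f"abundance sample {e} not in genotype matrix") from e
        dosages = g.dosages[row_idx]
    else:
        dosages = g.dosages

    frames = []
    for aptamer, gene, chrom, start, end, _ in ann.loci():
        if aptamer not in a.values.columns:
            continue
        widx = g.variants_in_window(chrom, start, end)
        if widx.size == 0:
            logger.info("no variants in cis window of %s/%s; skipped", aptamer, gene)
            continue
        y = a.values[aptamer].to_numpy()
        beta, se, t, p = marginal_regression(y, dosages[:, widx])
        v = g.variants.iloc[widx]
        frames.append(pd.DataFrame({
            "aptamer_id": aptamer, "gene_id": gene,
            "variant_id": v["variant_id"].to_numpy(),
            "chrom": v["chrom"].to_numpy(), "pos": v["pos"].to_numpy(),
            "ref": v["ref"].to_numpy(), "alt": v["alt"].to_numpy(),
            "beta": beta, "se": se, "t": t, "p": p,
        }))
    if not frames:
        return pd.DataFrame(columns=["aptamer_id", "gene_id", "variant_id", "chrom",
                                     "pos", "ref", "alt", "beta", "se", "t", "p",
                                     "q", "population"])
    table = pd.concat(frames, ignore_index=True)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["population"] = population
    return table
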