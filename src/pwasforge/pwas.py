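"""Summary-statistic protein-trait association (the S-PrediXcan statistic).

Given a trained protein prediction model with weights w, the training-set
dosage covariance Gamma, and GWAS per-SNP z-scores, the protein-level
association z-score is

    z_protein = sum_l w_l * sigma_l * z_l / sigma_protein,
    sigma_protein^2 = w' Gamma w,   sigma_l = sqrt(Gamma_ll),

i.e. the association between the genetically predicted protein level and
the trait, computable from summary statistics alone.  LD (Gamma) comes
from the model training population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("pwasforge")

GWAS_COLUMNS = ["snp", "chr", "pos", "effect_allele", "other_allele",
                "beta", "se", "z", "p", "n"]


@dataclass
class GwasSummary:
    """GWAS summary statistics table (one row per variant)."""

    table: pd.DataFrame
    trait: str = "trait"

    def __post_init__(self) -> None:
        missing = set(GWAS_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"GWAS summary missing columns: {sorted(missing)}")
        t = self.table
        both = t["z"].notna() & t["se"].notna() & (t["se"] > 0) & t["beta"].notna()
        if both.any():
            implied = t.loc[both, "beta"] / t.loc[both, "se"]
            rel = np.abs(implied - t.loc[both, "z"]) / np.maximum(np.abs(implied), 1e-8)
            bad = (rel > 0.10) & (np.abs(implied) > 1e-6)
            if bad.any():
                raise ValueError(f"{int(bad.sum())} rows with z inconsistent with beta/se")

    @classmethod
    def read_tsv(cls, path: str, trait: str = "trait") -> "GwasSummary":
        return cls(table=pd.read_csv(path, sep="\t", dtype={"chr": str}), trait=trait)

    def write_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class AssociationResult:
    """One protein-trait association from S-PrediXcan."""

    aptamer: str
    gene: str
    trait: str
    population: str
    strategy: str
    z: float
    p: float
    direction: int
    n_snps_used: int
    n_snps_model: int
    bonferroni: bool = False


def harmonize_gwas(gwas: GwasSummary, model) -> dict[str, float]:
    """Align GWAS z-scores to the model's effect alleles.

    Variants are matched by chrom:pos and allele pair; when the GWAS effect
    allele equals the model's non-effect (ref) allele the z sign is flipped.
    Mismatched allele pairs are dropped (counted in the log).
    """
    t = gwas.table
    gw = {}
    for row in t.itertuples(index=False):
        gw[(str(row.chr), int(row.pos))] = row
    aligned: dict[str, float] = {}
    n_dropped = 0
    for w in model.weights.itertuples(index=False):
        row = gw.get((str(w.chrom), int(w.pos)))
        if row is None:
            continue
        z = row.z if np.isfinite(row.z) else row.beta / row.se
        ea, oa = str(row.effect_allele).upper(), str(row.other_allele).upper()
        if (ea, oa) == (w.eff_allele, w.ref_allele):
            aligned[w.variant_id] = float(z)
        elif (ea, oa) == (w.ref_allele, w.eff_allele):
            aligned[w.variant_id] = -float(z)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("harmonize_gwas: dropped %d variants with mismatched alleles", n_dropped)
    return aligned


def spredixcan_assoc(model, cov, gwas: GwasSummary) -> AssociationResult | None:
    """S-PrediXcan association for one model against one GWAS.

    Model variants absent from the GWAS are dropped from both the numerator
    and the covariance submatrix.  Returns None when no variant overlaps or
    the predicted-protein variance is numerically zero.
    """
    aligned = harmonize_gwas(gwas, model)
    if not aligned:
        logger.info("no GWAS overlap for %s / %s", model.aptamer, gwas.trait)
        return None
    vids = [v for v in model.weights["variant_id"] if v in aligned]
    w = model.weights.set_index("variant_id").loc[vids, "weight"].to_numpy(dtype=float)
    gamma = cov.submatrix(model.aptamer, vids)
    sigma2 = float(w @ gamma @ w)
    if sigma2 <= 1e-12:
        logger.info("zero predicted variance for %s / %s", model.aptamer, gwas.trait)
        return None
    sig_l = np.sqrt(np.diag(gamma))
    zvec = np.array([aligned[v] for v in vids])
    z_protein = float((w * sig_l * zvec).sum() / np.sqrt(sigma2))
    p = float(2 * stats.norm.sf(abs(z_protein)))
    return AssociationResult(
        aptamer=model.aptamer, gene=model.gene, trait=gwas.trait,
        population=model.population, strategy=model.strategy,
        z=z_protein, p=max(p, np.finfo(float).tiny),
        direction=int(np.sign(z_protein)) or 1,
        n_snps_used=len(vids), n_snps_model=len(model.weights),
    )


def pooled_bonferroni(results: list[AssociationResult], strategy: str,
                      alpha: float = 0.05) -> float:
    """Bonferroni threshold pooled over every test for one model strategy.

    All association tests for all populations and all traits of the given
    strategy are pooled; the threshold is alpha / n_tests.  Flags are set
    on the results in place.
    """
    pool = [r for r in results if r.strategy == strategy]
    if not pool:
        raise ValueError(f"no association results for strategy {strategy!r}")
    threshold = alpha / len(pool)
    for r in pool:
        r.bonferroni = r.p < threshold
    return threshold


def associations_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "aptamer": r.aptamer, "gene": r.gene, "trait": r.trait,
        "population": r.population, "strategy": r.strategy,
        "zscore": r.z, "pvalue": r.p, "direction": r.direction,
        "n_snps_used": r.n_snps_used, "n_snps_model": r.n_snps_model,
        "bonferroni_flag": r.bonferroni,
    } for r in results])
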