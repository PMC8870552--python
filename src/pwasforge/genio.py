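"""Genotype and annotation ingestion, QC filters, PCA, MAF and F_ST.

Dosage matrices are held in memory as samples x variants float arrays with
variant metadata (chromosome, 1-based position, ref/alt alleles, imputation
R-squared) in a pandas DataFrame and per-sample population labels alongside.
Variants are biallelic SNPs; imputed dosages may be fractional in [0, 2].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("pwasforge")

#: VEP consequence terms treated as protein-altering (may change aptamer binding).
PAV_CONSEQUENCES = (
    "coding sequence variant",
    "frameshift variant",
    "inframe deletion",
    "inframe insertion",
    "missense variant",
    "protein altering variant",
    "splice acceptor variant",
    "splice donor variant",
    "splice region variant",
    "start lost",
    "stop gained",
    "stop lost",
)

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "r2"]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with metadata.

    Attributes
    ----------
    dosages : ndarray, shape (n_samples, n_variants)
        Allelic dosages of the alt allele, in [0, 2].
    samples : DataFrame with columns ``sample_id``, ``population``.
    variants : DataFrame with columns ``variant_id, chrom, pos, ref, alt, r2``.
    """

    dosages: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.dosages.size and (self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("variant ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def populations(self) -> list[str]:
        return sorted(self.samples["population"].unique())

    def sample_mask(self, population: str) -> np.ndarray:
        if population == "ALL":
            return np.ones(self.n_samples, dtype=bool)
        return (self.samples["population"] == population).to_numpy()

    def alt_frequency(self, population: str = "ALL") -> np.ndarray:
        """Estimated alt-allele frequency p-hat = mean(dosage)/2 per variant."""
        mask = self.sample_mask(population)
        if not mask.any():
            raise ValueError(f"no samples in population {population!r}")
        return self.dosages[mask].mean(axis=0) / 2.0

    def maf(self, population: str = "ALL") -> np.ndarray:
        """Minor allele frequency min(p, 1-p) per variant."""
        p = self.alt_frequency(population)
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            samples=self.samples.reset_index(drop=True),
            variants=self.variants.iloc[index].reset_index(drop=True),
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[mask],
            samples=self.samples.loc[mask].reset_index(drop=True),
            variants=self.variants.reset_index(drop=True),
        )

    def variants_in_window(self, chrom, start: int, end: int) -> np.ndarray:
        """Indices of variants in [start, end] (1-based, closed) on chrom."""
        v = self.variants
        return np.flatnonzero(
            (v["chrom"].astype(str) == str(chrom))
            & (v["pos"] >= max(start, 1))
            & (v["pos"] <= end)
        )


@dataclass
class AptamerAnnotation:
    """Aptamer -> gene mapping with TSS coordinates and optional PAV lists.

    ``table`` columns: aptamer_id, gene_id, chrom, tss, pav_ids (list of
    variant ids), pav_consequences (list of VEP-style labels).  An aptamer
    binding a protein complex may map to several genes; each aptamer-gene
    pair defines an independent cis locus.
    """

    table: pd.DataFrame
    cis_window: int = 1_000_000

    def __post_init__(self) -> None:
        required = {"aptamer_id", "gene_id", "chrom", "tss"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        for col in ("pav_ids", "pav_consequences"):
            if col not in self.table.columns:
                self.table[col] = [[] for _ in range(len(self.table))]

    def loci(self):
        """Yield (aptamer_id, gene_id, chrom, window_start, window_end, pav_ids)."""
        for row in self.table.itertuples(index=False):
            start = max(int(row.tss) - self.cis_window, 1)
            end = int(row.tss) + self.cis_window
            yield row.aptamer_id, row.gene_id, row.chrom, start, end, list(row.pav_ids)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_genotypes_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a VCF v4.2 with one ALT per record and DS in FORMAT.

    Imputation R2 goes to INFO; population labels are not part of VCF and
    must be carried in a covariate table.
    """
    order = np.lexsort((g.variants["pos"].to_numpy(), g.variants["chrom"].astype(str).to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation R-squared">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        for chrom in pd.unique(g.variants["chrom"].astype(str).iloc[order]):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(g.samples["sample_id"].astype(str))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        gt_codes = ("0/0", "0/1", "1/1")
        for j in order:
            v = g.variants.iloc[j]
            ds = g.dosages[:, j]
            gt = np.clip(np.rint(ds).astype(int), 0, 2)
            fields = [f"{gt_codes[k]}:{d:.3f}" for k, d in zip(gt, ds)]
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{v['variant_id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\tPASS\tR2={v['r2']:.4f}\tGT:DS\t" + "\t".join(fields) + "\n"
            )


def read_genotypes_vcf(path: str, populations: dict | None = None) -> GenotypeMatrix:
    """Read biallelic records from a VCF; DS preferred, GT fallback.

    Multiallelic records are skipped with a warning.  ``populations`` maps
    sample id -> population label (default "ALL" for every sample).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    rows = []
    dosage_rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping multiallelic record %s:%s", rec.CHROM, rec.POS)
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # GT fallback: count of alt alleles, e.g. 0/1 -> 1.0
            gts = np.asarray(rec.genotypes)[:, :2]
            d = np.clip(gts, 0, None).sum(axis=1).astype(float)
        r2 = rec.INFO.get("R2")
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        rows.append((vid, str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0],
                     float(r2) if r2 is not None else 1.0))
        dosage_rows.append(d)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dos = np.array(dosage_rows, dtype=float).T if dosage_rows else np.empty((len(sample_ids), 0))
    populations = populations or {}
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "population": [populations.get(s, "ALL") for s in sample_ids],
    })
    return GenotypeMatrix(dosages=np.round(dos, 3), samples=samples, variants=variants)


def write_genotypes_tsv(g: GenotypeMatrix, path: str) -> None:
    """Dosage TSV: first column ``chr:pos:ref:alt`` variant key, then samples."""
    keys = (
        g.variants["chrom"].astype(str) + ":" + g.variants["pos"].astype(str)
        + ":" + g.variants["ref"] + ":" + g.variants["alt"]
    )
    df = pd.DataFrame(g.dosages.T, index=keys, columns=g.samples["sample_id"])
    df.index.name = "variant"
    df.round(3).to_csv(path, sep="\t")


def read_genotypes_tsv(path: str, populations: dict | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    parts = df.index.to_series().str.split(":", expand=True)
    if parts.shape[1] != 4:
        raise ValueError(f"{path}: variant keys must be chr:pos:ref:alt")
    variants = pd.DataFrame({
        "variant_id": df.index,
        "chrom": parts[0].to_numpy(),
        "pos": parts[1].astype(int).to_numpy(),
        "ref": parts[2].to_numpy(),
        "alt": parts[3].to_numpy(),
        "r2": 1.0,
    }).reset_index(drop=True)
    populations = populations or {}
    samples = pd.DataFrame({
        "sample_id": df.columns,
        "population": [populations.get(s, "ALL") for s in df.columns],
    })
    return GenotypeMatrix(dosages=df.to_numpy().T, samples=samples, variants=variants)


def read_genotypes(path: str, format: str = "vcf", populations: dict | None = None) -> GenotypeMatrix:
    if format == "vcf":
        return read_genotypes_vcf(path, populations)
    if format == "tsv":
        return read_genotypes_tsv(path, populations)
    raise ValueError(f"unknown genotype format {format!r}")


def read_annotation(path: str) -> AptamerAnnotation:
    """Annotation TSV columns: aptamer_id, gene_id, chrom, tss, pav_ids, pav_consequences.

    pav_ids / pav_consequences are comma-separated (empty allowed).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("pav_ids", "pav_consequences"):
        if col in df.columns:
            df[col] = df[col].fillna("").apply(lambda s: [x for x in str(s).split(",") if x])
    return AptamerAnnotation(table=df)


def write_annotation(ann: AptamerAnnotation, path: str) -> None:
    df = ann.table.copy()
    for col in ("pav_ids", "pav_consequences"):
        df[col] = df[col].apply(",".join)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC and population-genetic statistics
# ---------------------------------------------------------------------------

def qc_filter(g: GenotypeMatrix, maf_min: float = 0.01, r2_min: float = 0.8,
              population: str = "ALL") -> GenotypeMatrix:
    """Filter variants on imputation R2 and MAF.

    Per-population mode keeps variants with that population's MAF > maf_min
    and R2 > r2_min.  "ALL" mode keeps the intersection of variants passing
    R2 in every population, with MAF computed on the combined sample.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0 <= r2_min <= 1):
        raise ValueError("r2_min must be in [0, 1]")
    # per-population imputation quality may be supplied as r2_<POP> columns
    r2_cols = [c for c in g.variants.columns if c.startswith("r2_")]
    if population == "ALL":
        if r2_cols:
            r2_pass = np.ones(g.n_variants, dtype=bool)
            for c in r2_cols:  # intersection: R2 must pass in every population
                r2_pass &= g.variants[c].to_numpy(dtype=float) > r2_min
        else:
            r2_pass = g.variants["r2"].to_numpy(dtype=float) > r2_min
        keep = r2_pass & (g.maf("ALL") > maf_min)
    else:
        col = f"r2_{population}" if f"r2_{population}" in g.variants.columns else "r2"
        keep = (g.variants[col].to_numpy(dtype=float) > r2_min) & (g.maf(population) > maf_min)
    if not keep.any():
        logger.warning("qc_filter removed every variant (maf_min=%s, r2_min=%s)", maf_min, r2_min)
    return g.subset_variants(np.flatnonzero(keep))


def genotype_pca(g: GenotypeMatrix, k: int = 10):
    """Principal components of the centered, unit-variance dosage matrix.

    Returns (scores, explained_variance_ratio).  Monomorphic variants are
    dropped before scaling.  Plain PCA: samples are assumed unrelated.
    """
    if k == 0:
        return np.empty((g.n_samples, 0)), np.empty(0)
    X = g.dosages
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic variants for PCA")
    if g.n_samples < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} components")
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    # economy SVD; rank limited by min(n-1, p)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    scores = U[:, :k] * s[:k]
    evr = (s**2) / (s**2).sum()
    return scores, evr[:k]


def fst_hudson(p1, p2, n1: int, n2: int):
    """Hudson's F_ST estimator for one SNP (vectorized over frequencies).

    [(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)] / [p1(1-p2) + p2(1-p1)].
    Returns NaN where the denominator is 0 (both populations fixed for the
    same allele).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("frequencies must be in [0, 1]")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return fst if fst.ndim else float(fst)


def fst_hudson_mean(p1, p2, n1: int, n2: int) -> float:
    """Ratio-of-averages Hudson F_ST over a set of SNPs (model-level F_ST)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    if not ok.any():
        return float("nan")
    return float(num[ok].sum() / den[ok].sum())


def fst_weir_cockerham(p1, p2, n1: int, n2: int):
    """Weir-Cockerham two-population theta from allele frequencies.

    Heterozygosity taken at its HWE expectation 2p(1-p) per population.
    Provided as an optional cross-check estimator; vectorized per SNP.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * 2 * p1 * (1 - p1) + n2 * 2 * p2 * (1 - p2)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        den = a + b + c
        fst = np.where(den != 0, a / np.where(den != 0, den, 1.0), np.nan)
    return fst if fst.ndim else float(fst)
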