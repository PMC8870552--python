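"""Synthetic multi-population genotype, proteome and GWAS generation.

Every downstream stage of the pipeline is exercised on data from this
module, with full ground truth retained: causal cis variants and their
effects, true cis-heritability, aptamer binding-affinity (PAV) artifacts,
and the protein-mediation effects that drive the simulated GWAS traits.

Population structure follows the Balding-Nichols model: per-population
allele frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) draws around an
ancestral frequency p, so the expected differentiation between populations
is governed by the single parameter F (approximately F_ST).  Within a
locus, haplotypes are generated from a latent first-order Gaussian chain
with neighbour correlation ``ld_decay`` thresholded at the allele
frequency, giving geometrically decaying pairwise LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import PAV_CONSEQUENCES, AptamerAnnotation, GenotypeMatrix
from .pwas import GwasSummary

__all__ = [
    "SimTruth",
    "simulate_genotypes",
    "simulate_proteome",
    "simulate_gwas_pair",
    "default_annotation",
]


@dataclass
class SimTruth:
    """Ground truth for one simulated data set.

    causal_effects map aptamer id -> list of (variant_id, effect) on the
    latent log-abundance scale; h2 is the true cis-heritability of that
    latent variable.  pav_effects hold binding-affinity artifact terms for
    artifact-driven aptamers.  gamma is the protein -> trait mediation
    effect used by the GWAS generator.
    """

    ancestral_freq: np.ndarray
    pop_freqs: dict[str, np.ndarray]
    fst_target: float | dict[str, float]
    ld_decay: float
    variants: pd.DataFrame
    locus_index: list[np.ndarray]  # variant column indices per locus
    causal_effects: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    h2: dict[str, float] = field(default_factory=dict)
    pav_effects: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    gamma: dict[str, float] = field(default_factory=dict)
    genetic_values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fvals = (self.fst_target.values() if isinstance(self.fst_target, dict)
                 else [self.fst_target])
        if any(not (0 <= f < 1) for f in fvals):
            raise ValueError("fst_target must be in [0, 1)")
        known = set(self.variants["variant_id"])
        for apt, pairs in self.causal_effects.items():
            for vid, eff in pairs:
                if vid not in known:
                    raise ValueError(f"causal variant {vid} for {apt} not in panel")
                if not np.isfinite(eff):
                    raise ValueError(f"non-finite effect for {apt}/{vid}")
        for h in self.h2.values():
            if not (0 <= h <= 1):
                raise ValueError("h2 must be in [0, 1]")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

_LOCUS_SPACING = 5_000_000
_SNP_SPACING = 1_000


def _haplotype_dosages(freqs: np.ndarray, n_ind: int, ld_decay: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Dosages for one locus: two latent-AR(1)-threshold haplotypes per person.

    The latent chain z_j = r z_{j-1} + sqrt(1-r^2) eps keeps adjacent latent
    correlation at ``ld_decay``; alleles are 1 where z < Phi^-1(freq), so the
    marginal allele frequency is ``freqs`` and LD decays geometrically.
    """
    p = len(freqs)
    thresh = stats.norm.ppf(freqs)
    dosage = np.zeros((n_ind, p), dtype=np.float32)
    for _ in range(2):
        z = np.empty((n_ind, p), dtype=np.float32)
        z[:, 0] = rng.standard_normal(n_ind, dtype=np.float32)
        if p > 1:
            eps = rng.standard_normal((n_ind, p - 1), dtype=np.float32)
            scale = np.sqrt(1.0 - ld_decay**2)
            for j in range(1, p):
                z[:, j] = ld_decay * z[:, j - 1] + scale * eps[:, j - 1]
        dosage += (z < thresh[None, :]).astype(np.float32)
    return dosage


def simulate_genotypes(n_per_population: dict[str, int], n_loci: int = 10,
                       snps_per_locus: int = 20,
                       fst_target: float | dict[str, float] = 0.1,
                       ld_decay: float = 0.7, seed: int = 0, *,
                       fst_locus_shape: float | None = None,
                       ) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a multi-population dosage panel with blockwise LD.

    Parameters
    ----------
    n_per_population : mapping population label -> sample count (each >= 1).
    fst_target : Balding-Nichols F in [0, 1); 0 gives frequencies identical
        to the ancestral draw.  A mapping gives each population its own F
        (its differentiation from the ancestral pool).
    ld_decay : latent neighbour correlation in [0, 1).
    fst_locus_shape : when set, per-locus drift multipliers are drawn from
        Gamma(shape, 1/shape) (mean 1) and scale every population's F at
        that locus, emulating the heterogeneous differentiation real
        genomes show across loci; None keeps drift homogeneous.
    """
    fst_by_pop = (dict(fst_target) if isinstance(fst_target, dict)
                  else {pop: float(fst_target) for pop in n_per_population})
    if any(not (0 <= f < 1) for f in fst_by_pop.values()):
        raise ValueError("fst_target must be in [0, 1)")
    if not (0 <= ld_decay < 1):
        raise ValueError("ld_decay must be in [0, 1)")
    if any(n < 1 for n in n_per_population.values()):
        raise ValueError("population counts must be >= 1")
    rng = np.random.default_rng(seed)

    n_snps = n_loci * snps_per_locus
    ancestral = rng.uniform(0.05, 0.95, size=n_snps)
    if fst_locus_shape is not None:
        locus_mult = rng.gamma(fst_locus_shape, 1.0 / fst_locus_shape, size=n_loci)
    else:
        locus_mult = np.ones(n_loci)
    snp_f_scale = np.repeat(locus_mult, snps_per_locus)
    pop_freqs: dict[str, np.ndarray] = {}
    for pop in n_per_population:
        F = np.clip(fst_by_pop[pop] * snp_f_scale, 0.0, 0.95)
        pf = np.where(
            F > 0,
            rng.beta(ancestral * (1 - F) / np.maximum(F, 1e-12),
                     (1 - ancestral) * (1 - F) / np.maximum(F, 1e-12)),
            ancestral,
        )
        pf = np.where(F > 0, np.clip(pf, 1e-3, 1 - 1e-3), pf)
        pop_freqs[pop] = pf

    rows = []
    locus_index = []
    for l in range(n_loci):
        start = 1_000_000 + l * _LOCUS_SPACING
        idx = np.arange(l * snps_per_locus, (l + 1) * snps_per_locus)
        locus_index.append(idx)
        for k, j in enumerate(idx):
            pos = start + k * _SNP_SPACING
            rows.append((f"1:{pos}:A:G", "1", pos, "A", "G", 1.0))
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt", "r2"])

    blocks = []
    sample_rows = []
    for pop, n in n_per_population.items():
        locus_blocks = [
            _haplotype_dosages(pop_freqs[pop][idx], n, ld_decay, rng)
            for idx in locus_index
        ]
        blocks.append(np.concatenate(locus_blocks, axis=1))
        sample_rows += [(f"{pop}_{i:05d}", pop) for i in range(n)]
    dosages = np.concatenate(blocks, axis=0).astype(float)
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population"])

    g = GenotypeMatrix(dosages=dosages, samples=samples, variants=variants)
    truth = SimTruth(
        ancestral_freq=ancestral, pop_freqs=pop_freqs, fst_target=fst_target,
        ld_decay=ld_decay, variants=variants, locus_index=locus_index,
    )
    return g, truth


def default_annotation(truth: SimTruth, cis_window: int = 1_000_000) -> AptamerAnnotation:
    """One aptamer-gene pair per simulated locus, TSS at the locus midpoint."""
    rows = []
    for l, idx in enumerate(truth.locus_index):
        pos = truth.variants["pos"].to_numpy()[idx]
        tss = int(pos.mean())
        rows.append((f"APT_{l:04d}", f"GENE_{l:04d}", "1", tss, [], []))
    table = pd.DataFrame(rows, columns=["aptamer_id", "gene_id", "chrom", "tss",
                                        "pav_ids", "pav_consequences"])
    return AptamerAnnotation(table=table, cis_window=cis_window)


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

def simulate_proteome(genotypes: GenotypeMatrix, annotation: AptamerAnnotation,
                      truth: SimTruth, n_causal: int = 1, h2: float = 0.5,
                      pav_fraction: float = 0.0, artifact_sd: float = 1.0,
                      n_timepoints: int = 2, seed: int = 0, *,
                      n_pav_per_aptamer: int = 1, missing_rate: float = 0.2,
                      age_effect: float = 0.01, sex_effect: float = 0.1,
                      timepoint_sd: float = 0.3):
    """Simulate raw aptamer abundances over one or more timepoints.

    The latent (person-level) log abundance is genetic value + person noise
    scaled so var(genetic)/var(latent) = h2.  A ``pav_fraction`` of aptamers
    is artifact-driven: their only genetic signal is a binding-affinity term
    PAV dosage x N(0, artifact_sd), emulating aptamer assays where a coding
    variant changes reagent binding rather than true abundance.  Each
    observed timepoint adds age/sex covariate effects and timepoint noise
    before exponentiation to a positive raw scale.

    Returns (raw long DataFrame [sample, aptamer, timepoint, value],
    covariates DataFrame [sample, age, sex, population], truth updated in
    place with causal effects, h2 and PAV artifacts).
    """
    if not (0 <= h2 <= 1):
        raise ValueError("h2 must be in [0, 1]")
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples

    age = rng.uniform(45, 85, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    covariates = pd.DataFrame({
        "sample": genotypes.samples["sample_id"],
        "age": age, "sex": sex,
        "population": genotypes.samples["population"],
    })

    loci = list(annotation.loci())
    n_apt = len(loci)
    artifact_flag = rng.random(n_apt) < pav_fraction

    records = []
    vid_arr = genotypes.variants["variant_id"].to_numpy()
    for k, (aptamer, gene, chrom, start, end, _) in enumerate(loci):
        widx = genotypes.variants_in_window(chrom, start, end)
        if widx.size == 0:
            raise ValueError(f"aptamer {aptamer} maps to a window with no variants")
        if n_causal > widx.size:
            raise ValueError("n_causal exceeds variants in window")
        maf = genotypes.maf("ALL")[widx]
        eligible = widx[maf >= 0.05] if (maf >= 0.05).any() else widx
        pav_pool = rng.permutation(widx)
        pav_idx = pav_pool[:min(n_pav_per_aptamer, widx.size)]
        pav_ids = [vid_arr[j] for j in pav_idx]
        pav_cons = list(rng.choice(PAV_CONSEQUENCES, size=len(pav_ids)))
        ann_row = annotation.table.index[annotation.table["aptamer_id"] == aptamer][0]
        annotation.table.at[ann_row, "pav_ids"] = pav_ids
        annotation.table.at[ann_row, "pav_consequences"] = pav_cons

        # always draw the artifact coefficient so rng streams line up
        artifact_coef = rng.standard_normal() * artifact_sd

        if artifact_flag[k]:
            # artifact-driven: zero true abundance genetics beyond PAV term
            truth.causal_effects[aptamer] = []
            truth.h2[aptamer] = 0.0
            pav_col = genotypes.dosages[:, pav_idx[0]]
            genetic = artifact_coef * pav_col
            truth.pav_effects[aptamer] = [(pav_ids[0], artifact_coef)]
            person_var = 1.0
        else:
            cidx = rng.choice(eligible, size=min(n_causal, eligible.size), replace=False)
            raw_eff = rng.normal(0.0, 1.0, size=cidx.size)
            gvec = genotypes.dosages[:, cidx] @ raw_eff
            vg = gvec.var()
            if h2 > 0 and vg > 0:
                scale = np.sqrt(h2 / vg)
                person_var = 1.0 - h2
            else:
                scale = 0.0
                person_var = 1.0
            eff = raw_eff * scale
            genetic = gvec * scale
            truth.causal_effects[aptamer] = [
                (vid_arr[j], float(e)) for j, e in zip(cidx, eff)
            ]
            truth.h2[aptamer] = h2
            truth.pav_effects[aptamer] = []

        person_noise = rng.normal(0.0, np.sqrt(person_var), size=n)
        latent = genetic + person_noise
        truth.genetic_values[aptamer] = np.asarray(genetic, dtype=float)

        sample_ids = covariates["sample"].to_numpy()
        for t in range(n_timepoints):
            eps = rng.normal(0.0, timepoint_sd, size=n)
            log_abund = latent + age_effect * age + sex_effect * sex + eps
            observed = np.ones(n, dtype=bool)
            if t > 0 and missing_rate > 0:
                observed = rng.random(n) >= missing_rate
            records.append(pd.DataFrame({
                "sample": sample_ids[observed],
                "aptamer": aptamer,
                "timepoint": t + 1,
                "value": np.exp(log_abund[observed]),
            }))

    raw = pd.concat(records, ignore_index=True)
    return raw, covariates, truth


# ---------------------------------------------------------------------------
# GWAS cohorts
# ---------------------------------------------------------------------------

def _marginal_gwas(dosages: np.ndarray, trait: np.ndarray,
                   variants: pd.DataFrame, n: int) -> pd.DataFrame:
    """Per-SNP simple linear regression summary statistics (vectorized)."""
    X = dosages
    y = trait
    xbar = X.mean(axis=0)
    ybar = y.mean()
    sxx = (X * X).sum(axis=0) - n * xbar**2
    sxy = y @ X - n * xbar * ybar
    syy = float(y @ y - n * ybar**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        rss = syy - beta**2 * sxx
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        se = np.sqrt(np.where(sxx > 0, sigma2 / np.where(sxx > 0, sxx, 1.0), np.inf))
    z = np.where(se > 0, beta / se, 0.0)
    p = 2 * stats.t.sf(np.abs(z), df=n - 2)
    return pd.DataFrame({
        "snp": variants["variant_id"],
        "chr": variants["chrom"],
        "pos": variants["pos"],
        "effect_allele": variants["alt"],
        "other_allele": variants["ref"],
        "beta": beta, "se": se, "z": z,
        "p": np.clip(p, np.finfo(float).tiny, 1.0),
        "n": n,
    })


def _simulate_cohort_summary(truth: SimTruth, protein_effects: dict[str, float],
                             annotation: AptamerAnnotation, n: int,
                             population: str, noise_sd: float,
                             rng: np.random.Generator) -> GwasSummary:
    freqs = truth.pop_freqs[population]
    blocks = [
        _haplotype_dosages(freqs[idx], n, truth.ld_decay, rng)
        for idx in truth.locus_index
    ]
    X = np.concatenate(blocks, axis=1).astype(np.float32)
    col_of = {vid: j for j, vid in enumerate(truth.variants["variant_id"])}
    trait = rng.normal(0.0, noise_sd, size=n)
    for aptamer, gamma in protein_effects.items():
        if gamma == 0:
            continue
        for vid, eff in truth.causal_effects.get(aptamer, []):
            trait = trait + gamma * eff * X[:, col_of[vid]].astype(float)
    table = _marginal_gwas(X.astype(float), trait, truth.variants, n)
    return GwasSummary(table=table)


def simulate_gwas_pair(truth: SimTruth, protein_effects: dict[str, float],
                       n_discovery: int = 10_000, n_replication: int = 10_000,
                       seed: int = 0, *, annotation: AptamerAnnotation | None = None,
                       population: str | None = None, noise_sd: float = 1.0,
                       ) -> tuple[GwasSummary, GwasSummary]:
    """Paired discovery/replication GWAS of a protein-mediated trait.

    Two cohorts are drawn independently at the individual level from the
    same generative population frequencies; the trait is
    sum_a gamma_a * (true genetic protein value) + N(0, noise_sd).  Per-SNP
    marginal regressions are then summarized exactly (beta, se, z, p, N).
    """
    if n_discovery < 100 or n_replication < 100:
        raise ValueError("cohort sizes must be >= 100")
    rng = np.random.default_rng(seed)
    if population is None:
        population = next(iter(truth.pop_freqs))
    truth.gamma.update(protein_effects)
    disc = _simulate_cohort_summary(truth, protein_effects, annotation, n_discovery,
                                    population, noise_sd, rng)
    repl = _simulate_cohort_summary(truth, protein_effects, annotation, n_replication,
                                    population, noise_sd, rng)
    return disc, repl
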