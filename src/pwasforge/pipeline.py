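"""End-to-end synthetic-study pipeline.

Chains every stage on simulated data: genotypes -> proteome -> abundance
preparation -> cis-pQTL scan -> fine-mapping -> penalty-factor elastic
net (baseline and fine-mapped strategies) -> paired discovery/replication
GWAS -> S-PrediXcan -> colocalization -> triage verdicts.  Ground truth
from the generator is carried through so calibration and power can be
measured directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import enet, finemap, phenoprep, pqtl, pwas, simdata, triage
from .genio import genotype_pca

logger = logging.getLogger("pwasforge")


@dataclass
class PipelineConfig:
    """Tunable study conditions for one synthetic pipeline run."""

    n_train: int = 400
    n_proteins: int = 50
    snps_per_locus: int = 20
    n_causal: int = 1
    h2: float = 0.5
    fst_target: float = 0.0
    ld_decay: float = 0.7
    n_timepoints: int = 2
    pav_fraction: float = 0.0
    artifact_sd: float = 1.0
    n_mediated: int = 1
    gamma: float = 0.4
    n_gwas: int = 10_000
    gwas_noise_sd: float = 1.0
    n_pcs: int = 10
    pip_threshold: float = 0.001
    cluster_filter: bool = True
    finemap_K: int = 3
    train_population: str = "TRAIN"
    strategies: tuple = ("baseline", "fine_mapped")


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: "simdata.SimTruth"
    annotation: object
    genotypes: object
    abundance: object
    pqtl_table: pd.DataFrame
    finemap_results: dict
    models: list
    covariance: "enet.CovarianceBundle"
    discovery: "pwas.GwasSummary"
    replication: "pwas.GwasSummary"
    assocs: list = field(default_factory=list)
    repl_assocs: list = field(default_factory=list)
    colocs: list = field(default_factory=list)
    records: list = field(default_factory=list)
    summary: pd.DataFrame | None = None
    headline: pd.DataFrame | None = None
    thresholds: dict = field(default_factory=dict)


def train_models_for_locus(g, abundance_values, variants_window, widx, *,
                           aptamer, gene, population, strategies, fm_result=None,
                           pip_threshold=0.001, cluster_filter=True, seed=42,
                           pav_idx=None):
    """Train the requested model strategies for one aptamer-gene locus."""
    out = []
    X_full = g.dosages[:, widx]
    poly = X_full.std(axis=0) > 0
    X = X_full[:, poly]
    vsub = variants_window.iloc[poly].reset_index(drop=True)
    if X.shape[1] == 0:
        return out
    y = abundance_values
    for strategy in strategies:
        if strategy == "baseline":
            pf = np.ones(X.shape[1])
            Xd, vd = X, vsub
        else:
            if fm_result is None:
                continue
            pfs = finemap.penalty_factors(fm_result, pip_threshold, cluster_filter)
            cols = [j for j, vid in enumerate(vsub["variant_id"]) if vid in pfs]
            if not cols:
                continue
            Xd = X[:, cols]
            vd = vsub.iloc[cols].reset_index(drop=True)
            pf = np.array([pfs[v] for v in vd["variant_id"]])
        model, cov = enet.train_final_model(
            Xd, y, pf, vd, aptamer=aptamer, gene=gene, population=population,
            strategy=strategy, seed=seed,
        )
        if model is not None:
            out.append((model, cov))
    return out


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0,
                 **overrides) -> PipelineResult:
    """Run the full synthetic study once.

    ``overrides`` update fields of the default :class:`PipelineConfig`.
    All randomness derives from ``seed``.
    """
    cfg = config or PipelineConfig(**overrides)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    g, truth = simdata.simulate_genotypes(
        {cfg.train_population: cfg.n_train}, n_loci=cfg.n_proteins,
        snps_per_locus=cfg.snps_per_locus, fst_target=cfg.fst_target,
        ld_decay=cfg.ld_decay, seed=int(seeds[0]),
    )
    ann = simdata.default_annotation(truth)
    raw, covariates, truth = simdata.simulate_proteome(
        g, ann, truth, n_causal=cfg.n_causal, h2=cfg.h2,
        pav_fraction=cfg.pav_fraction, artifact_sd=cfg.artifact_sd,
        n_timepoints=cfg.n_timepoints, seed=int(seeds[1]),
    )
    k_pcs = min(cfg.n_pcs, cfg.n_train - 2)
    pcs, _ = genotype_pca(g, k=k_pcs)
    abundance = phenoprep.prepare_abundance(
        raw, covariates, pcs=pcs, n_pcs=k_pcs,
        pc_sample_ids=g.samples["sample_id"].to_numpy(),
    )
    pqtl_table = pqtl.map_cis_pqtl(g, abundance, ann, population=cfg.train_population)

    fm_results = {}
    models = []
    bundle = enet.CovarianceBundle()
    vid_pos = g.variants.set_index("variant_id")["pos"]
    for aptamer, gene, chrom, start, end, _ in ann.loci():
        widx = g.variants_in_window(chrom, start, end)
        if widx.size == 0 or aptamer not in abundance.values.columns:
            continue
        y = abundance.values[aptamer].to_numpy()
        vsub = g.variants.iloc[widx].reset_index(drop=True)
        X = g.dosages[:, widx]
        poly = X.std(axis=0) > 0
        fm = None
        if poly.any():
            fm = finemap.enumerate_posteriors(
                y, X[:, poly], K=cfg.finemap_K, locus=f"{aptamer}:{gene}",
                variant_ids=list(vsub["variant_id"].to_numpy()[poly]),
                positions=vsub["pos"].to_numpy()[poly],
            )
            fm_results[(aptamer, gene)] = fm
        for model, cov in train_models_for_locus(
            g, y, vsub, widx, aptamer=aptamer, gene=gene,
            population=cfg.train_population, strategies=cfg.strategies,
            fm_result=fm, pip_threshold=cfg.pip_threshold,
            cluster_filter=cfg.cluster_filter, seed=int(seeds[2]),
        ):
            bundle.add(f"{model.aptamer}:{model.strategy}",
                       list(model.weights["variant_id"]), cov)
            models.append(model)

    mediated = list(ann.table["aptamer_id"].iloc[: cfg.n_mediated])
    protein_effects = {a: cfg.gamma for a in mediated}
    discovery, replication = simdata.simulate_gwas_pair(
        truth, protein_effects, n_discovery=cfg.n_gwas, n_replication=cfg.n_gwas,
        seed=int(seeds[3]), noise_sd=cfg.gwas_noise_sd,
    )
    discovery.trait = "trait_discovery"
    replication.trait = "trait_replication"

    assocs, repl_assocs = [], []
    for m in models:
        key = f"{m.aptamer}:{m.strategy}"
        a = pwas.spredixcan_assoc(m, _BundleView(bundle, key), discovery)
        if a is not None:
            assocs.append(a)
            r = pwas.spredixcan_assoc(m, _BundleView(bundle, key), replication)
            if r is not None:
                r.trait = a.trait  # same aptamer-trait pairing across cohorts
                repl_assocs.append(r)
    thresholds = {}
    for strategy in {a.strategy for a in assocs}:
        thresholds[strategy] = pwas.pooled_bonferroni(assocs, strategy)

    colocs = []
    for (aptamer, gene) in fm_results:
        try:
            c = coloc_mod.colocalize(pqtl_table, discovery, aptamer, gene)
        except ValueError:
            continue
        colocs.append(c)

    records, summary, headline = triage.triage_associations(assocs, colocs, repl_assocs)
    return PipelineResult(
        config=cfg, truth=truth, annotation=ann, genotypes=g, abundance=abundance,
        pqtl_table=pqtl_table, finemap_results=fm_results, models=models,
        covariance=bundle, discovery=discovery, replication=replication,
        assocs=assocs, repl_assocs=repl_assocs, colocs=colocs, records=records,
        summary=summary, headline=headline, thresholds=thresholds,
    )


class _BundleView:
    """Adapter presenting one bundle entry under the model's aptamer key."""

    def __init__(self, bundle: "enet.CovarianceBundle", key: str):
        self._bundle = bundle
        self._key = key

    def submatrix(self, _aptamer: str, variant_ids: list[str]) -> np.ndarray:
        return self._bundle.submatrix(self._key, variant_ids)
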