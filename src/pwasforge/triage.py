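"""Replication testing and the three-criteria association verdict.

Discovered protein-trait associations pass through three staged filters:
(A) Bonferroni significance in the discovery GWAS, (B) colocalization of
the pQTL and GWAS signals (max P4 > 0.5), and (C) replication — the same
model-trait association is Bonferroni significant in an independent GWAS
with the same direction of effect.  Only colocalized discoveries are
tested for replication; stage counts are therefore monotone
non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coloc import ColocResult
from .pwas import AssociationResult

logger = logging.getLogger("pwasforge")

VERDICTS = ("not_significant", "discovered", "discovered+colocalized",
            "discovered+colocalized+replicated")


@dataclass
class TriageRecord:
    aptamer: str
    gene: str
    trait: str
    population: str
    strategy: str
    discovery_z: float
    discovery_p: float
    bonferroni: bool
    max_p4: float | None
    colocalized: bool
    replication_z: float | None
    replication_p: float | None
    replicated: bool
    direction_concordant: bool | None
    verdict: str
    coloc_missing: bool = False
    replication_untested: bool = False


def replication_test(discovery: AssociationResult,
                     replication: AssociationResult | None,
                     threshold: float) -> dict:
    """Replication flags for one association.

    Replicated iff the replication p is below the (replication-set
    Bonferroni) threshold AND the z signs agree across cohorts.
    """
    if replication is None:
        return {"replicated": False, "untested": True, "concordant": None,
                "z": None, "p": None}
    concordant = np.sign(discovery.z) == np.sign(replication.z)
    return {
        "replicated": bool(replication.p < threshold and concordant),
        "untested": False, "concordant": bool(concordant),
        "z": replication.z, "p": replication.p,
    }


def _key(r: AssociationResult):
    return (r.aptamer, r.gene, r.trait, r.population, r.strategy)


def triage_associations(assocs: list[AssociationResult],
                        colocs: list[ColocResult],
                        replications: list[AssociationResult],
                        alpha: float = 0.05):
    """Join discoveries with colocalization and replication into verdicts.

    ``assocs`` must already carry discovery Bonferroni flags.  The
    replication Bonferroni threshold is alpha / n over the replication
    test set of each strategy.  Returns (records, summary DataFrame of
    stage counts per population x strategy, headline DataFrame with one
    row per distinct (aptamer, trait) pair at the lowest discovery p).
    """
    coloc_by_key: dict[tuple, float] = {}
    for c in colocs:
        k = (c.aptamer, c.gene, c.trait)
        coloc_by_key[k] = max(coloc_by_key.get(k, 0.0), c.p4)
    repl_by_key = {_key(r): r for r in replications}
    repl_thresholds: dict[str, float] = {}
    for strat in {r.strategy for r in replications}:
        n = sum(1 for r in replications if r.strategy == strat)
        repl_thresholds[strat] = alpha / n

    records: list[TriageRecord] = []
    for a in assocs:
        ck = (a.aptamer, a.gene, a.trait)
        max_p4 = coloc_by_key.get(ck)
        coloc_missing = a.bonferroni and max_p4 is None
        colocalized = bool(max_p4 is not None and max_p4 > 0.5)
        if coloc_missing:
            logger.info("coloc missing for discovery %s/%s vs %s", a.aptamer, a.gene, a.trait)
        rep_info = {"replicated": False, "untested": True, "concordant": None,
                    "z": None, "p": None}
        if a.bonferroni and colocalized:
            rep = repl_by_key.get(_key(a))
            thr = repl_thresholds.get(a.strategy, alpha)
            rep_info = replication_test(a, rep, thr)
        if not a.bonferroni:
            verdict = "not_significant"
        elif not colocalized:
            verdict = "discovered"
        elif not rep_info["replicated"]:
            verdict = "discovered+colocalized"
        else:
            verdict = "discovered+colocalized+replicated"
        records.append(TriageRecord(
            aptamer=a.aptamer, gene=a.gene, trait=a.trait,
            population=a.population, strategy=a.strategy,
            discovery_z=a.z, discovery_p=a.p, bonferroni=a.bonferroni,
            max_p4=max_p4, colocalized=colocalized,
            replication_z=rep_info["z"], replication_p=rep_info["p"],
            replicated=rep_info["replicated"],
            direction_concordant=rep_info["concordant"],
            verdict=verdict, coloc_missing=coloc_missing,
            replication_untested=rep_info["untested"],
        ))

    rows = []
    for (pop, strat), grp in _group_records(records):
        n_a = sum(r.bonferroni for r in grp)
        n_b = sum(r.bonferroni and r.colocalized for r in grp)
        n_c = sum(r.verdict == "discovered+colocalized+replicated" for r in grp)
        rows.append({"population": pop, "strategy": strat,
                     "n_discovered": n_a, "n_colocalized": n_b, "n_replicated": n_c})
    summary = pd.DataFrame(rows)

    headline = _headline_table(records)
    return records, summary, headline


def _group_records(records):
    keys = sorted({(r.population, r.strategy) for r in records})
    for k in keys:
        yield k, [r for r in records if (r.population, r.strategy) == k]


def _headline_table(records: list[TriageRecord]) -> pd.DataFrame:
    """One row per distinct (aptamer, trait): the lowest discovery p among
    Bonferroni-significant records."""
    best: dict[tuple, TriageRecord] = {}
    for r in records:
        if not r.bonferroni:
            continue
        k = (r.aptamer, r.trait)
        if k not in best or r.discovery_p < best[k].discovery_p:
            best[k] = r
    return pd.DataFrame([{
        "aptamer": r.aptamer, "gene": r.gene, "trait": r.trait,
        "population": r.population, "strategy": r.strategy,
        "discovery_z": r.discovery_z, "discovery_p": r.discovery_p,
        "replication_z": r.replication_z, "replication_p": r.replication_p,
        "coloc_p4": r.max_p4, "verdict": r.verdict,
    } for r in best.values()])


def records_to_frame(records: list[TriageRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "aptamer": r.aptamer, "gene": r.gene, "trait": r.trait,
        "population": r.population, "strategy": r.strategy,
        "discovery_z": r.discovery_z, "discovery_p": r.discovery_p,
        "bonferroni": r.bonferroni, "max_p4": r.max_p4,
        "colocalized": r.colocalized, "replication_z": r.replication_z,
        "replication_p": r.replication_p, "replicated": r.replicated,
        "verdict": r.verdict,
    } for r in records])
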