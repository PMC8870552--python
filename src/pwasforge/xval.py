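"""External-cohort prediction and model/population comparison analyses.

Predicted abundance in a test cohort is the weighted dosage sum over model
variants harmonized by chrom:pos:ref:alt (allele-swapped matches flip the
weight sign).  Accuracy is the Spearman correlation between predicted and
observed abundance.  Paired model-set comparisons use the Wilcoxon
signed-rank test on the intersection of predicted proteins; the allele
frequency differentiation analysis contrasts mean model F_ST between
proteins with large and small cross-population performance differences
(Mann-Whitney rank-sum).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .enet import PredictionModel
from .genio import GenotypeMatrix, fst_hudson_mean

logger = logging.getLogger("pwasforge")


def predict_external(model: PredictionModel, g: GenotypeMatrix,
                     maf_min: float = 0.01) -> np.ndarray | None:
    """Predicted abundance for every sample of a test cohort.

    Model variants are matched by chrom:pos with either allele orientation;
    unmatched variants contribute 0.  The prediction is emitted only when
    at least one matched variant is polymorphic (MAF > maf_min) in the
    test cohort.
    """
    v = g.variants
    key_direct = {}
    for j, row in enumerate(v.itertuples(index=False)):
        key_direct[(str(row.chrom), int(row.pos), row.ref, row.alt)] = j
    maf = g.maf("ALL")
    pred = np.zeros(g.n_samples)
    n_used = 0
    for w in model.weights.itertuples(index=False):
        j = key_direct.get((str(w.chrom), int(w.pos), w.ref_allele, w.eff_allele))
        flip = False
        if j is None:
            j = key_direct.get((str(w.chrom), int(w.pos), w.eff_allele, w.ref_allele))
            flip = True
        if j is None:
            logger.debug("model variant %s unmatched in test cohort", w.variant_id)
            continue
        if maf[j] <= maf_min:
            continue
        dosage = g.dosages[:, j]
        pred += (-w.weight if flip else w.weight) * dosage
        n_used += 1
    if n_used == 0:
        logger.info("model %s: no matched polymorphic variant in test cohort", model.aptamer)
        return None
    return pred


def evaluate_prediction(predicted: np.ndarray, observed: np.ndarray):
    """Spearman rho (average ranks) and two-sided t-approximation p.

    A constant predicted vector gives (nan, nan): rho is undefined.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size != observed.size:
        raise ValueError("predicted and observed must align")
    if predicted.size < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        return float("nan"), float("nan")
    n = predicted.size
    rho = float(stats.spearmanr(predicted, observed).statistic)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(2 * stats.t.sf(abs(t), df=n - 2))


def compare_paired(rho_a: np.ndarray, rho_b: np.ndarray,
                   alternative: str = "two-sided") -> float:
    """Wilcoxon signed-rank p for paired performance vectors.

    Zero differences are dropped (Wilcoxon's rule); the null is exact by
    enumeration for up to 12 nonzero pairs and a continuity-corrected
    normal approximation beyond.
    """
    a = np.asarray(rho_a, dtype=float)
    b = np.asarray(rho_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size < 3:
        raise ValueError("need at least 3 nonzero paired differences")
    method = "exact" if d.size <= 12 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                         alternative=alternative, method=method)
    return float(res.pvalue)


def rank_sum_test(x: np.ndarray, y: np.ndarray,
                  alternative: str = "two-sided") -> float:
    """Two-sample Mann-Whitney rank-sum p; exact for small tie-free groups."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


def build_performance_table(models: list[PredictionModel], test_g: GenotypeMatrix,
                            observed: pd.DataFrame, train_g: GenotypeMatrix,
                            test_cohort: str = "external") -> pd.DataFrame:
    """Evaluate each model in a test cohort and attach its mean model F_ST.

    ``observed`` is the adjusted wide abundance table of the test cohort
    (samples x aptamers).  Model F_ST is the ratio-of-averages Hudson
    estimate over the model's SNPs between the training population and the
    test cohort.
    """
    rows = []
    test_freq_by_key = {}
    v = test_g.variants
    for j, r in enumerate(v.itertuples(index=False)):
        test_freq_by_key[(str(r.chrom), int(r.pos))] = test_g.alt_frequency("ALL")[j]
    train_freq = {}
    for j, r in enumerate(train_g.variants.itertuples(index=False)):
        train_freq[(str(r.chrom), int(r.pos))] = None  # filled below per population
    for m in models:
        if m.aptamer not in observed.columns:
            continue
        pred = predict_external(m, test_g)
        if pred is None:
            continue
        rho, p = evaluate_prediction(pred, observed[m.aptamer].to_numpy())
        mask = train_g.sample_mask(m.population)
        p_train = train_g.dosages[mask].mean(axis=0) / 2.0
        keys = {(str(r.chrom), int(r.pos)): k
                for k, r in enumerate(train_g.variants.itertuples(index=False))}
        p1, p2 = [], []
        for w in m.weights.itertuples(index=False):
            key = (str(w.chrom), int(w.pos))
            if key in keys and key in test_freq_by_key:
                p1.append(p_train[keys[key]])
                p2.append(test_freq_by_key[key])
        fst = fst_hudson_mean(np.array(p1), np.array(p2),
                              int(mask.sum()), test_g.n_samples) if p1 else float("nan")
        rows.append({
            "aptamer": m.aptamer, "train_population": m.population,
            "strategy": m.strategy, "test_cohort": test_cohort,
            "rho": rho, "p": p, "n": test_g.n_samples, "mean_fst": fst,
        })
    return pd.DataFrame(rows)


def fst_performance_groups(perf: pd.DataFrame, thresholds=(0.1, 0.2),
                           pop_a: str | None = None, pop_b: str | None = None,
                           strategy: str | None = None) -> pd.DataFrame:
    """Rank-sum comparison of model F_ST differences between |delta rho| groups.

    Per protein, delta rho is the performance difference between two
    training populations on the same test cohort, and the F_ST metric is
    the difference in mean model F_ST (each model's SNPs vs the test
    cohort) between the same two training populations.  At each threshold
    t the metric for proteins with |delta rho| > t is compared with the
    group at |delta rho| <= t: performance gaps driven by allele-frequency
    differentiation show up as larger F_ST gaps in the large-delta group.
    """
    df = perf
    if strategy is not None:
        df = df[df["strategy"] == strategy]
    pops = sorted(df["train_population"].unique())
    if pop_a is None or pop_b is None:
        if len(pops) != 2:
            raise ValueError("specify pop_a and pop_b when more than two populations")
        pop_a, pop_b = pops
    a = df[df["train_population"] == pop_a].set_index("aptamer")
    b = df[df["train_population"] == pop_b].set_index("aptamer")
    shared = a.index.intersection(b.index)
    delta = (a.loc[shared, "rho"] - b.loc[shared, "rho"]).abs()
    mean_fst = (a.loc[shared, "mean_fst"] - b.loc[shared, "mean_fst"]).abs()
    out = []
    for t in thresholds:
        large = mean_fst[delta > t].dropna()
        small = mean_fst[delta <= t].dropna()
        if large.empty or small.empty:
            logger.warning("threshold t=%s skipped: empty group", t)
            continue
        p = rank_sum_test(large.to_numpy(), small.to_numpy())
        out.append({
            "t": t, "n_large": large.size, "n_small": small.size,
            "mean_fst_large": large.mean(), "mean_fst_small": small.mean(),
            "p": p,
        })
    return pd.DataFrame(out)
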