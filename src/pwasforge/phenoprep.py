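"""Protein-abundance preparation.

The training-cohort chain is: natural log per timepoint -> residualize on
age and sex per timepoint -> mean across available timepoints (a sample
measured at only one timepoint keeps that value as its mean) -> rank
inverse normalization -> residualize on the leading genotypic principal
components.  An external cohort convention with a different covariate list
is expressed through the same operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("pwasforge")


@dataclass
class AbundanceMatrix:
    """Aptamer abundances, raw (long) or adjusted (wide samples x aptamers)."""

    values: pd.DataFrame
    stage: str  # "raw_timepoint" | "adjusted"
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.stage not in ("raw_timepoint", "adjusted"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "adjusted" and self.values.isna().any().any():
            raise ValueError("adjusted abundance matrix must have no missing values")


def rank_inverse_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^-1((rank - 0.5)/n).

    Ties receive average ranks; at least 3 finite values and at least two
    distinct values are required.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 3 finite values")
    if np.ptp(x) == 0:
        raise ValueError("all values identical; ranks degenerate")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / x.size)


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of y on [1, covariates].

    Collinear covariate columns are dropped (with a warning) so the fit is
    well-defined; residuals are orthogonal to every retained column.
    """
    y = np.asarray(y, dtype=float)
    if covariates is None or np.size(covariates) == 0:
        return y - y.mean()
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != y.size:
        C = C.T
    X = np.column_stack([np.ones(y.size), C])
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))
    if not keep.all():
        logger.warning("residualize: dropped %d collinear covariate column(s)",
                       int((~keep).sum()))
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def prepare_abundance(raw: pd.DataFrame, covariates: pd.DataFrame,
                      pcs: np.ndarray | None = None, n_pcs: int = 10,
                      pc_sample_ids: np.ndarray | None = None,
                      covariate_columns: tuple[str, ...] = ("age", "sex"),
                      ) -> AbundanceMatrix:
    """Run the full preparation chain on a raw long-format table.

    Parameters
    ----------
    raw : long DataFrame with columns sample, aptamer, timepoint, value (>0).
    covariates : DataFrame with columns sample + ``covariate_columns``.
    pcs : per-sample genotypic PC scores aligned to ``pc_sample_ids``
        (or to covariates order when ids are omitted).
    n_pcs : number of leading PCs to residualize on (default 10).
    """
    bad = raw["value"] <= 0
    if bad.any():
        row = raw.loc[bad].iloc[0]
        raise ValueError(
            f"nonpositive raw abundance for sample {row['sample']} "
            f"aptamer {row['aptamer']}"
        )
    cov = covariates.set_index("sample")
    work = raw.copy()
    work["log_value"] = np.log(work["value"])

    # per-timepoint adjustment for the measurement covariates
    adjusted_parts = []
    for (aptamer, timepoint), grp in work.groupby(["aptamer", "timepoint"], sort=True):
        C = cov.loc[grp["sample"], list(covariate_columns)].to_numpy()
        resid = residualize(grp["log_value"].to_numpy(), C)
        adjusted_parts.append(pd.DataFrame({
            "sample": grp["sample"].to_numpy(), "aptamer": aptamer, "resid": resid,
        }))
    adj = pd.concat(adjusted_parts, ignore_index=True)

    # mean across available timepoints (single measurement = its own mean)
    mean_tbl = adj.groupby(["sample", "aptamer"])["resid"].mean().unstack("aptamer")
    mean_tbl = mean_tbl.reindex(index=cov.index)
    if mean_tbl.isna().any().any():
        raise ValueError("samples missing at every timepoint for some aptamer")

    if pcs is not None and n_pcs > 0:
        pcs = np.asarray(pcs, dtype=float)
        if n_pcs > pcs.shape[1]:
            raise ValueError(f"n_pcs={n_pcs} exceeds available components {pcs.shape[1]}")
        if pc_sample_ids is not None:
            pc_df = pd.DataFrame(pcs[:, :n_pcs], index=pd.Index(pc_sample_ids))
            pc_mat = pc_df.reindex(mean_tbl.index).to_numpy()
        else:
            pc_mat = pcs[:, :n_pcs]
    else:
        pc_mat = None

    out = {}
    for aptamer in mean_tbl.columns:
        v = rank_inverse_normalize(mean_tbl[aptamer].to_numpy())
        if pc_mat is not None:
            v = residualize(v, pc_mat)
        out[aptamer] = v
    wide = pd.DataFrame(out, index=mean_tbl.index)
    wide.index.name = "sample"
    return AbundanceMatrix(values=wide, stage="adjusted", covariates=covariates)
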