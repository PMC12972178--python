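"""Per-CpG association testing with signed z-scores.

Each CpG's beta values are regressed on a numeric predictor (plus optional
covariates) by ordinary least squares.  The slope's two-sided p-value is
mapped to a signed z-score through the probit,

    z = sign(t) * Phi^{-1}(1 - p / 2),

so |z| > 2 corresponds to p < 0.0455 and the sign carries the direction of
the association.  |z| is capped at 38, where double-precision p-values
underflow.  CpGs with missing cells are tested on their complete cases;
CpGs with too few complete cases are flagged untestable (NaN statistics)
rather than dropped, so the output always has one row per input CpG.

The same engine drives clock pre-selection (association with transformed
age) and the downstream association study of ensemble age acceleration.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .io import BetaMatrix

logger = logging.getLogger(__name__)

Z_CAP = 38.0
#: Extra complete cases required beyond the number of regression parameters.
MIN_EXTRA_CASES = 3


def signed_z(p, sign) -> np.ndarray:
    """Signed probit map of a two-sided p-value, capped at +-38."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(p / 2.0)
    z = np.minimum(z, Z_CAP)
    return np.asarray(np.sign(sign)) * z


def _slope_stats(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, ...]:
    """OLS of each column of Y on X; returns (estimate, t, p) for X's second
    column (the predictor of interest).  X must be full rank."""
    n, k = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (X.T @ Y)                       # k x C
    resid = Y - X @ B
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    est = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return est, t, p


def ewas(m: BetaMatrix, predictor: Sequence[float] | pd.Series,
         covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Epigenome-wide association of methylation with a numeric predictor.

    Parameters
    ----------
    m:
        Beta matrix (CpG x sample).
    predictor:
        Per-sample numeric values, aligned to ``m.sample_ids`` (a Series is
        re-indexed by sample id; a plain sequence is taken positionally).
    covariates:
        Optional per-sample numeric DataFrame of adjustment covariates.

    Returns
    -------
    DataFrame with columns ``cpg_id, estimate, t, p, z, n_complete,
    untestable``, one row per CpG in input order.
    """
    samples = m.sample_ids
    if isinstance(predictor, pd.Series):
        x = predictor.reindex(samples).to_numpy(dtype=float)
    else:
        x = np.asarray(predictor, dtype=float)
    if len(x) != len(samples):
        raise DesignError("predictor length does not match sample count")
    if np.any(np.isnan(x)):
        raise DesignError("predictor contains missing values")
    if np.ptp(x) == 0:
        raise DesignError("predictor is constant")
    cols = [np.ones_like(x), x]
    if covariates is not None:
        C = (covariates.reindex(samples)
             if isinstance(covariates, pd.DataFrame) else
             pd.DataFrame(np.asarray(covariates, dtype=float)))
        for name in C.columns:
            cols.append(C[name].to_numpy(dtype=float))
    X = np.column_stack(cols)
    k = X.shape[1]
    min_n = k + MIN_EXTRA_CASES

    Y = m.values.to_numpy(dtype=float)            # CpG x sample
    cpgs = m.cpg_ids
    nC = len(cpgs)
    est = np.full(nC, np.nan)
    tstat = np.full(nC, np.nan)
    pval = np.full(nC, np.nan)
    ncomp = np.zeros(nC, dtype=int)
    untest = np.zeros(nC, dtype=bool)

    missing_any = np.isnan(Y).any(axis=1)
    complete_idx = np.flatnonzero(~missing_any)
    if len(X) < min_n:
        untest[:] = True
    else:
        if complete_idx.size:
            e, t, p = _slope_stats(X, Y[complete_idx].T)
            est[complete_idx], tstat[complete_idx], pval[complete_idx] = e, t, p
            ncomp[complete_idx] = len(X)
        for i in np.flatnonzero(missing_any):
            keep = ~np.isnan(Y[i])
            ncomp[i] = int(keep.sum())
            if ncomp[i] < min_n or np.ptp(x[keep]) == 0:
                untest[i] = True
                continue
            e, t, p = _slope_stats(X[keep], Y[i, keep][:, None])
            est[i], tstat[i], pval[i] = e[0], t[0], p[0]

    z = np.where(untest, np.nan, signed_z(pval, np.where(tstat == 0, 0, tstat)))
    return pd.DataFrame({
        "cpg_id": cpgs, "estimate": est, "t": tstat, "p": pval, "z": z,
        "n_complete": ncomp, "untestable": untest,
    })


def preselect(rows: pd.DataFrame, z_thresh: float = 2.0,
              max_k: int | None = None) -> list[str]:
    """CpGs with |z| > ``z_thresh``, sorted by |z| descending (ties broken
    by cpg_id), truncated to ``max_k``.  An empty result is allowed."""
    ok = rows[~rows["untestable"].astype(bool)].copy()
    ok = ok[ok["z"].abs() > z_thresh]
    ok["_absz"] = ok["z"].abs()
    ok = ok.sort_values(["_absz", "cpg_id"], ascending=[False, True],
                        kind="mergesort")
    ids = ok["cpg_id"].tolist()
    if max_k is not None:
        ids = ids[:max_k]
    return ids


def acceleration_ewas(m: BetaMatrix, accel: pd.Series | Sequence[float],
                      covariates: pd.DataFrame | None = None,
                      p_thresh: float = 1e-5) -> pd.DataFrame:
    """Association of methylation with epigenetic age acceleration.

    Same engine as :func:`ewas` with the acceleration as predictor; adds a
    ``significant`` column at the reporting threshold (default p < 1e-5).
    """
    out = ewas(m, accel, covariates)
    out["significant"] = (out["p"] < p_thresh) & ~out["untestable"]
    return out


def stouffer_combine(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-experiment signed z-scores across EWAS tables by
    Stouffer's method (equal weights), for pooled pre-selection.

    Returns a table with cpg_id, z (combined), n_experiments.  CpGs
    untestable in an experiment simply do not contribute there.
    """
    acc: dict[str, list[float]] = {}
    for tab in tables:
        ok = tab[~tab["untestable"].astype(bool)]
        for cpg, z in zip(ok["cpg_id"], ok["z"]):
            acc.setdefault(cpg, []).append(float(z))
    rows = [(cpg, sum(zs) / np.sqrt(len(zs)), len(zs))
            for cpg, zs in acc.items()]
    out = pd.DataFrame(rows, columns=["cpg_id", "z", "n_experiments"])
    out["z"] = out["z"].clip(-Z_CAP, Z_CAP)
    out["untestable"] = False
    return out.sort_values("cpg_id", kind="mergesort").reset_index(drop=True)
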