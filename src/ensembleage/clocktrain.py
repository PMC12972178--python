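"""Training of penalized-regression epigenetic clocks.

A clock regresses transformed age on CpG beta values with a ridge, lasso or
elastic-net penalty.  The regularization strength is chosen on a 100-point
log-spaced path by 10-fold cross-validation minimizing mean squared error
(a one-standard-error rule is available via ``cv_rule="1se"``); folds are
seeded and stratified by tissue.  Predictors are standardized internally
and coefficients are returned on the raw beta scale, so a saved clock is a
plain linear model ``transform(age) = intercept + sum_j w_j * beta_j``.

Libraries of clocks are produced by mapping :func:`train_clock` over a grid
of recipes (penalty family x CpG pre-selection strategy x transform x
seed); individual recipe failures are logged and skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet

from . import agetransform as at
from .errors import (LibraryError, RecipeError, SplitError, TrainingError,
                     ValidationError)
from .ewas import ewas, preselect
from .io import BetaMatrix, ClockModel, SampleSheet, align_to_clock

logger = logging.getLogger(__name__)

PENALTIES = ("ridge", "lasso", "elasticnet")
STRATEGIES = ("ewas", "random", "region_file", "all")

N_ALPHAS = 100
N_FOLDS = 10
MIN_TRAIN = 20
#: Predicted ages below this are floored (years); inverse transforms are
#: total but a clock can extrapolate below zero on unusual samples.
AGE_FLOOR = 1e-3


@dataclass(frozen=True)
class ClockRecipe:
    """One point of the clock-library grid.

    ``mixing`` is the lasso fraction of the elastic-net penalty (0 = ridge,
    1 = lasso); it is forced to the consistent value for the pure
    penalties.
    """

    penalty: str = "elasticnet"
    mixing: float = 0.5
    preselect_strategy: str = "ewas"
    preselect_params: tuple = ()          # mapping as sorted (key, value) pairs
    transform: at.AgeTransformSpec = field(default_factory=at.AgeTransformSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penalty not in PENALTIES:
            raise ValidationError(f"unknown penalty {self.penalty!r}")
        if self.preselect_strategy not in STRATEGIES:
            raise ValidationError(
                f"unknown pre-selection strategy {self.preselect_strategy!r}")
        if self.penalty == "ridge" and self.mixing != 0.0:
            object.__setattr__(self, "mixing", 0.0)
        if self.penalty == "lasso" and self.mixing != 1.0:
            object.__setattr__(self, "mixing", 1.0)
        if not 0.0 <= self.mixing <= 1.0:
            raise ValidationError("mixing must be in [0, 1]")
        if isinstance(self.preselect_params, dict):
            object.__setattr__(self, "preselect_params",
                               tuple(sorted(self.preselect_params.items())))

    @property
    def params(self) -> dict[str, Any]:
        return dict(self.preselect_params)


def split_samples(sheet: SampleSheet, train_frac: float = 0.7,
                  seed: int = 0) -> tuple[list[str], list[str]]:
    """Deterministic train/test split of samples, stratified by tissue.

    Each tissue contributes ``round(n * train_frac)`` training samples;
    tissues with fewer than 2 samples go entirely to training with a
    warning.
    """
    if not 0.0 < train_frac < 1.0:
        raise SplitError("train_frac must be in (0, 1)")
    if len(sheet.sample_ids) < 10:
        raise SplitError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for tissue in sorted(sheet.data["tissue"].unique()):
        ids = sorted(sheet.data.index[sheet.data["tissue"] == tissue])
        if len(ids) < 2:
            logger.warning("tissue %r has < 2 samples; assigned to train",
                           tissue)
            train.extend(ids)
            continue
        perm = rng.permutation(len(ids))
        n_train = int(round(len(ids) * train_frac))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return sorted(train), sorted(test)


def _cv_folds(tissues: Sequence[str], n_folds: int, seed: int,
              ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded fold assignment, stratified by tissue (round-robin within
    each tissue after a shuffle)."""
    n = len(tissues)
    n_folds = min(n_folds, n)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    order = []
    for tissue in sorted(set(tissues)):
        idx = [i for i, t in enumerate(tissues) if t == tissue]
        rng.shuffle(idx)
        order.extend(idx)
    for pos, i in enumerate(order):
        fold_of[i] = pos % n_folds
    folds = []
    for f in range(n_folds):
        va = np.flatnonzero(fold_of == f)
        tr = np.flatnonzero(fold_of != f)
        folds.append((tr, va))
    return folds


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _ridge_fit(Xs: np.ndarray, y: np.ndarray, alpha: float,
               ) -> tuple[float, np.ndarray]:
    """Ridge solution on standardized predictors via SVD (coefficients on
    the standardized scale, intercept = mean of y)."""
    ym = y.mean()
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    d = s / (s ** 2 + alpha)
    w = Vt.T @ (d * (U.T @ (y - ym)))
    return float(ym), w


def _ridge_cv_mse(X: np.ndarray, y: np.ndarray, alphas: np.ndarray,
                  folds: list) -> np.ndarray:
    """Per-alpha CV mean squared error for ridge; SVD once per fold makes
    the full path cheap."""
    sse = np.zeros(len(alphas))
    n_total = 0
    for tr, va in folds:
        Xtr, ytr = X[tr], y[tr]
        Xs, mu, sd = _standardize(Xtr)
        ym = ytr.mean()
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        Uty = U.T @ (ytr - ym)
        M = ((X[va] - mu) / sd) @ Vt.T
        n_total += len(va)
        for ai, a in enumerate(alphas):
            pred = ym + M @ ((s / (s ** 2 + a)) * Uty)
            sse[ai] += float(((y[va] - pred) ** 2).sum())
    return sse / n_total


def _enet_alpha_grid(Xs: np.ndarray, y: np.ndarray, l1_ratio: float,
                     n_alphas: int = N_ALPHAS) -> np.ndarray:
    """Log-spaced path from the smallest alpha that zeroes every lasso
    coefficient down to alpha_max * 1e-4, the coordinate-descent standard."""
    n = len(y)
    yc = y - y.mean()
    alpha_max = np.abs(Xs.T @ yc).max() / (n * max(l1_ratio, 0.05))
    alpha_max = max(alpha_max, 1e-8)
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max * 1e-4),
                       n_alphas)


def _select_alpha(alphas: np.ndarray, mse: np.ndarray, se: np.ndarray | None,
                  cv_rule: str) -> float:
    best = int(np.argmin(mse))
    if cv_rule == "min" or se is None:
        return float(alphas[best])
    # 1-SE rule: most-penalized alpha whose CV MSE is within one standard
    # error of the minimum.  Alphas are sorted descending in penalty.
    thresh = mse[best] + se[best]
    for i in range(len(alphas)):
        if mse[i] <= thresh:
            return float(alphas[i])
    return float(alphas[best])


def _preselect_cpgs(m: BetaMatrix, y: np.ndarray, train_ids: list[str],
                    recipe: ClockRecipe) -> list[str]:
    params = recipe.params
    strategy = recipe.preselect_strategy
    if strategy == "all":
        return m.cpg_ids
    if strategy == "random":
        k = int(params.get("k", 500))
        rng = np.random.default_rng(recipe.seed)
        cpgs = sorted(m.cpg_ids)
        k = min(k, len(cpgs))
        return [cpgs[i] for i in rng.choice(len(cpgs), size=k, replace=False)]
    if strategy == "region_file":
        ids = params.get("cpg_ids")
        if ids is None:
            path = params.get("path")
            if path is None:
                raise RecipeError("region_file strategy needs cpg_ids or path")
            ids = [ln.strip() for ln in
                   Path(path).read_text(encoding="utf-8").splitlines()
                   if ln.strip()]
        present = set(m.cpg_ids)
        return [c for c in ids if c in present]
    # "ewas": association of beta with the (transformed-age) target on the
    # training samples only, thresholded on |z|.
    sub = BetaMatrix(m.values[train_ids])
    tab = ewas(sub, pd.Series(y, index=train_ids))
    return preselect(tab, z_thresh=float(params.get("z_thresh", 2.0)),
                     max_k=params.get("max_k"))


def train_clock(m: BetaMatrix, sheet: SampleSheet, recipe: ClockRecipe,
                train_ids: Sequence[str], *,
                clock_id: str | None = None,
                target: pd.Series | None = None,
                refit_all: bool = False,
                cv_rule: str = "min",
                n_folds: int = N_FOLDS) -> ClockModel:
    """Train one clock from a recipe.

    ``target`` optionally overrides chronological age with per-sample ages
    in years (used when distilling calibrated ages); the recipe's transform
    is applied to it the same way.  ``refit_all`` refits at the selected
    regularization strength on every sample in the sheet after
    cross-validated selection on ``train_ids``.
    """
    train_ids = list(train_ids)
    if len(train_ids) < MIN_TRAIN:
        raise TrainingError(
            f"need >= {MIN_TRAIN} training samples, got {len(train_ids)}")
    ages = (target.reindex(train_ids) if target is not None
            else sheet.data.loc[train_ids, "age"]).astype(float)
    if ages.isna().any():
        raise TrainingError("missing target age for some training samples")
    y = np.asarray(at.transform(ages.to_numpy(), recipe.transform))

    cpgs = _preselect_cpgs(m, y, train_ids, recipe)
    if not cpgs:
        raise RecipeError(
            f"pre-selection {recipe.preselect_strategy!r} produced 0 CpGs")

    def build_X(ids: list[str], means: pd.Series | None = None,
                ) -> tuple[np.ndarray, pd.Series]:
        sub = m.values.loc[cpgs, ids].T  # samples x cpgs
        col_means = sub.mean(axis=0, skipna=True) if means is None else means
        col_means = col_means.fillna(0.5)  # CpG unobserved in training
        return sub.fillna(col_means).to_numpy(dtype=float), col_means

    X, train_means = build_X(train_ids)
    tissues = sheet.data.loc[train_ids, "tissue"].tolist()
    folds = _cv_folds(tissues, n_folds, recipe.seed)

    if recipe.penalty == "ridge":
        alphas = np.logspace(4, -4, N_ALPHAS)
        mse = _ridge_cv_mse(X, y, alphas, folds)
        alpha = _select_alpha(alphas, mse, None, cv_rule)
        fit_ids, fit_y = train_ids, y
        if refit_all:
            fit_ids = sheet.sample_ids
            fit_y = _target_for(sheet, fit_ids, target, recipe)
        Xf, train_means = build_X(fit_ids)
        Xs, mu, sd = _standardize(Xf)
        b0_std, w_std = _ridge_fit(Xs, fit_y, alpha)
    else:
        l1_ratio = recipe.mixing
        Xs0, _, _ = _standardize(X)
        alphas = _enet_alpha_grid(Xs0, y, l1_ratio)
        mse_folds = np.zeros((len(folds), len(alphas)))
        for fi, (tr, va) in enumerate(folds):
            Xs, mu, sd = _standardize(X[tr])
            model = ElasticNet(l1_ratio=l1_ratio, fit_intercept=True,
                               max_iter=5000, tol=1e-5, warm_start=True)
            Xva = (X[va] - mu) / sd
            for ai, a in enumerate(alphas):
                model.set_params(alpha=a)
                model.fit(Xs, y[tr])
                pred = model.predict(Xva)
                mse_folds[fi, ai] = float(((y[va] - pred) ** 2).mean())
        mse = mse_folds.mean(axis=0)
        se = mse_folds.std(axis=0, ddof=1) / np.sqrt(len(folds))
        alpha = _select_alpha(alphas, mse, se, cv_rule)
        fit_ids, fit_y = train_ids, y
        if refit_all:
            fit_ids = sheet.sample_ids
            fit_y = _target_for(sheet, fit_ids, target, recipe)
        Xf, train_means = build_X(fit_ids)
        Xs, mu, sd = _standardize(Xf)
        final = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, fit_intercept=True,
                           max_iter=50000, tol=1e-7)
        final.fit(Xs, fit_y)
        b0_std, w_std = float(final.intercept_), final.coef_

    # Back-transform standardized coefficients to the beta scale.
    w_beta = w_std / sd
    intercept = b0_std - float(w_beta @ mu)
    nz = np.flatnonzero(w_beta)
    weights = {cpgs[i]: float(w_beta[i]) for i in nz}
    means = {cpgs[i]: float(train_means.iloc[i]) for i in nz}

    provenance = {
        "penalty": recipe.penalty, "mixing": recipe.mixing,
        "preselect_strategy": recipe.preselect_strategy,
        "preselect_params": recipe.params, "seed": recipe.seed,
        "alpha": float(alpha), "cv_rule": cv_rule,
        "n_preselected": len(cpgs), "n_nonzero": int(len(nz)),
        "n_train": len(fit_ids), "refit_all": bool(refit_all),
    }
    cid = clock_id or (f"clock_{recipe.penalty}_{recipe.preselect_strategy}"
                       f"_s{recipe.seed}")
    return ClockModel(clock_id=cid, intercept=intercept, weights=weights,
                      transform=recipe.transform, train_means=means,
                      recipe=provenance)


def _target_for(sheet: SampleSheet, ids: list[str],
                target: pd.Series | None, recipe: ClockRecipe) -> np.ndarray:
    ages = (target.reindex(ids) if target is not None
            else sheet.data.loc[ids, "age"]).astype(float)
    return np.asarray(at.transform(ages.to_numpy(), recipe.transform))


def predict_age(m: BetaMatrix, c: ClockModel,
                max_missing_fraction: float = 0.5) -> pd.Series:
    """Predict age in years for every sample of ``m``.

    The matrix is aligned to the clock's CpGs (absent probes imputed with
    training means), the linear predictor is evaluated and the clock's age
    transform inverted.  Predictions below the floor are clipped to
    0.001 years with a warning.
    """
    if not c.weights:
        val = at.inverse(c.intercept, c.transform)
        val = max(val, AGE_FLOOR)
        return pd.Series(val, index=m.sample_ids, dtype=float)
    aligned = align_to_clock(m, c, max_missing_fraction)
    w = np.array([c.weights[g] for g in aligned.cpg_ids])
    lin = c.intercept + w @ aligned.values.to_numpy(dtype=float)
    ages = np.asarray(at.inverse(lin, c.transform), dtype=float)
    n_floor = int((ages < AGE_FLOOR).sum())
    if n_floor:
        logger.warning("clock %s: %d predictions below %g y floored",
                       c.clock_id, n_floor, AGE_FLOOR)
        ages = np.maximum(ages, AGE_FLOOR)
    return pd.Series(ages, index=m.sample_ids, dtype=float)


def train_library(m: BetaMatrix, sheet: SampleSheet,
                  recipes: Sequence[ClockRecipe], train_ids: Sequence[str],
                  test_ids: Sequence[str] | None = None,
                  **train_kwargs) -> list[ClockModel]:
    """Map :func:`train_clock` over a recipe grid.

    Individual failures are logged and skipped; if every recipe fails a
    :class:`LibraryError` is raised.  When ``test_ids`` is given each
    clock's held-out Pearson correlation with chronological age is recorded
    in its recipe provenance.
    """
    clocks: list[ClockModel] = []
    for i, recipe in enumerate(recipes):
        cid = (f"clock{i:03d}_{recipe.penalty}_{recipe.preselect_strategy}"
               f"_s{recipe.seed}")
        try:
            c = train_clock(m, sheet, recipe, train_ids, clock_id=cid,
                            **train_kwargs)
        except Exception as e:  # noqa: BLE001 - grid robustness by design
            logger.warning("recipe %d (%s) failed: %s", i, cid, e)
            continue
        if test_ids:
            pred = predict_age(BetaMatrix(m.values[list(test_ids)]), c)
            truth = sheet.data.loc[list(test_ids), "age"].astype(float)
            if pred.std() > 0 and truth.std() > 0:
                c.recipe["heldout_r"] = float(np.corrcoef(pred, truth)[0, 1])
            else:
                c.recipe["heldout_r"] = float("nan")
        clocks.append(c)
    if not clocks:
        raise LibraryError("every recipe in the library grid failed")
    return clocks
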