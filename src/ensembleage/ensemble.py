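"""Ensemble construction and the dynamic / static age estimators.

``select_ensemble`` ranks benchmarked clocks (weighted correct-response
score, then median direction-aligned z, then correct ratio) and keeps the
top K, guarding that both stress- and rejuvenation-detecting clocks are
represented when any exist.

For a new experiment, ``dynamic_predict`` re-evaluates every ensemble
clock on that stratum, keeps the responsive ones (|z| > 2), and reports
the per-sample median predicted age across responsive clocks together
with the median of their z-scores (the ensemble z).  The dynamic
estimator therefore adapts its clock composition to each dataset.  When
no clock is responsive the median over the whole ensemble is returned
and flagged as a fallback.

``calibrate`` turns dynamic results into per-sample calibrated ages —
either the dynamic medians themselves, or the predictions of the single
most responsive clock (maximum direction-aligned z) — and ``train_static``
distills those calibrated ages into one elastic-net clock trained on
treated animals only, yielding a fixed, perturbation-sensitive predictor
for screening future data without stratum labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import clocktrain as ct
from .benchmark import (ClockScore, StratumResponse, Z_THRESH,
                        age_acceleration, stratum_z)
from .errors import CalibrationError, SelectionError, TrainingError
from .io import BetaMatrix, ClockModel, SampleSheet

logger = logging.getLogger(__name__)

DEFAULT_K = 40


@dataclass
class EnsembleSpec:
    """Selected clock identifiers in rank order plus selection metadata."""

    clock_ids: list[str]
    selection_metrics: dict[str, ClockScore] = field(default_factory=dict)
    split_seed: int = 0
    z_thresh: float = Z_THRESH

    def __post_init__(self) -> None:
        if len(set(self.clock_ids)) != len(self.clock_ids):
            raise SelectionError("duplicate clock ids in ensemble")

    def to_dict(self) -> dict:
        return {
            "clock_ids": list(self.clock_ids),
            "selection_metrics": {k: v.to_dict()
                                  for k, v in self.selection_metrics.items()},
            "split_seed": self.split_seed,
            "z_thresh": self.z_thresh,
        }


@dataclass
class DynamicResult:
    """Dynamic ensemble output for one stratum."""

    stratum_id: str
    ages: pd.Series                       # per-sample median age (years)
    ensemble_z: float
    responsive_clocks: list[str]
    fallback_used: bool
    clock_z: dict[str, float]
    clock_ages: pd.DataFrame              # sample x clock predicted ages


def _rank_key(s: ClockScore) -> tuple:
    return (-s.weighted_correct, -s.median_z_expected, -s.correct_ratio,
            s.clock_id)


def select_ensemble(scores: Sequence[ClockScore], k: int = DEFAULT_K,
                    split_seed: int = 0, z_thresh: float = Z_THRESH,
                    ) -> EnsembleSpec:
    """Take the top-k clocks by benchmark rank.

    Rank order: weighted_correct desc, then median_z_expected, then
    correct_ratio, then clock_id.  If the top-k contains no clock that ever
    detected stress (or rejuvenation) while such clocks exist, the lowest-
    ranked selection is swapped for the best such clock, so the ensemble
    can respond in both directions.
    """
    if len(scores) < k:
        raise SelectionError(f"asked for k={k} clocks, only {len(scores)} "
                             "scored")
    ranked = sorted(scores, key=_rank_key)
    chosen = list(ranked[:k])
    rest = ranked[k:]

    def detects(s: ClockScore, attr: str) -> bool:
        v = getattr(s, attr)
        return bool(np.isfinite(v) and v > 0)

    for attr in ("stress_detection", "rejuvenation_detection"):
        if not any(detects(s, attr) for s in chosen):
            cand = next((s for s in rest if detects(s, attr)), None)
            if cand is not None:
                logger.info("ensemble balance guard: swapping %s in for %s "
                            "(%s)", cand.clock_id, chosen[-1].clock_id, attr)
                chosen[-1] = cand
    return EnsembleSpec(
        clock_ids=[s.clock_id for s in chosen],
        selection_metrics={s.clock_id: s for s in chosen},
        split_seed=split_seed, z_thresh=z_thresh)


def dynamic_predict(m: BetaMatrix, sheet: SampleSheet, stratum_id: str,
                    spec: EnsembleSpec, library: Mapping[str, ClockModel],
                    ) -> DynamicResult:
    """EnsembleAge.Dynamic for one stratum.

    Every ensemble clock predicts ages for the stratum's samples; each
    clock's acceleration contrast gives a signed z.  Responsive clocks
    (|z| > z_thresh) define the dynamic estimate: per-sample median of
    their predicted ages, and the median of their z-scores as the ensemble
    z.  With no responsive clock, medians over the full ensemble are
    returned with ``fallback_used=True``.
    """
    if not spec.clock_ids:
        raise SelectionError("empty ensemble spec")
    sub_ids = list(sheet.stratum_samples(stratum_id).index)
    sub_m = BetaMatrix(m.values[sub_ids])
    clock_ages: dict[str, pd.Series] = {}
    clock_z: dict[str, float] = {}
    for cid in spec.clock_ids:
        clock = library[cid]
        pred = ct.predict_age(sub_m, clock)
        accel = age_acceleration(pred, sheet, stratum_id)
        r = stratum_z(accel, sheet, stratum_id, clock_id=cid,
                      z_thresh=spec.z_thresh)
        clock_ages[cid] = pred
        clock_z[cid] = float("nan") if r.untestable else r.z
    ages_df = pd.DataFrame(clock_ages)       # sample x clock
    zs = pd.Series(clock_z)
    responsive = zs.index[zs.abs() > spec.z_thresh].tolist()
    fallback = not responsive
    use = list(zs.index[zs.notna()]) if fallback else responsive
    if not use:                               # every clock untestable
        use = list(zs.index)
    ens_ages = ages_df[use].median(axis=1)
    ens_z = float(np.nanmedian(zs[use].to_numpy())) if use else float("nan")
    if fallback:
        logger.info("stratum %s: no responsive clock; falling back to "
                    "all-ensemble median", stratum_id)
    return DynamicResult(stratum_id=stratum_id, ages=ens_ages,
                         ensemble_z=ens_z, responsive_clocks=responsive,
                         fallback_used=fallback, clock_z=clock_z,
                         clock_ages=ages_df)


def calibrate(mode: str, results: Mapping[str, DynamicResult],
              sheet: SampleSheet) -> pd.Series:
    """Per-sample calibrated ages from per-stratum dynamic results.

    ``mode="median"`` uses the dynamic (median-of-responsive) ages;
    ``mode="top"`` uses the predictions of the single clock with the
    largest direction-aligned z in each stratum (z for stress, -z for
    rejuvenation), which requires a documented direction.  Samples sharing
    an identical calibrated value are de-duplicated: the first in sample-
    sheet order is kept, later ones are dropped (count logged).
    """
    if mode not in ("median", "top"):
        raise CalibrationError(f"unknown calibration mode {mode!r}")
    pieces: list[pd.Series] = []
    for sid, res in results.items():
        if mode == "median":
            pieces.append(res.ages)
            continue
        direction = sheet.stratum_direction(sid)
        if direction == "none":
            raise CalibrationError(
                f"mode='top' undefined for stratum {sid!r} with "
                "expected_direction 'none'")
        zs = pd.Series(res.clock_z).dropna()
        if zs.empty:
            raise CalibrationError(f"stratum {sid!r}: no testable clock")
        aligned = zs if direction == "stress" else -zs
        top_clock = aligned.idxmax()
        pieces.append(res.clock_ages[top_clock])
    cal = pd.concat(pieces)
    cal = cal.reindex([s for s in sheet.sample_ids if s in cal.index])
    dup = cal.duplicated(keep="first")
    if dup.any():
        logger.info("calibration: dropped %d samples with duplicate "
                    "calibrated values", int(dup.sum()))
    return cal[~dup]


def train_static(m: BetaMatrix, sheet: SampleSheet, calibrated: pd.Series,
                 variant: str = "median", *,
                 recipe: ct.ClockRecipe | None = None,
                 train_ids: Sequence[str] | None = None) -> ClockModel:
    """Distill calibrated ages into a single elastic-net clock
    (EnsembleAge.Static), trained exclusively on treated samples so the
    model emphasizes perturbation-responsive CpGs."""
    if variant not in ("median", "top"):
        raise CalibrationError(f"unknown static variant {variant!r}")
    treated = sheet.data.index[sheet.data["role"] == "treated"]
    ids = [s for s in (train_ids if train_ids is not None else treated)
           if s in calibrated.index and s in treated]
    if len(ids) < ct.MIN_TRAIN:
        raise TrainingError(
            f"need >= {ct.MIN_TRAIN} treated samples with calibrated ages, "
            f"got {len(ids)}")
    recipe = recipe or ct.ClockRecipe(penalty="elasticnet", mixing=0.5,
                                      preselect_strategy="all", seed=0)
    clock = ct.train_clock(m, sheet, recipe, ids,
                           clock_id=f"ensembleage_static_{variant}",
                           target=calibrated)
    clock.recipe["static_variant"] = variant
    return clock


def radar_scale(zs: Sequence[float]) -> np.ndarray:
    """Piecewise scaling of a set of z-scores to [-1, 1] for radar plots.

    |z| <= 2 maps linearly to [-0.2, 0.2] (s = 0.1 z); z > 2 maps linearly
    onto (0.2, 1] anchored at the set's maximum positive z, and z < -2
    symmetrically onto [-1, -0.2) anchored at the set's most negative z.
    Order-preserving within the set; a lone boundary value maps to +-0.2.
    """
    z = np.asarray(zs, dtype=float)
    s = 0.1 * z
    hi = z > 2
    if hi.any():
        zmax = z[hi].max()
        if zmax > 2:
            s[hi] = 0.2 + 0.8 * (z[hi] - 2.0) / (zmax - 2.0)
        else:
            s[hi] = 0.2
    lo = z < -2
    if lo.any():
        zmin = z[lo].min()
        if zmin < -2:
            s[lo] = -0.2 - 0.8 * (z[lo] + 2.0) / (zmin + 2.0)
        else:
            s[lo] = -0.2
    return s
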