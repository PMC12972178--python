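"""Scoring clocks against directional perturbation panels.

A perturbation panel is organized in strata (one intervention experiment in
one tissue, with age-matched controls).  For a given clock:

1. ``age_acceleration`` residualizes predicted age against the control
   regression line of the stratum, so treated samples are compared with
   what the clock predicts for untreated animals of the same age;
2. ``stratum_z`` tests the treated-vs-control difference in acceleration
   (OLS on a treated indicator, equivalent to a pooled two-sample t-test)
   and maps the two-sided p to a signed z;
3. ``score_clock`` aggregates per-stratum z-scores into confusion-matrix
   metrics against each stratum's documented expected direction: a stress
   intervention should accelerate epigenetic age (z > 0) and a rejuvenation
   intervention decelerate it (z < 0); |z| > 2 marks a responsive call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SplitError, StratumError
from .ewas import Z_CAP, signed_z
from .io import SampleSheet

logger = logging.getLogger(__name__)

Z_THRESH = 2.0


@dataclass
class StratumResponse:
    """Signed response of one clock in one stratum."""

    clock_id: str
    stratum_id: str
    z: float
    n_control: int
    n_treated: int
    expected_direction: str
    responsive: bool
    correct: bool | None
    untestable: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClockScore:
    """Confusion-matrix summary of a clock over a panel of strata."""

    clock_id: str
    n_strata: int
    correct_ratio: float
    median_z_expected: float
    weighted_correct: float
    accuracy: float
    error_rate: float
    nonsignificant_rate: float
    stress_detection: float
    rejuvenation_detection: float

    def to_dict(self) -> dict:
        return asdict(self)


def age_acceleration(pred: pd.Series, sheet: SampleSheet, stratum_id: str,
                     ) -> pd.Series:
    """Epigenetic age acceleration for every sample of a stratum.

    Predicted age is regressed on chronological age over the stratum's
    controls; acceleration is each sample's residual from that control
    line.  With fewer than 3 controls, or controls of constant age, the
    fit is unreliable and the difference predicted - chronological is used
    instead (logged).
    """
    sub = sheet.stratum_samples(stratum_id)
    ctrl = sub[sub["role"] == "control"]
    if ctrl.empty:
        raise StratumError(f"stratum {stratum_id!r} has no control samples")
    ages = sub["age"].astype(float)
    p = pred.reindex(sub.index).astype(float)
    ctrl_ages = ctrl["age"].astype(float).to_numpy()
    if len(ctrl) < 3 or np.ptp(ctrl_ages) == 0:
        logger.info("stratum %s: %d controls / constant ages -> delta-age "
                    "fallback", stratum_id, len(ctrl))
        return p - ages
    slope, intercept = np.polyfit(ctrl_ages,
                                  p.reindex(ctrl.index).to_numpy(), 1)
    return p - (intercept + slope * ages)


def stratum_z(accel: pd.Series, sheet: SampleSheet, stratum_id: str,
              clock_id: str = "", z_thresh: float = Z_THRESH,
              ) -> StratumResponse:
    """Signed z for the treated-vs-control acceleration contrast.

    OLS of acceleration on a treated indicator; the indicator's two-sided
    p-value is mapped through the signed probit.  Requires >= 2 treated and
    >= 2 control samples with overall nonzero variance; degenerate strata
    come back flagged untestable with z = 0.
    """
    sub = sheet.stratum_samples(stratum_id)
    direction = sub["expected_direction"].iloc[0]
    a = accel.reindex(sub.index).astype(float)
    is_treated = (sub["role"] == "treated").to_numpy()
    n_t, n_c = int(is_treated.sum()), int((~is_treated).sum())

    def resp(z: float, untestable: bool = False) -> StratumResponse:
        responsive = (not untestable) and abs(z) > z_thresh
        correct = None
        if direction != "none" and not untestable:
            correct = (z > 0) if direction == "stress" else (z < 0)
        return StratumResponse(clock_id=clock_id, stratum_id=stratum_id,
                               z=z, n_control=n_c, n_treated=n_t,
                               expected_direction=direction,
                               responsive=responsive, correct=correct,
                               untestable=untestable)

    if n_t < 2 or n_c < 2 or np.ptp(a.to_numpy()) == 0:
        if n_t >= 2 and n_c >= 2 and np.ptp(a.to_numpy()) == 0:
            return resp(0.0)           # identical groups: a true null
        return resp(0.0, untestable=True)
    x = is_treated.astype(float)
    y = a.to_numpy()
    n = len(y)
    diff = y[is_treated].mean() - y[~is_treated].mean()
    resid = y.copy()
    resid[is_treated] -= y[is_treated].mean()
    resid[~is_treated] -= y[~is_treated].mean()
    s2 = (resid ** 2).sum() / (n - 2)
    if s2 == 0:
        z = float(np.sign(diff)) * Z_CAP if diff != 0 else 0.0
        return resp(z)
    se = np.sqrt(s2 * (1.0 / n_t + 1.0 / n_c))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return resp(float(signed_z(max(p, np.finfo(float).tiny), t)))


def score_clock(responses: Sequence[StratumResponse],
                z_thresh: float = Z_THRESH) -> ClockScore:
    """Aggregate a clock's stratum responses into benchmark metrics.

    Only strata with a documented expected direction and a testable z
    enter the confusion table.  ``accuracy + error_rate +
    nonsignificant_rate = 1`` over those strata.
    """
    usable = [r for r in responses
              if r.expected_direction != "none" and not r.untestable]
    if not usable:
        raise StratumError("no testable stratum with an expected direction")
    clock_id = usable[0].clock_id
    z = np.array([r.z for r in usable])
    correct = np.array([bool(r.correct) for r in usable])
    responsive = np.abs(z) > z_thresh
    stress = np.array([r.expected_direction == "stress" for r in usable])
    aligned = np.where(stress, z, -z)

    n = len(usable)
    accuracy = float((responsive & correct).mean())
    error_rate = float((responsive & ~correct).mean())
    abs_sum = float(np.abs(z).sum())
    weighted = (float((np.abs(z) * (responsive & correct)).sum() / abs_sum)
                if abs_sum > 0 else 0.0)
    n_stress = int(stress.sum())
    n_rejuv = n - n_stress
    stress_det = (float((z[stress] > z_thresh).mean()) if n_stress else
                  float("nan"))
    rejuv_det = (float((z[~stress] < -z_thresh).mean()) if n_rejuv else
                 float("nan"))
    return ClockScore(
        clock_id=clock_id, n_strata=n,
        correct_ratio=float(correct.mean()),
        median_z_expected=float(np.median(aligned)),
        weighted_correct=weighted,
        accuracy=accuracy, error_rate=error_rate,
        nonsignificant_rate=float(1.0 - accuracy - error_rate),
        stress_detection=stress_det,
        rejuvenation_detection=rejuv_det,
    )


def split_panel(strata: Sequence[tuple[str, str]], frac: float = 2.0 / 3.0,
                seed: int = 0) -> tuple[list[str], list[str]]:
    """Split strata into a clock-selection set and a held-out test set.

    ``strata`` is a sequence of (stratum_id, expected_direction) pairs.
    The split is deterministic given the seed and stratified by direction,
    so both halves contain stress and rejuvenation strata whenever a
    direction group has at least 2 members.
    """
    if not 0.0 < frac < 1.0:
        raise SplitError("panel split fraction must be in (0, 1)")
    if len(strata) < 3:
        raise SplitError("need at least 3 strata to split a panel")
    rng = np.random.default_rng(seed)
    sel: list[str] = []
    test: list[str] = []
    by_dir: dict[str, list[str]] = {}
    for sid, d in strata:
        by_dir.setdefault(d, []).append(sid)
    for d in sorted(by_dir):
        ids = sorted(by_dir[d])
        perm = rng.permutation(len(ids))
        if len(ids) == 1:
            sel.append(ids[0])
            continue
        n_sel = int(round(len(ids) * frac))
        n_sel = min(max(n_sel, 1), len(ids) - 1)
        sel.extend(ids[i] for i in perm[:n_sel])
        test.extend(ids[i] for i in perm[n_sel:])
    return sorted(sel), sorted(test)


def outcome_association(accel: pd.Series, outcome: pd.Series,
                        ) -> tuple[float, float, float]:
    """Pearson correlation between acceleration and a numeric outcome.

    Returns (r, p, z) with p from the t-distribution and z through the
    signed probit.  Requires >= 4 complete pairs with nonzero variance.
    """
    df = pd.concat({"a": accel.astype(float), "o": outcome.astype(float)},
                   axis=1, join="inner").dropna()
    if len(df) < 4:
        raise StratumError("need >= 4 paired values for outcome association")
    if df["a"].std() == 0 or df["o"].std() == 0:
        raise StratumError("constant vector in outcome association")
    r, p = stats.pearsonr(df["a"], df["o"])
    return float(r), float(p), float(signed_z(max(p, np.finfo(float).tiny), r))


def responses_to_frame(responses: Sequence[StratumResponse]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in responses])


def scores_to_frame(scores: Sequence[ClockScore]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in scores])
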