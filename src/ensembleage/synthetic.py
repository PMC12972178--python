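"""Synthetic methylation benchmark panels with known ground truth.

The generator emulates the structure of a controlled-perturbation
benchmark: several tissue-specific strata, each holding age-matched
control animals and treated animals whose methylomes are shifted by a
signed *effective-age* delta — positive for pro-aging (stress)
interventions, negative for rejuvenating ones.

The methylation model is squashed-linear: CpG j of sample i takes

    beta_ij = clip( b0_j + s_j * g(effective_age_i) + tissue_offset_tj
                    + noise_sd * eps_ij ,  0.001, 0.999 )

with baseline b0_j ~ U(0.1, 0.9), slopes s_j ~ +-U(0.02, 0.15) for the
causal fraction of CpGs and exactly 0 otherwise, g the configured age
transform, per-(tissue, CpG) Gaussian offsets, and i.i.d. standard normal
eps scaled by ``noise_sd``.  Clipping (rather than a logistic squash)
keeps planted slopes exactly linear mid-range, so closed-form oracles
apply.  Effective age is chronological age for controls and chronological
+ delta for treated samples; deltas may be absolute years or a fraction of
chronological age.

CpG-universe parameters (baselines, causal set, slopes) are drawn from
``universe_seed`` and everything sample-specific from ``seed``, so panels
sharing a universe seed share their ground-truth CpG biology — the setting
in which a clock trained on one panel transfers to another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import agetransform as at
from .errors import ValidationError
from .io import BetaMatrix, SampleSheet

BETA_LO, BETA_HI = 0.001, 0.999


@dataclass(frozen=True)
class SimConfig:
    """Panel-generator settings.

    Defaults give a 2000-CpG, 12-stratum panel with 10 controls and 10
    treated animals per stratum, mouse-like ages uniform on 0.2-3.0 years,
    10% causal CpGs, measurement noise of 0.05 on the beta scale and mild
    tissue offsets — a size at which every pipeline stage runs in seconds
    while effects of a few tenths of a year remain clearly detectable.
    """

    n_cpgs: int = 2000
    frac_causal: float = 0.1
    n_strata: int = 12
    n_control: int = 10
    n_treated: int = 10
    age_range: tuple[float, float] = (0.2, 3.0)
    effect_sizes: tuple[float, ...] | None = None   # per-stratum delta
    directions: tuple[str, ...] | None = None
    relative_effects: bool = False    # delta as fraction of chronological age
    tissue_offsets_sd: float = 0.02
    noise_sd: float = 0.05
    transform: at.AgeTransformSpec = field(
        default_factory=lambda: at.AgeTransformSpec(kind="identity"))
    species: str = "mouse"
    seed: int = 0
    universe_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cpgs < 1 or self.n_strata < 1 or self.n_control < 1:
            raise ValidationError("counts must be >= 1")
        if not 0.0 <= self.frac_causal <= 1.0:
            raise ValidationError("frac_causal must be in [0, 1]")
        if self.age_range[0] <= 0 or self.age_range[1] <= self.age_range[0]:
            raise ValidationError("age_range must satisfy 0 < min < max")
        dirs = self.directions
        if dirs is None:
            dirs = tuple("stress" if i % 2 == 0 else "rejuvenation"
                         for i in range(self.n_strata))
            object.__setattr__(self, "directions", dirs)
        if len(dirs) != self.n_strata:
            raise ValidationError("directions length must equal n_strata")
        eff = self.effect_sizes
        if eff is None:
            eff = tuple(0.5 if d == "stress" else
                        (-0.5 if d == "rejuvenation" else 0.0)
                        for d in dirs)
            object.__setattr__(self, "effect_sizes", eff)
        if len(eff) != self.n_strata:
            raise ValidationError("effect_sizes length must equal n_strata")
        for d, e in zip(dirs, eff):
            if d == "stress" and e <= 0:
                raise ValidationError("stress strata need delta > 0")
            if d == "rejuvenation" and e >= 0:
                raise ValidationError("rejuvenation strata need delta < 0")
            if d not in ("stress", "rejuvenation", "none"):
                raise ValidationError(f"unknown direction {d!r}")

    @property
    def resolved_universe_seed(self) -> int:
        return self.seed if self.universe_seed is None else self.universe_seed


@dataclass
class SimTruth:
    """Ground truth of a simulated panel."""

    causal_cpg_ids: list[str]
    baseline: pd.Series                 # b0 per CpG
    slope: pd.Series                    # s per CpG (0 for non-causal)
    effective_age: pd.Series            # per sample, years
    delta: dict[str, float]             # per stratum (config value)


def _universe(cfg: SimConfig) -> tuple[pd.Series, pd.Series, list[str]]:
    rng = np.random.default_rng(cfg.resolved_universe_seed)
    cpgs = [f"cg{i:06d}" for i in range(cfg.n_cpgs)]
    b0 = pd.Series(rng.uniform(0.1, 0.9, cfg.n_cpgs), index=cpgs)
    n_causal = int(round(cfg.frac_causal * cfg.n_cpgs))
    causal_idx = rng.choice(cfg.n_cpgs, size=n_causal, replace=False)
    s = pd.Series(0.0, index=cpgs)
    mags = rng.uniform(0.02, 0.15, n_causal)
    signs = rng.choice([-1.0, 1.0], n_causal)
    s.iloc[causal_idx] = mags * signs
    causal = sorted(b0.index[causal_idx])
    return b0, s, causal


def simulate_panel(cfg: SimConfig) -> tuple[BetaMatrix, SampleSheet, SimTruth]:
    """Generate a perturbation benchmark panel.

    Each stratum is one tissue with ``n_control`` controls and
    ``n_treated`` treated samples; ages are uniform on ``age_range`` and
    age-matched in distribution between the roles.  Fully deterministic
    given (seed, universe_seed).
    """
    b0, s, causal = _universe(cfg)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.age_range

    rows = []
    eff_ages = []
    for si in range(cfg.n_strata):
        sid = f"stratum{si:02d}"
        tissue = f"tissue{si:02d}"
        direction = cfg.directions[si]
        delta = cfg.effect_sizes[si]
        n = cfg.n_control + cfg.n_treated
        ages = rng.uniform(lo, hi, n)
        for j in range(n):
            role = "control" if j < cfg.n_control else "treated"
            age = float(ages[j])
            d = (delta * age if cfg.relative_effects else delta)
            eff = age + d if role == "treated" else age
            eff = max(eff, 1e-3)
            rows.append({"sample_id": f"{sid}_s{j:03d}", "age": age,
                         "species": cfg.species, "tissue": tissue,
                         "stratum_id": sid, "role": role,
                         "expected_direction": direction})
            eff_ages.append(eff)
    sheet_df = pd.DataFrame(rows).set_index("sample_id")
    eff = pd.Series(eff_ages, index=sheet_df.index, name="effective_age")

    g = np.asarray(at.transform(eff.to_numpy(), cfg.transform))
    base = b0.to_numpy()[:, None] + s.to_numpy()[:, None] * g[None, :]

    # per-(tissue, CpG) offsets, then i.i.d. noise; noise enters as
    # noise_sd * standard normal so the same seed at different noise
    # levels reuses identical draws.
    tissues = sheet_df["tissue"].to_numpy()
    offsets = {t: rng.normal(0.0, cfg.tissue_offsets_sd, cfg.n_cpgs)
               for t in dict.fromkeys(tissues)}
    if cfg.tissue_offsets_sd > 0:
        off = np.column_stack([offsets[t] for t in tissues])
    else:
        off = 0.0
    eps = rng.standard_normal(base.shape)
    values = np.clip(base + off + cfg.noise_sd * eps, BETA_LO, BETA_HI)

    m = BetaMatrix(pd.DataFrame(values, index=b0.index,
                                columns=sheet_df.index))
    sheet = SampleSheet(sheet_df)
    truth = SimTruth(causal_cpg_ids=causal, baseline=b0, slope=s,
                     effective_age=eff,
                     delta={f"stratum{i:02d}": cfg.effect_sizes[i]
                            for i in range(cfg.n_strata)})
    return m, sheet, truth


def simulate_aging_only(cfg: SimConfig) -> tuple[BetaMatrix, SampleSheet,
                                                 SimTruth]:
    """Control-only panel for clock training: same generative model with
    zero treated samples and no expected direction."""
    cfg2 = replace(cfg, n_treated=0,
                   directions=tuple("none" for _ in range(cfg.n_strata)),
                   effect_sizes=tuple(0.0 for _ in range(cfg.n_strata)))
    return simulate_panel(cfg2)


def simulate_outcome_panel(cfg: SimConfig, hazard_slope: float = 1.0,
                           max_lifespan: float = 4.0,
                           outcome_noise_sd: float = 0.0,
                           ) -> tuple[BetaMatrix, SampleSheet, SimTruth]:
    """Panel with a per-sample time-to-death outcome negatively coupled to
    effective-age excess:

        time_to_death = max(L - age - hazard_slope * (eff - age) + noise, 0.01)

    With ``hazard_slope = 0`` the outcome carries no perturbation signal.
    The outcome is stored in the sample sheet under ``time_to_death``.
    """
    m, sheet, truth = simulate_panel(cfg)
    rng = np.random.default_rng([cfg.seed, 9151])
    age = sheet.data["age"].astype(float)
    excess = truth.effective_age - age
    noise = rng.normal(0.0, outcome_noise_sd, len(age))
    ttd = np.maximum(max_lifespan - age - hazard_slope * excess + noise, 0.01)
    df = sheet.data.copy()
    df["time_to_death"] = ttd
    return m, SampleSheet(df, outcome_names=["time_to_death"]), truth
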