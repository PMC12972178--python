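"""End-to-end orchestration: simulate -> train -> benchmark -> select ->
dynamic -> calibrate -> static, driven by a single run configuration.

The pipeline exists so the whole framework can be exercised (and
reproduced bit-for-bit) from one config file; each stage is also callable
on its own through the library or the CLI subcommands.  All randomness
flows from the single ``seed`` via fixed small offsets.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import agetransform as at
from . import benchmark as bm
from . import clocktrain as ct
from . import ensemble as ens
from . import io as eio
from . import synthetic as syn
from .errors import ConfigError

logger = logging.getLogger(__name__)

# Fixed offsets deriving stage seeds from the root seed.
_AGING_SEED, _PANEL_SEED, _SPLIT_SEED, _PANEL_SPLIT_SEED = 11, 23, 37, 53
_SEED_MOD = 2 ** 31 - 1


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``default_config``)."""

    seed: int = 0
    n_cpgs: int = 1000
    frac_causal: float = 0.1
    noise_sd: float = 0.05
    tissue_offsets_sd: float = 0.02
    age_range: tuple[float, float] = (0.2, 3.0)
    aging_tissues: int = 6
    aging_samples_per_tissue: int = 20
    panel_strata: int = 6
    panel_control: int = 8
    panel_treated: int = 8
    effect_size: float = 0.5
    train_frac: float = 0.7
    panel_frac: float = 2.0 / 3.0
    ensemble_k: int = 6
    z_thresh: float = 2.0
    p_thresh: float = 1e-5
    penalties: tuple[str, ...] = ("ridge", "lasso", "elasticnet")
    strategies: tuple[str, ...] = ("ewas", "random")
    seeds_per_recipe: int = 2
    transform: str = "identity"
    cv_rule: str = "min"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ConfigError("train_frac must be in (0, 1)")
        if not 0.0 < self.panel_frac < 1.0:
            raise ConfigError("panel_frac must be in (0, 1)")
        if self.z_thresh < 0:
            raise ConfigError("z_thresh must be >= 0")
        if not 0.0 < self.p_thresh <= 1.0:
            raise ConfigError("p_thresh must be in (0, 1]")
        if self.ensemble_k < 1:
            raise ConfigError("ensemble_k must be >= 1")
        if self.transform not in at.KINDS:
            raise ConfigError(f"unknown transform {self.transform!r}")
        if self.cv_rule not in ("min", "1se"):
            raise ConfigError("cv_rule must be 'min' or '1se'")
        for p in self.penalties:
            if p not in ct.PENALTIES:
                raise ConfigError(f"unknown penalty {p!r}")
        for s in self.strategies:
            if s not in ct.STRATEGIES:
                raise ConfigError(f"unknown strategy {s!r}")
        object.__setattr__(self, "age_range", tuple(self.age_range))
        object.__setattr__(self, "penalties", tuple(self.penalties))
        object.__setattr__(self, "strategies", tuple(self.strategies))

    @classmethod
    def from_mapping(cls, d: dict[str, Any]) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(
                f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        d["penalties"] = list(self.penalties)
        d["strategies"] = list(self.strategies)
        return d


def default_config(**overrides) -> RunConfig:
    return RunConfig.from_mapping(overrides)


def _stage_seed(root: int, offset: int) -> int:
    return (int(root) * 1009 + offset) % _SEED_MOD


def transform_spec(cfg: RunConfig) -> at.AgeTransformSpec:
    return at.AgeTransformSpec(kind=cfg.transform)


def build_recipes(cfg: RunConfig) -> list[ct.ClockRecipe]:
    """The clock-library grid: penalties x pre-selection strategies x
    replicate seeds."""
    spec = transform_spec(cfg)
    recipes = []
    for rep in range(cfg.seeds_per_recipe):
        for penalty in cfg.penalties:
            for strategy in cfg.strategies:
                params: dict[str, Any] = {}
                if strategy == "ewas":
                    params = {"z_thresh": 2.0, "max_k": 500}
                elif strategy == "random":
                    params = {"k": 300}
                recipes.append(ct.ClockRecipe(
                    penalty=penalty, preselect_strategy=strategy,
                    preselect_params=params, transform=spec,
                    seed=_stage_seed(cfg.seed, 100 + rep)))
    return recipes


def benchmark_library(panel_m: eio.BetaMatrix, panel_sheet: eio.SampleSheet,
                      clocks: list[eio.ClockModel], z_thresh: float = 2.0,
                      ) -> list[bm.StratumResponse]:
    """Stratum responses of every clock across every panel stratum."""
    responses = []
    for clock in clocks:
        pred = ct.predict_age(panel_m, clock)
        for sid in panel_sheet.strata:
            accel = bm.age_acceleration(pred, panel_sheet, sid)
            responses.append(bm.stratum_z(accel, panel_sheet, sid,
                                          clock_id=clock.clock_id,
                                          z_thresh=z_thresh))
    return responses


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the full framework on synthetic data and write all artifacts.

    Writes under ``outdir``: training/panel matrices and sheets, the clock
    library, benchmark responses and scores, the ensemble spec, dynamic
    results, radar-scaled z table, calibrated ages, the two static clocks,
    a report JSON and a run manifest.  Returns the report as a dict.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # 1. synthetic data: shared CpG universe, distinct samples
    universe_seed = _stage_seed(cfg.seed, 7)
    aging_cfg = syn.SimConfig(
        n_cpgs=cfg.n_cpgs, frac_causal=cfg.frac_causal,
        n_strata=cfg.aging_tissues, n_control=cfg.aging_samples_per_tissue,
        n_treated=0, age_range=cfg.age_range,
        tissue_offsets_sd=cfg.tissue_offsets_sd, noise_sd=cfg.noise_sd,
        transform=transform_spec(cfg),
        seed=_stage_seed(cfg.seed, _AGING_SEED), universe_seed=universe_seed)
    aging_m, aging_sheet, _ = syn.simulate_aging_only(aging_cfg)
    panel_cfg = syn.SimConfig(
        n_cpgs=cfg.n_cpgs, frac_causal=cfg.frac_causal,
        n_strata=cfg.panel_strata, n_control=cfg.panel_control,
        n_treated=cfg.panel_treated, age_range=cfg.age_range,
        effect_sizes=tuple(cfg.effect_size if i % 2 == 0 else -cfg.effect_size
                           for i in range(cfg.panel_strata)),
        directions=tuple("stress" if i % 2 == 0 else "rejuvenation"
                         for i in range(cfg.panel_strata)),
        tissue_offsets_sd=cfg.tissue_offsets_sd, noise_sd=cfg.noise_sd,
        transform=transform_spec(cfg),
        seed=_stage_seed(cfg.seed, _PANEL_SEED), universe_seed=universe_seed)
    panel_m, panel_sheet, panel_truth = syn.simulate_panel(panel_cfg)
    eio.write_beta(aging_m, outdir / "aging_beta.csv")
    eio.write_samples(aging_sheet, outdir / "aging_samples.csv")
    eio.write_beta(panel_m, outdir / "panel_beta.csv")
    eio.write_samples(panel_sheet, outdir / "panel_samples.csv")

    # 2. clock library on the normal-aging data
    train_ids, test_ids = ct.split_samples(
        aging_sheet, cfg.train_frac, _stage_seed(cfg.seed, _SPLIT_SEED))
    recipes = build_recipes(cfg)
    clocks = ct.train_library(aging_m, aging_sheet, recipes, train_ids,
                              test_ids=test_ids, cv_rule=cfg.cv_rule)
    eio.write_library(clocks, outdir / "library")

    # 3. benchmark on the perturbation panel
    responses = benchmark_library(panel_m, panel_sheet, clocks, cfg.z_thresh)
    bm.responses_to_frame(responses).to_csv(
        outdir / "responses.csv", index=False)

    # 4. selection on a split of the panel strata
    strata = [(sid, panel_sheet.stratum_direction(sid))
              for sid in panel_sheet.strata]
    split_seed = _stage_seed(cfg.seed, _PANEL_SPLIT_SEED)
    sel_strata, test_strata = bm.split_panel(strata, cfg.panel_frac,
                                             split_seed)
    sel_set = set(sel_strata)
    scores = []
    for clock in clocks:
        rs = [r for r in responses
              if r.clock_id == clock.clock_id and r.stratum_id in sel_set]
        scores.append(bm.score_clock(rs, cfg.z_thresh))
    bm.scores_to_frame(scores).to_csv(outdir / "scores.csv", index=False)
    k = min(cfg.ensemble_k, len(scores))
    spec = ens.select_ensemble(scores, k, split_seed=split_seed,
                               z_thresh=cfg.z_thresh)
    with open(outdir / "ensemble.json", "w", encoding="utf-8") as fh:
        json.dump(spec.to_dict(), fh, indent=1)

    # 5. dynamic prediction per stratum, radar table
    library = {c.clock_id: c for c in clocks}
    dynamic: dict[str, ens.DynamicResult] = {}
    dyn_rows, radar_rows = [], []
    for sid in panel_sheet.strata:
        res = ens.dynamic_predict(panel_m, panel_sheet, sid, spec, library)
        dynamic[sid] = res
        for sample, age in res.ages.items():
            dyn_rows.append({"sample_id": sample, "stratum_id": sid,
                             "dynamic_age": age,
                             "ensemble_z": res.ensemble_z,
                             "fallback_used": res.fallback_used})
        zs = [res.clock_z[c] for c in spec.clock_ids]
        scaled = ens.radar_scale(np.nan_to_num(zs))
        for cid, z, s in zip(spec.clock_ids, zs, scaled):
            radar_rows.append({"stratum_id": sid, "clock_id": cid,
                               "z": z, "scaled": s})
    pd.DataFrame(dyn_rows).to_csv(outdir / "dynamic.csv", index=False)
    pd.DataFrame(radar_rows).to_csv(outdir / "radar.csv", index=False)

    # 6. calibration and static distillation
    cal_median = ens.calibrate("median", dynamic, panel_sheet)
    cal_top = ens.calibrate("top", dynamic, panel_sheet)
    pd.DataFrame({"calibrated_median": cal_median,
                  "calibrated_top": cal_top}).rename_axis("sample_id").to_csv(
        outdir / "calibrated.csv")
    static_recipe = ct.ClockRecipe(penalty="elasticnet", mixing=0.5,
                                   preselect_strategy="all",
                                   transform=transform_spec(cfg),
                                   seed=_stage_seed(cfg.seed, 71))
    static_median = ens.train_static(panel_m, panel_sheet, cal_median,
                                     "median", recipe=static_recipe)
    static_top = ens.train_static(panel_m, panel_sheet, cal_top, "top",
                                  recipe=static_recipe)
    eio.write_clock(static_median, outdir / "static_median.csv")
    eio.write_clock(static_top, outdir / "static_top.csv")

    # 7. report + manifest
    report = {
        "config": cfg.to_dict(),
        "n_clocks_trained": len(clocks),
        "heldout_r": {c.clock_id: c.recipe.get("heldout_r") for c in clocks},
        "selection_strata": sel_strata,
        "test_strata": test_strata,
        "ensemble_clock_ids": spec.clock_ids,
        "ensemble_z_by_stratum": {sid: dynamic[sid].ensemble_z
                                  for sid in panel_sheet.strata},
        "fallback_strata": [sid for sid, r in dynamic.items()
                            if r.fallback_used],
        "direction_by_stratum": {sid: d for sid, d in strata},
        "planted_delta_by_stratum": panel_truth.delta,
        "n_calibrated_median": int(len(cal_median)),
        "n_calibrated_top": int(len(cal_top)),
        "static_nonzero_weights": {
            "median": len(static_median.weights),
            "top": len(static_top.weights)},
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    manifest = {
        "tool": "ensembleage", "version": __version__,
        "seed": cfg.seed, "outdir": str(outdir),
        "wall_time_s": round(time.time() - t0, 3),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return report
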