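"""Shared fixtures: small synthetic panels and a trained clock library.

Session-scoped fixtures keep the expensive pieces (clock training on the
default-size panel) to a single computation shared by the unit and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ensembleage import clocktrain as ct
from ensembleage import synthetic as syn
from ensembleage.io import BetaMatrix, SampleSheet

UNIVERSE_SEED = 424242


@pytest.fixture(scope="session")
def aging_panel():
    """Default-size normal-aging panel: 2000 CpGs, 200 causal, n = 200."""
    cfg = syn.SimConfig(n_cpgs=2000, frac_causal=0.1, n_strata=5,
                        n_control=40, n_treated=0,
                        directions=tuple("none" for _ in range(5)),
                        effect_sizes=tuple(0.0 for _ in range(5)),
                        seed=7, universe_seed=UNIVERSE_SEED)
    return syn.simulate_panel(cfg)


@pytest.fixture(scope="session")
def aging_split(aging_panel):
    _, sheet, _ = aging_panel
    return ct.split_samples(sheet, 0.7, seed=1)


@pytest.fixture(scope="session")
def trained_clock(aging_panel, aging_split):
    """Elastic-net clock with EWAS pre-selection on the default panel."""
    m, sheet, _ = aging_panel
    train_ids, _ = aging_split
    recipe = ct.ClockRecipe(penalty="elasticnet", preselect_strategy="ewas",
                            preselect_params={"z_thresh": 2.0, "max_k": 500},
                            seed=1)
    return ct.train_clock(m, sheet, recipe, train_ids)


@pytest.fixture(scope="session")
def clock_library(aging_panel, aging_split):
    """Small library across penalties and strategies, sharing the panel's
    CpG universe, for benchmarking/ensemble tests."""
    m, sheet, _ = aging_panel
    train_ids, test_ids = aging_split
    recipes = [
        ct.ClockRecipe(penalty=p, preselect_strategy=s,
                       preselect_params=({"z_thresh": 2.0, "max_k": 400}
                                         if s == "ewas" else {"k": 300}),
                       seed=10 + i)
        for i, (p, s) in enumerate(
            (p, s) for p in ("ridge", "lasso", "elasticnet")
            for s in ("ewas", "random"))
    ]
    clocks = ct.train_library(m, sheet, recipes, train_ids,
                              test_ids=test_ids)
    return {c.clock_id: c for c in clocks}


@pytest.fixture(scope="session")
def perturbation_panel():
    """12-stratum directional panel sharing the aging panel's universe."""
    cfg = syn.SimConfig(n_cpgs=2000, frac_causal=0.1, n_strata=12,
                        n_control=10, n_treated=10, seed=21,
                        universe_seed=UNIVERSE_SEED)
    return syn.simulate_panel(cfg)


@pytest.fixture(scope="session")
def ensemble_spec(clock_library, perturbation_panel):
    """Ensemble selected on the selection split of the perturbation panel."""
    from ensembleage import benchmark as bm
    from ensembleage import ensemble as ens
    from ensembleage import pipeline as pl

    m, sheet, _ = perturbation_panel
    clocks = list(clock_library.values())
    responses = pl.benchmark_library(m, sheet, clocks)
    strata = [(sid, sheet.stratum_direction(sid)) for sid in sheet.strata]
    sel, _ = bm.split_panel(strata, 2.0 / 3.0, seed=5)
    sel_set = set(sel)
    scores = []
    for c in clocks:
        rs = [r for r in responses
              if r.clock_id == c.clock_id and r.stratum_id in sel_set]
        scores.append(bm.score_clock(rs))
    k = min(4, len(scores))
    return ens.select_ensemble(scores, k, split_seed=5)


@pytest.fixture
def tiny_beta():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0.1, 0.9, (6, 4))
    return BetaMatrix(pd.DataFrame(
        vals, index=[f"cg{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(4)]))


def make_sheet(rows: list[dict]) -> SampleSheet:
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleSheet(df)
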