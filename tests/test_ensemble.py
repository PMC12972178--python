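"""Ensemble selection, dynamic prediction (median oracle), calibration,
static distillation and radar scaling."""

import numpy as np
import pandas as pd
import pytest

from ensembleage import benchmark as bm
from ensembleage import clocktrain as ct
from ensembleage import ensemble as ens
from ensembleage.errors import CalibrationError, SelectionError
from ensembleage.io import BetaMatrix


def score(clock_id, weighted=0.5, median_z=1.0, ratio=0.5,
          stress=0.5, rejuv=0.5):
    return bm.ClockScore(
        clock_id=clock_id, n_strata=10, correct_ratio=ratio,
        median_z_expected=median_z, weighted_correct=weighted,
        accuracy=0.5, error_rate=0.1, nonsignificant_rate=0.4,
        stress_detection=stress, rejuvenation_detection=rejuv)


class TestSelectEnsemble:
    def test_identity_selection_in_rank_order(self):
        scores = [score("a", 0.9), score("b", 0.7), score("c", 0.8)]
        spec = ens.select_ensemble(scores, k=3)
        assert spec.clock_ids == ["a", "c", "b"]

    def test_tie_break_by_median_z(self):
        scores = [score("a", 0.8, median_z=1.0),
                  score("b", 0.8, median_z=2.0)]
        spec = ens.select_ensemble(scores, k=1)
        assert spec.clock_ids == ["b"]

    def test_dominant_clock_first_for_any_k(self):
        scores = [score("dom", 0.99, 5.0, 0.99),
                  score("x", 0.5), score("y", 0.4)]
        for k in (1, 2, 3):
            assert ens.select_ensemble(scores, k).clock_ids[0] == "dom"

    def test_balance_guard_swaps_in_rejuvenation_detector(self):
        scores = [score("s1", 0.9, rejuv=0.0), score("s2", 0.8, rejuv=0.0),
                  score("r1", 0.1, rejuv=0.5)]
        spec = ens.select_ensemble(scores, k=2)
        assert "r1" in spec.clock_ids

    def test_too_few_clocks(self):
        with pytest.raises(SelectionError):
            ens.select_ensemble([score("a")], k=2)


def make_panel_inputs(zs_by_clock, n_control=5, n_treated=5,
                      direction="stress"):
    """A stratum where each synthetic clock's acceleration contrast is
    engineered through linear single-CpG clocks on a constructed matrix."""
    from conftest import make_sheet
    from ensembleage.agetransform import AgeTransformSpec
    from ensembleage.io import ClockModel

    n = n_control + n_treated
    ages = np.full(n, 1.5)
    rows = [dict(sample_id=f"s{i:02d}", age=ages[i], species="mouse",
                 tissue="liver", stratum_id="stA",
                 role="control" if i < n_control else "treated",
                 expected_direction=direction) for i in range(n)]
    sheet = make_sheet(rows)
    rng = np.random.default_rng(0)
    cpgs, clocks, vals = [], {}, []
    for j, (cid, shift) in enumerate(zs_by_clock.items()):
        cpg = f"cg{j:02d}"
        cpgs.append(cpg)
        # treated shifted by `shift` years on this clock's private CpG
        col = np.r_[np.zeros(n_control), np.full(n_treated, shift)]
        col = 0.4 + 0.1 * (col + rng.normal(0, 1e-3, n))
        vals.append(np.clip(col, 0, 1))
        clocks[cid] = ClockModel(
            cid, intercept=-2.5, weights={cpg: 10.0},
            transform=AgeTransformSpec(kind="identity"),
            train_means={cpg: 0.4})
    m = BetaMatrix(pd.DataFrame(np.vstack(vals), index=cpgs,
                                columns=sheet.sample_ids))
    return m, sheet, clocks


class TestDynamicPredict:
    def test_one_clock_ensemble_equals_that_clock(self):
        m, sheet, clocks = make_panel_inputs({"c1": 2.0})
        spec = ens.EnsembleSpec(clock_ids=["c1"])
        res = ens.dynamic_predict(m, sheet, "stA", spec, clocks)
        pd.testing.assert_series_equal(
            res.ages, ct.predict_age(m, clocks["c1"]), check_names=False)

    def test_hand_median_of_responsive(self):
        m, sheet, clocks = make_panel_inputs(
            {"c1": -1.0, "c2": -1.2, "c3": -0.05, "c4": 0.9},
            direction="rejuvenation")
        spec = ens.EnsembleSpec(clock_ids=list(clocks))
        res = ens.dynamic_predict(m, sheet, "stA", spec, clocks)
        zs = pd.Series(res.clock_z)
        responsive = zs[zs.abs() > 2]
        assert set(res.responsive_clocks) == set(responsive.index)
        assert res.ensemble_z == pytest.approx(np.median(responsive))
        assert not res.fallback_used

    def test_median_matches_bruteforce_oracle(self):
        """Per-sample dynamic medians equal a sort-and-middle recount."""
        m, sheet, clocks = make_panel_inputs(
            {f"c{i}": d for i, d in enumerate([2.0, 1.5, 3.0])})
        spec = ens.EnsembleSpec(clock_ids=list(clocks))
        res = ens.dynamic_predict(m, sheet, "stA", spec, clocks)
        preds = {cid: ct.predict_age(m, c) for cid, c in clocks.items()}
        for s in sheet.sample_ids:
            vals = sorted(preds[cid][s] for cid in res.responsive_clocks)
            n = len(vals)
            want = (vals[n // 2] if n % 2 else
                    0.5 * (vals[n // 2 - 1] + vals[n // 2]))
            assert res.ages[s] == pytest.approx(want)

    def test_fallback_when_none_responsive(self):
        m, sheet, clocks = make_panel_inputs({"c1": 1e-5, "c2": -1e-5})
        spec = ens.EnsembleSpec(clock_ids=list(clocks))
        res = ens.dynamic_predict(m, sheet, "stA", spec, clocks)
        assert res.fallback_used and res.responsive_clocks == []
        med = pd.concat(
            [ct.predict_age(m, c) for c in clocks.values()], axis=1
        ).median(axis=1)
        pd.testing.assert_series_equal(res.ages, med, check_names=False,
                                       atol=1e-12, rtol=0)

    def test_empty_spec_is_error(self):
        m, sheet, clocks = make_panel_inputs({"c1": 2.0})
        with pytest.raises(SelectionError):
            ens.dynamic_predict(m, sheet, "stA",
                                ens.EnsembleSpec(clock_ids=[]), clocks)


class TestCalibrate:
    def dynamic_results(self, direction="stress"):
        m, sheet, clocks = make_panel_inputs({"c1": 2.0, "c2": 3.5},
                                             direction=direction)
        spec = ens.EnsembleSpec(clock_ids=list(clocks))
        res = ens.dynamic_predict(m, sheet, "stA", spec, clocks)
        return m, sheet, clocks, {"stA": res}

    def test_median_mode_passes_dynamic_through(self):
        _, sheet, _, results = self.dynamic_results()
        cal = ens.calibrate("median", results, sheet)
        expect = results["stA"].ages
        assert (cal == expect.reindex(cal.index)).all()

    def test_top_mode_picks_max_aligned_z(self):
        _, sheet, clocks, results = self.dynamic_results()
        zs = results["stA"].clock_z
        top = max(zs, key=zs.get)
        cal = ens.calibrate("top", results, sheet)
        expect = results["stA"].clock_ages[top]
        assert (cal == expect.reindex(cal.index)).all()

    def test_top_mode_requires_direction(self):
        m, sheet, clocks = make_panel_inputs({"c1": 2.0}, direction="none")
        spec = ens.EnsembleSpec(clock_ids=["c1"])
        res = ens.dynamic_predict(m, sheet, "stA", spec, clocks)
        with pytest.raises(CalibrationError):
            ens.calibrate("top", {"stA": res}, sheet)

    def test_duplicate_values_deduplicated(self):
        _, sheet, _, results = self.dynamic_results()
        res = results["stA"]
        ages = res.ages.copy()
        ages.iloc[1] = ages.iloc[0]      # force a duplicate value
        ages.iloc[2] = ages.iloc[0]
        dup = ens.DynamicResult(res.stratum_id, ages, res.ensemble_z,
                                res.responsive_clocks, res.fallback_used,
                                res.clock_z, res.clock_ages)
        cal = ens.calibrate("median", {"stA": dup}, sheet)
        assert len(cal) == len(ages) - 2
        assert ages.index[0] in cal.index      # first in sheet order kept
        assert ages.index[1] not in cal.index


class TestTrainStatic:
    def test_null_calibration_matches_plain_clock(self, aging_panel,
                                                  aging_split):
        """Distilling chronological age must behave like an ordinary clock."""
        m, sheet, _ = aging_panel
        train_ids, test_ids = aging_split
        # mark half the samples treated so the static trainer has material
        df = sheet.data.copy()
        treated_ids = sheet.sample_ids[::2]
        df.loc[treated_ids, "role"] = "treated"
        from ensembleage.io import SampleSheet
        sheet2 = SampleSheet(df)
        recipe = ct.ClockRecipe(penalty="elasticnet",
                                preselect_strategy="all", seed=4)
        cal = sheet2.data["age"].astype(float)
        treated_train = [s for s in treated_ids if s in train_ids]
        static = ens.train_static(m, sheet2, cal, "median", recipe=recipe,
                                  train_ids=treated_train)
        plain = ct.train_clock(m, sheet2, recipe, treated_train)
        test = list(test_ids)
        ps = ct.predict_age(BetaMatrix(m.values[test]), static)
        pp = ct.predict_age(BetaMatrix(m.values[test]), plain)
        truth = sheet2.data.loc[test, "age"]
        r_static = np.corrcoef(ps, truth)[0, 1]
        r_plain = np.corrcoef(pp, truth)[0, 1]
        assert abs(r_static - r_plain) <= 0.05

    def test_controls_do_not_influence_coefficients(self, aging_panel):
        m, sheet, _ = aging_panel
        df = sheet.data.copy()
        treated_ids = sheet.sample_ids[:60]
        df.loc[treated_ids, "role"] = "treated"
        from ensembleage.io import SampleSheet
        sheet2 = SampleSheet(df)
        cal = sheet2.data["age"].astype(float)
        recipe = ct.ClockRecipe(penalty="elasticnet",
                                preselect_strategy="all", seed=4)
        c1 = ens.train_static(m, sheet2, cal, "median", recipe=recipe)
        # perturb control columns only
        vals = m.values.copy()
        ctrl = [s for s in sheet2.sample_ids if s not in treated_ids]
        vals[ctrl] = np.clip(vals[ctrl] + 0.05, 0, 1)
        c2 = ens.train_static(BetaMatrix(vals), sheet2, cal, "median",
                              recipe=recipe)
        assert c1.weights == c2.weights
        assert c1.intercept == c2.intercept


class TestRadarScale:
    def test_contract_points(self):
        s = ens.radar_scale([0.0, 2.0, 4.48, 6.96])
        assert s[0] == pytest.approx(0.0)
        assert s[1] == pytest.approx(0.2)
        assert s[2] == pytest.approx(0.6)
        assert s[3] == pytest.approx(1.0)

    def test_negative_branch_symmetry(self):
        s = ens.radar_scale([-6.96, -4.48, -2.0, 0.0])
        assert s[0] == pytest.approx(-1.0)
        assert s[1] == pytest.approx(-0.6)
        assert s[2] == pytest.approx(-0.2)

    def test_midband_linear(self):
        np.testing.assert_allclose(ens.radar_scale([-2, -1, 0, 1, 2]),
                                   [-0.2, -0.1, 0, 0.1, 0.2])

    def test_order_preserving_random_sets(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            z = rng.normal(0, 3, rng.integers(2, 15))
            s = ens.radar_scale(z)
            order = np.argsort(z)
            assert np.all(np.diff(s[order]) >= -1e-12)
            assert np.all(np.abs(s) <= 1 + 1e-12)

    def test_single_boundary_value(self):
        assert ens.radar_scale([2.0])[0] == pytest.approx(0.2)
        assert ens.radar_scale([-2.0])[0] == pytest.approx(-0.2)
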