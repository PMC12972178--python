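"""Benchmark operations: control-line acceleration, stratum z, confusion
metrics vs. an independent recount, panel splits, outcome association."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_sheet
from ensembleage import benchmark as bm
from ensembleage.errors import SplitError, StratumError


def stratum_sheet(n_control, n_treated, direction="stress",
                  ages=None, stratum="stA"):
    n = n_control + n_treated
    if ages is None:
        ages = np.linspace(1.0, 2.0, n)
    rows = [dict(sample_id=f"{stratum}_{i:02d}", age=ages[i],
                 species="mouse", tissue="liver", stratum_id=stratum,
                 role="control" if i < n_control else "treated",
                 expected_direction=direction)
            for i in range(n)]
    return make_sheet(rows)


class TestAgeAcceleration:
    def test_perfect_prediction_zero_acceleration(self):
        sheet = stratum_sheet(5, 5)
        pred = sheet.data["age"].copy()
        accel = bm.age_acceleration(pred, sheet, "stA")
        np.testing.assert_allclose(accel, 0.0, atol=1e-12)

    def test_control_line_residual(self):
        """Controls on pred = age + 1, treated at pred = age + 3 -> treated
        acceleration exactly 2."""
        sheet = stratum_sheet(5, 4)
        age = sheet.data["age"]
        treated = sheet.data["role"] == "treated"
        pred = age + 1.0 + 2.0 * treated
        accel = bm.age_acceleration(pred, sheet, "stA")
        np.testing.assert_allclose(accel[treated], 2.0, atol=1e-10)
        np.testing.assert_allclose(accel[~treated], 0.0, atol=1e-10)

    def test_two_controls_fall_back_to_delta_age(self, caplog):
        sheet = stratum_sheet(2, 3)
        pred = sheet.data["age"] + 0.7
        with caplog.at_level("INFO"):
            accel = bm.age_acceleration(pred, sheet, "stA")
        assert "fallback" in caplog.text
        np.testing.assert_allclose(accel, 0.7)

    def test_no_controls_is_error(self):
        sheet = stratum_sheet(0, 4)
        with pytest.raises(StratumError):
            bm.age_acceleration(sheet.data["age"], sheet, "stA")


class TestStratumZ:
    def test_identical_groups_z_zero(self):
        sheet = stratum_sheet(4, 4)
        accel = pd.Series(1.0, index=sheet.sample_ids)
        r = bm.stratum_z(accel, sheet, "stA")
        assert r.z == 0.0 and not r.responsive and not r.untestable

    def test_separated_groups_significant(self):
        sheet = stratum_sheet(4, 4)
        rng = np.random.default_rng(0)
        accel = pd.Series(
            np.r_[np.zeros(4), np.full(4, 2.0)] + rng.normal(0, 1e-3, 8),
            index=sheet.sample_ids)
        r = bm.stratum_z(accel, sheet, "stA")
        assert r.z > 2 and r.responsive and r.correct

    def test_antisymmetry_under_negation(self):
        sheet = stratum_sheet(5, 5)
        rng = np.random.default_rng(1)
        accel = pd.Series(rng.normal(size=10), index=sheet.sample_ids)
        z1 = bm.stratum_z(accel, sheet, "stA").z
        z2 = bm.stratum_z(-accel, sheet, "stA").z
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_matches_pooled_t_test(self):
        from scipy import stats
        sheet = stratum_sheet(6, 5)
        rng = np.random.default_rng(2)
        accel = pd.Series(rng.normal(size=11), index=sheet.sample_ids)
        treated = sheet.data["role"] == "treated"
        t, p = stats.ttest_ind(accel[treated], accel[~treated],
                               equal_var=True)
        r = bm.stratum_z(accel, sheet, "stA")
        expect = np.sign(t) * stats.norm.isf(p / 2)
        assert r.z == pytest.approx(expect, abs=1e-10)

    def test_single_treated_untestable(self):
        sheet = stratum_sheet(4, 1)
        accel = pd.Series(np.arange(5.0), index=sheet.sample_ids)
        r = bm.stratum_z(accel, sheet, "stA")
        assert r.untestable


def response(direction, z, clock="c1", stratum="s"):
    return bm.StratumResponse(
        clock_id=clock, stratum_id=stratum, z=z, n_control=5, n_treated=5,
        expected_direction=direction, responsive=abs(z) > 2,
        correct=None if direction == "none"
        else ((z > 0) if direction == "stress" else (z < 0)))


class TestScoreClock:
    def test_hand_confusion_table(self):
        dirs = ["stress", "stress", "rejuvenation", "rejuvenation",
                "rejuvenation"]
        zs = [2.5, -0.5, -3.0, 1.0, -2.2]
        s = bm.score_clock([response(d, z) for d, z in zip(dirs, zs)])
        assert s.correct_ratio == pytest.approx(0.6)
        assert s.stress_detection == pytest.approx(0.5)
        assert s.rejuvenation_detection == pytest.approx(2 / 3)
        assert s.error_rate == 0.0
        assert s.accuracy == pytest.approx(3 / 5)
        assert s.accuracy + s.error_rate + s.nonsignificant_rate == \
            pytest.approx(1.0)
        # direction-aligned z: [2.5, -0.5, 3.0, -1.0, 2.2] -> median 2.2
        assert s.median_z_expected == pytest.approx(2.2)

    def test_all_zero_z(self):
        s = bm.score_clock([response("stress", 0.0),
                            response("rejuvenation", 0.0)])
        assert s.stress_detection == 0.0
        assert s.rejuvenation_detection == 0.0
        assert s.error_rate == 0.0

    def test_perfect_stress_clock(self):
        s = bm.score_clock([response("stress", 10.0) for _ in range(4)])
        assert s.accuracy == 1.0 and s.weighted_correct == 1.0

    def test_matches_independent_recount(self):
        """Randomized responses vs. a from-scratch recount of every metric."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = rng.integers(3, 12)
            dirs = rng.choice(["stress", "rejuvenation"], n)
            zs = rng.normal(0, 3, n)
            rs = [response(d, z) for d, z in zip(dirs, zs)]
            s = bm.score_clock(rs)
            correct = [(z > 0) == (d == "stress") for d, z in zip(dirs, zs)]
            resp = [abs(z) > 2 for z in zs]
            aligned = [z if d == "stress" else -z for d, z in zip(dirs, zs)]
            assert s.correct_ratio == pytest.approx(np.mean(correct))
            assert s.accuracy == pytest.approx(
                np.mean([c and r for c, r in zip(correct, resp)]))
            assert s.error_rate == pytest.approx(
                np.mean([(not c) and r for c, r in zip(correct, resp)]))
            assert s.median_z_expected == pytest.approx(np.median(aligned))
            denom = np.sum(np.abs(zs))
            want = (np.sum([abs(z) for z, c, r in zip(zs, correct, resp)
                            if c and r]) / denom)
            assert s.weighted_correct == pytest.approx(want)

    def test_direction_relabel_symmetry(self):
        """Swapping stress<->rejuvenation while negating z leaves every
        metric unchanged."""
        rng = np.random.default_rng(10)
        dirs = rng.choice(["stress", "rejuvenation"], 9)
        zs = rng.normal(0, 3, 9)
        s1 = bm.score_clock([response(d, z) for d, z in zip(dirs, zs)])
        flip = {"stress": "rejuvenation", "rejuvenation": "stress"}
        s2 = bm.score_clock([response(flip[d], -z)
                             for d, z in zip(dirs, zs)])
        assert s1.correct_ratio == pytest.approx(s2.correct_ratio)
        assert s1.accuracy == pytest.approx(s2.accuracy)
        assert s1.error_rate == pytest.approx(s2.error_rate)
        assert s1.weighted_correct == pytest.approx(s2.weighted_correct)
        assert s1.median_z_expected == pytest.approx(s2.median_z_expected)
        assert s1.stress_detection == pytest.approx(s2.rejuvenation_detection)

    def test_no_directional_stratum_is_error(self):
        with pytest.raises(StratumError):
            bm.score_clock([response("none", 1.0)])


class TestSplitPanel:
    def strata(self, n_stress, n_rejuv):
        return ([(f"s{i}", "stress") for i in range(n_stress)] +
                [(f"r{i}", "rejuvenation") for i in range(n_rejuv)])

    def test_counts_and_rejuv_in_test(self):
        sel, test = bm.split_panel(self.strata(6, 3), 2 / 3, seed=0)
        assert len(sel) == 6 and len(test) == 3
        assert any(s.startswith("r") for s in test)

    def test_deterministic(self):
        s = self.strata(6, 3)
        assert bm.split_panel(s, 2 / 3, 3) == bm.split_panel(s, 2 / 3, 3)

    def test_frac_one_disallowed(self):
        with pytest.raises(SplitError):
            bm.split_panel(self.strata(4, 2), 1.0, 0)

    def test_too_few_strata(self):
        with pytest.raises(SplitError):
            bm.split_panel(self.strata(1, 1), 2 / 3, 0)


class TestOutcomeAssociation:
    def test_exact_negative(self):
        rng = np.random.default_rng(3)
        a = pd.Series(rng.normal(size=20))
        r, p, z = bm.outcome_association(a, -a)
        assert r == pytest.approx(-1.0)
        assert z <= -bm.Z_THRESH

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(4)
        rs = []
        for _ in range(1000):
            a = pd.Series(rng.normal(size=200))
            o = pd.Series(rng.normal(size=200))
            r, _, _ = bm.outcome_association(a, o)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_planted_correlation(self):
        rng = np.random.default_rng(5)
        o = pd.Series(rng.normal(size=100))
        a = 2 * o + rng.normal(0, 0.1, 100)
        r, _, z = bm.outcome_association(a, o)
        assert r > 0.9 and z > 2

    def test_constant_vector_rejected(self):
        a = pd.Series(np.ones(10))
        with pytest.raises(StratumError):
            bm.outcome_association(a, pd.Series(np.arange(10.0)))
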