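import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import olivephen as op
from olivephen.errors import ValidationError

from conftest import segmented_season


# Closed-form expectations checked independently against the numeric
# triangle integral (triangle_oracle) before being frozen here.
CASE_EXAMPLES = [
    # (tmin, tmax, tc) -> (cd, ca, case)
    ((12, 20, 10), (0.0, 6.0, 1)),
    ((2, 12, 10), (-4.8, 0.2, 2)),
    ((2, 8, 10), (-3.0, 0.0, 3)),
    ((-5, 5, 10), (-1.25, 0.0, 4)),
    ((-5, 15, 10), (-5.0, 0.625, 5)),
    ((-8, -2, 10), (0.0, 0.0, 6)),
]


class TestSixCases:
    @pytest.mark.parametrize("args,expected", CASE_EXAMPLES)
    def test_closed_form_values(self, args, expected):
        result = op.chill_anti_chill(*args)
        cd, ca, case = expected
        assert result.case_index == case
        assert result.cd == pytest.approx(cd, abs=1e-12)
        assert result.ca == pytest.approx(ca, abs=1e-12)

    @pytest.mark.parametrize("args,expected", CASE_EXAMPLES)
    def test_oracle_agrees(self, args, expected):
        closed = op.chill_anti_chill(*args)
        oracle = op.triangle_oracle(*args, n_steps=10_000)
        assert closed.cd == pytest.approx(oracle.cd, abs=1e-3)
        assert closed.ca == pytest.approx(oracle.ca, abs=1e-3)

    def test_inverted_extremes_rejected(self):
        with pytest.raises(ValidationError):
            op.chill_anti_chill(10, 5, 10)

    def test_degenerate_day_has_zero_chill(self):
        flat = op.chill_anti_chill(5, 5, 10)
        assert (flat.cd, flat.ca) == (0.0, 0.0)
        # a constant day above the threshold still forces
        warm = op.chill_anti_chill(12, 12, 10)
        assert warm.cd == 0.0 and warm.ca == pytest.approx(2.0)

    @given(
        tn=st.floats(-25, 30),
        span=st.floats(0, 25),
        tc=st.floats(0.5, 15),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_sign_and_oracle_equivalence(self, tn, span, tc):
        tx = tn + span
        closed = op.chill_anti_chill(tn, tx, tc)
        assert closed.cd <= 0.0 and closed.ca >= 0.0
        assert 1 <= closed.case_index <= 6
        oracle = op.triangle_oracle(tn, tx, tc, n_steps=2000)
        assert closed.cd == pytest.approx(oracle.cd, abs=1e-3)
        assert closed.ca == pytest.approx(oracle.ca, abs=1e-3)


class TestCaseBoundaryContinuity:
    eps = 1e-8

    @pytest.mark.parametrize("tx,tc", [(5.0, 10.0), (8.0, 9.0)])
    def test_frost_boundary_case4_meets_case3(self, tx, tc):
        frosty = op.chill_anti_chill(-self.eps, tx, tc)
        mild = op.chill_anti_chill(0.0, tx, tc)
        assert (frosty.case_index, mild.case_index) == (4, 3)
        assert frosty.cd == pytest.approx(mild.cd, abs=1e-6)
        assert frosty.ca == pytest.approx(mild.ca, abs=1e-6)

    @pytest.mark.parametrize("tx,tc", [(15.0, 10.0), (20.0, 3.0)])
    def test_frost_boundary_case5_meets_case2(self, tx, tc):
        frosty = op.chill_anti_chill(-self.eps, tx, tc)
        mild = op.chill_anti_chill(0.0, tx, tc)
        assert (frosty.case_index, mild.case_index) == (5, 2)
        assert frosty.cd == pytest.approx(mild.cd, abs=1e-6)
        assert frosty.ca == pytest.approx(mild.ca, abs=1e-6)

    @pytest.mark.parametrize("tn", [2.0, 0.0])
    def test_threshold_boundary_case2_meets_case3(self, tn):
        below = op.chill_anti_chill(tn, 12.0, 12.0 - self.eps)
        at = op.chill_anti_chill(tn, 12.0, 12.0)
        assert (below.case_index, at.case_index) == (2, 3)
        assert below.cd == pytest.approx(at.cd, abs=1e-6)
        assert below.ca == pytest.approx(at.ca, abs=1e-6)

    @pytest.mark.parametrize("tn", [-5.0, -0.5])
    def test_threshold_boundary_case5_meets_case4(self, tn):
        below = op.chill_anti_chill(tn, 12.0, 12.0 - self.eps)
        at = op.chill_anti_chill(tn, 12.0, 12.0)
        assert (below.case_index, at.case_index) == (5, 4)
        assert below.cd == pytest.approx(at.cd, abs=1e-6)
        assert below.ca == pytest.approx(at.ca, abs=1e-6)


class TestSequentialAccumulation:
    def hand_traced_season(self):
        # 10 cool days at 3 chill units/day (case 3), then mild forcing days
        # at 5 anti-chill units/day (case 1 with Tn = Tc).
        return segmented_season(1997, [(10, 2, 8), (355, 12, 18)])

    def test_hand_traced_release_and_sprouting(self):
        season = self.hand_traced_season()
        traj = op.accumulate_cac(season, op.CACParams(tc=10, cr=-30))
        # 3 units/day -> S hits -30 at the end of day 10 (index 9)
        assert traj.endo_release_index == 9
        assert traj.endo_release_day == dt.date(1996, 11, 10)
        # forcing resumes next day at +5/day -> zero after 6 more days
        assert traj.sprouting_index == 15
        assert traj.sprouting_day == dt.date(1996, 11, 16)
        pred = op.predict_sprouting(season, op.CACParams(tc=10, cr=-30))
        assert pred.ok and pred.jday == int(season.jdays[15])

    def test_cumulative_shape(self):
        season = self.hand_traced_season()
        traj = op.accumulate_cac(season, op.CACParams(tc=10, cr=-30))
        rel = traj.endo_release_index
        assert np.all(np.diff(traj.cumulative[: rel + 1]) <= 0)
        assert np.all(np.diff(traj.cumulative[rel:]) >= 0)

    def test_all_warm_season_never_releases(self):
        season = segmented_season(1997, [(365, 15, 25)])
        traj = op.accumulate_cac(season, op.CACParams(tc=10, cr=-30))
        assert traj.endo_release_index is None
        pred = op.predict_sprouting(season, op.CACParams(tc=10, cr=-30))
        assert not pred.ok and pred.status == "requirement-not-met"

    def test_hyper_cold_season_never_sprouts(self):
        # chilling fulfilled quickly, but anti-chill never accrues below 0 degC
        season = segmented_season(1997, [(30, 1, 6), (335, -15, -5)])
        pred = op.predict_sprouting(season, op.CACParams(tc=10, cr=-30))
        assert not pred.ok

    def test_trajectory_export_columns(self):
        season = self.hand_traced_season()
        frame = op.accumulate_cac(season, op.CACParams(tc=10, cr=-30)).to_frame()
        assert list(frame.columns) == ["date", "cd", "ca", "cumulative", "phase"]
        assert set(frame["phase"]) == {"endo-dormancy", "eco-dormancy", "post-sprouting"}

    @pytest.mark.parametrize("delta", [0.5, 2.0, 5.0])
    def test_warming_forcing_period_never_delays_sprouting(self, delta):
        params = op.CACParams(tc=10, cr=-30)
        base = segmented_season(1997, [(10, 2, 8), (355, 12, 18)])
        warmed = segmented_season(1997, [(10, 2, 8), (355, 12 + delta, 18 + delta)])
        a = op.predict_sprouting(base, params)
        b = op.predict_sprouting(warmed, params)
        assert b.jday <= a.jday
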