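"""Symmetry index, landing timing, session summaries, baseline handling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pawkit.recording import Footfall
from pawkit.kinetics import (
    baseline_adjust,
    count_ntf1f2,
    landing_timing,
    session_summary,
    symmetry_index,
    washout_readiness,
)


class TestSymmetryIndex:
    @pytest.mark.parametrize(
        "op, no, expected",
        [
            (0.0, 180.0, -200.0),   # non-weight-bearing operated limb
            (150.0, 150.0, 0.0),    # perfect symmetry
            (100.0, 300.0, -100.0),
            (1.0, 2.0, -200.0 / 3.0),
        ],
    )
    def test_reference_values(self, op, no, expected):
        assert symmetry_index(op, no) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        assert math.isnan(symmetry_index(0.0, 0.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            symmetry_index(-1.0, 5.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.0, 1e6),
        b=st.floats(0.0, 1e6),
        k=st.floats(1e-3, 1e3),
    )
    def test_antisymmetry_bounds_and_scale_invariance(self, a, b, k):
        if a + b == 0:
            return
        si = symmetry_index(a, b)
        assert -200.0 <= si <= 200.0
        assert symmetry_index(b, a) == pytest.approx(-si, abs=1e-9)
        if k * (a + b) > 0:
            assert symmetry_index(k * a, k * b) == pytest.approx(si, rel=1e-9, abs=1e-9)

    def test_extremes_attained_only_at_single_limb_loading(self):
        assert symmetry_index(0.0, 5.0) == -200.0
        assert symmetry_index(5.0, 0.0) == 200.0
        assert abs(symmetry_index(0.01, 5.0)) < 200.0


def _landing_feet(op_t, no_t, hind_t=None, operated="LF"):
    other = "RF" if operated == "LF" else "LF"
    feet = []
    for limb, t in [(operated, op_t), (other, no_t)]:
        feet.append(
            Footfall(limb=limb, strike_time=t, lift_time=t + 0.1,
                     curve=np.ones(3), centroid_path=np.zeros((3, 2)))
        )
    if hind_t is not None:
        feet.append(
            Footfall(limb="LH", strike_time=hind_t, lift_time=hind_t + 0.1,
                     curve=np.ones(3), centroid_path=np.zeros((3, 2)))
        )
    return feet


class TestLandingTiming:
    def test_operated_one_frame_late(self):
        t = landing_timing(_landing_feet(1.017, 1.000), "LF")
        assert t.tf1f2_s == pytest.approx(0.017)
        assert t.measurable

    def test_simultaneous_strikes_not_measurable(self):
        t = landing_timing(_landing_feet(1.0, 1.0), "LF")
        assert t.tf1f2_s == 0.0
        assert not t.measurable

    def test_fore_hind_delay(self):
        t = landing_timing(_landing_feet(1.0, 1.0, hind_t=1.117), "LF")
        assert t.tf1h1_s == pytest.approx(0.117)

    def test_missing_forelimb_undefined(self):
        feet = _landing_feet(1.0, 1.0)[0:1]  # operated limb only
        t = landing_timing(feet, "LF")
        assert t.tf1f2_s is None and t.measurable is None

    def test_sign_convention_operated_late_is_positive(self):
        assert landing_timing(_landing_feet(1.1, 1.0), "LF").tf1f2_s > 0
        assert landing_timing(_landing_feet(1.0, 1.1), "LF").tf1f2_s < 0


class TestCountNtf1f2:
    def test_proportion(self):
        flags = [True] * 19 + [False] * 59
        n, prop = count_ntf1f2(flags)
        assert n == 19
        assert prop == pytest.approx(19 / 78)
        assert round(100 * prop) == 24

    @pytest.mark.parametrize("flags, n, prop", [([False] * 10, 0, 0.0), ([True] * 7, 7, 1.0)])
    def test_degenerate(self, flags, n, prop):
        assert count_ntf1f2(flags) == (n, prop)


class TestSessionSummary:
    def _trials(self, rows):
        return pd.DataFrame(rows, columns=["op_pvf", "no_pvf", "op_vi", "no_vi"])

    def test_identical_symmetric_trials(self):
        tr = self._trials([[100.0, 100.0, 10.0, 10.0]] * 5)
        s = session_summary(tr)
        assert s.si_pvf_mean == 0.0 and s.si_pvf_sd == 0.0
        assert s.n_trials == 5

    def test_half_loading_gives_si_minus_66_67(self):
        """op = half of non-op in every trial -> mean SI = -66.67."""
        tr = self._trials([[50.0, 100.0, 5.0, 10.0], [60.0, 120.0, 6.0, 12.0]])
        s = session_summary(tr)
        assert s.si_pvf_mean == pytest.approx(-200.0 / 3.0)
        assert s.si_vi_mean == pytest.approx(-200.0 / 3.0)

    def test_si_is_mean_of_per_trial_ratios(self):
        # SI from session means would be different from the mean of SIs
        tr = self._trials([[50.0, 100.0, 1, 1], [300.0, 100.0, 1, 1]])
        s = session_summary(tr)
        per_trial = np.mean([symmetry_index(50, 100), symmetry_index(300, 100)])
        assert s.si_pvf_mean == pytest.approx(per_trial)
        assert s.si_pvf_mean != pytest.approx(symmetry_index(175, 100))

    def test_recovers_planted_asymmetry(self, small_study):
        tt = small_study.trial_table()
        grp = tt[(tt.trial_type == "land") & (tt.timepoint_h == 54.0)
                 & (tt.treatment == "control")]
        s = session_summary(grp)
        lam, comp = 0.56, 1.0 + 0.4 * (1 - 0.56)
        planted = 100.0 * (lam - comp) / (0.5 * (lam + comp))
        assert s.si_pvf_mean == pytest.approx(planted, abs=12.0)  # Monte-Carlo tol


class TestBaselineAdjust:
    def _summaries(self):
        rows = []
        for tp, val in [(-48.0, 4.86), (-24.0, 4.86), (6.0, -41.42), (24.0, 4.86)]:
            rows.append({"cat": 1, "period": 1, "timepoint_h": tp, "si_pvf": val})
        return pd.DataFrame(rows)

    def test_subtracts_mean_of_two_baselines(self):
        out = baseline_adjust(self._summaries(), responses=("si_pvf",))
        d6 = out.loc[out.timepoint_h == 6.0, "si_pvf"].item()
        assert d6 == pytest.approx(-46.28)
        assert not out["baseline_incomplete"].any()

    def test_post_equal_to_baseline_gives_zero(self):
        out = baseline_adjust(self._summaries(), responses=("si_pvf",))
        assert out.loc[out.timepoint_h == 24.0, "si_pvf"].item() == pytest.approx(0.0)

    def test_missing_one_baseline_uses_single_session_and_flags(self):
        df = self._summaries().iloc[1:]  # drop the -48 h session
        out = baseline_adjust(df, responses=("si_pvf",))
        assert out["baseline_incomplete"].all()
        d6 = out.loc[out.timepoint_h == 6.0, "si_pvf"].item()
        assert d6 == pytest.approx(-41.42 - 4.86)

    def test_no_baseline_raises(self):
        df = self._summaries().iloc[2:]
        with pytest.raises(ValueError, match="baseline"):
            baseline_adjust(df, responses=("si_pvf",))

    def test_baselines_separated_per_period(self):
        a = self._summaries()
        b = self._summaries().assign(period=2, si_pvf=lambda d: d.si_pvf + 100.0)
        out = baseline_adjust(pd.concat([a, b]), responses=("si_pvf",))
        # identical deltas in both periods: each period uses its own baseline
        d1 = out[(out.period == 1) & (out.timepoint_h == 6.0)]["si_pvf"].item()
        d2 = out[(out.period == 2) & (out.timepoint_h == 6.0)]["si_pvf"].item()
        assert d1 == pytest.approx(d2)


class TestWashoutReadiness:
    def test_current_at_baseline_mean_is_ready(self, rng):
        base = rng.normal(180.0, 10.0, size=10)
        assert washout_readiness(base, np.full(5, base.mean()))

    def test_collapsed_loading_not_ready(self, rng):
        base = rng.normal(180.0, 10.0, size=10)
        assert not washout_readiness(base, base - 100.0)

    def test_boundary_inclusive(self):
        base = np.array([179.0, 180.0, 181.0, 180.0])
        from scipy import stats as sps

        m = base.mean()
        hw = sps.t.ppf(0.975, 3) * base.std(ddof=1) / 2.0
        assert washout_readiness(base, np.array([m + hw]))  # exactly at the edge
        assert not washout_readiness(base, np.array([m + hw * 1.001]))
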