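"""Synthetic study generator: structure, determinism, planted effects."""

import dataclasses

import numpy as np
import pytest

from pawkit.kinetics import symmetry_index
from pawkit.simulate import (
    DEFAULT_ALLOCATION,
    KINETIC_TIMEPOINTS_H,
    PAIN_TIMEPOINTS_H,
    SimConfig,
    simulate_landing_trial,
    simulate_pain_scores,
    simulate_study,
    simulate_walking_trial,
)


class TestConfigValidation:
    def test_lameness_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="lameness"):
            SimConfig(lameness_factor={"control": {6.0: 1.2}, "er_bup": {6.0: 0.5}})

    def test_allocation_must_cover_each_cat_and_period(self):
        alloc = {c: dict(p) for c, p in DEFAULT_ALLOCATION.items()}
        del alloc[3][2]
        with pytest.raises(ValueError, match="cat 3"):
            SimConfig(sequence_allocation=alloc)

    def test_nonpositive_jump_height_rejected(self):
        with pytest.raises(ValueError, match="jump_height"):
            SimConfig(jump_height_m=0.0)

    def test_default_allocation_is_counterbalanced(self, config):
        # cats 1-2: saline first; cats 3-4: analgesic first; feet L/R balanced
        assert config.treatment(1, 1) == "control"
        assert config.treatment(1, 2) == "er_bup"
        assert config.treatment(3, 1) == "er_bup"
        assert config.operated_limb(1, 1) == "LF"
        assert config.operated_limb(2, 1) == "RF"
        feet_p1 = [config.sequence_allocation[c][1][1] for c in range(1, 5)]
        assert sorted(feet_p1) == ["L", "L", "R", "R"]


class TestWalkingTrials:
    def test_fixed_seed_reproduces_identical_recording(self, config):
        rec1, _ = simulate_walking_trial(config, 1, -24.0, seed=5)
        rec2, _ = simulate_walking_trial(config, 1, -24.0, seed=5)
        assert rec1.frames.tobytes() == rec2.frames.tobytes()

    def test_distinct_seeds_differ(self, config):
        rec1, _ = simulate_walking_trial(config, 1, -24.0, seed=5)
        rec2, _ = simulate_walking_trial(config, 1, -24.0, seed=6)
        assert rec1.frames.tobytes() != rec2.frames.tobytes()

    def test_mat_too_short_raises(self):
        with pytest.raises(ValueError, match="mat too short"):
            cfg = SimConfig(mat_size_m=(0.5, 0.5))
            simulate_walking_trial(cfg, 1, -24.0, seed=0)

    def test_symmetric_baseline_si_near_zero(self, config):
        """Without lameness, mean ground-truth forelimb SI is ~0 over trials."""
        sis = []
        for seed in range(25):
            _, gt = _ground_truth_only(config, "walk", seed)
            sis.append(symmetry_index(gt.mean_peak("LF"), gt.mean_peak("RF")))
        assert abs(np.mean(sis)) < 5.0

    def test_lameness_scales_operated_peak(self, config):
        """Operated-limb peaks track the planted lameness factor (0.66 at 24 h)."""
        ratios = []
        for seed in range(25):
            _, gt = _ground_truth_only(config, "walk", seed, timepoint=24.0)
            op, no = gt.operated_limb, "RF" if gt.operated_limb == "LF" else "LF"
            # compensation inflates the sound limb; remove it to isolate lameness
            comp = 1.0 + config.walk_comp_gain * (1.0 - 0.66)
            ratios.append(gt.mean_peak(op) / (gt.mean_peak(no) / comp))
        assert np.mean(ratios) == pytest.approx(0.66, abs=0.066)

    def test_lameness_monotone_in_operated_peak(self, config):
        """Lower lameness factor never raises the operated-limb mean peak."""
        means = []
        for lam in (1.0, 0.8, 0.5, 0.2):
            cfg = dataclasses.replace(
                config,
                lameness_factor={t: {6.0: lam} for t in ("control", "er_bup")},
            )
            peaks = []
            for seed in range(10):
                _, gt = _ground_truth_only(cfg, "walk", seed, timepoint=6.0)
                peaks.append(gt.mean_peak(gt.operated_limb))
            means.append(np.mean(peaks))
        assert all(a >= b for a, b in zip(means, means[1:]))


def _ground_truth_only(cfg, ttype, seed, timepoint=-24.0, cat=1, period=1):
    from pawkit.simulate import _landing_ground_truth, _walking_ground_truth

    rng = np.random.default_rng(seed)
    fn = _walking_ground_truth if ttype == "walk" else _landing_ground_truth
    return None, fn(cfg, cat, period, timepoint, rng)


class TestLandingTrials:
    def test_forelimbs_strike_before_hindlimbs(self, config):
        for seed in range(10):
            _, gt = _ground_truth_only(config, "land", seed, timepoint=6.0)
            fore = [f.strike_time_s for f in gt.footfalls if f.limb in ("LF", "RF")]
            hind = [f.strike_time_s for f in gt.footfalls if f.limb in ("LH", "RH")]
            assert max(fore) < min(hind)

    def test_stagger_of_one_frame_gives_one_frame_tf1f2(self, config):
        """When a stagger is planted it is a whole number of 60 Hz frames."""
        staggers = []
        for seed in range(60):
            _, gt = _ground_truth_only(config, "land", seed, timepoint=6.0)
            if gt.tf1f2_measurable:
                staggers.append(abs(gt.tf1f2_s))
        assert staggers, "no measurable staggers in 60 trials"
        frames = np.array(staggers) * config.frame_rate_hz
        assert np.allclose(frames, np.round(frames))
        assert min(staggers) == pytest.approx(1.0 / 60.0, abs=1e-9)

    def test_no_stagger_means_simultaneous_strikes(self, config):
        for seed in range(60):
            _, gt = _ground_truth_only(config, "land", seed)
            if not gt.tf1f2_measurable:
                assert gt.tf1f2_s == 0.0
                break
        else:
            pytest.fail("no unstaggered baseline landing in 60 trials")

    def test_baseline_landing_si_near_zero(self, config):
        sis = []
        for seed in range(25):
            _, gt = _ground_truth_only(config, "land", seed)
            op = gt.operated_limb
            no = "RF" if op == "LF" else "LF"
            sis.append(symmetry_index(gt.mean_peak(op), gt.mean_peak(no)))
        assert abs(np.mean(sis)) < 5.0

    def test_baseline_forelimb_peak_matches_study_conditions(self, config):
        """Mean baseline landing PVF sits in the published 185-190 %BW band."""
        peaks = []
        for seed in range(40):
            _, gt = _ground_truth_only(config, "land", seed)
            peaks.extend(
                f.peak_pct_bw for f in gt.footfalls if f.limb in ("LF", "RF")
            )
        assert 175.0 < np.mean(peaks) < 200.0


class TestPainScores:
    def test_scores_ordinal_and_capped_at_two_by_default(self, config):
        for cat in (1, 2, 3, 4):
            for period in (1, 2):
                ps = simulate_pain_scores(config, cat, period, seed=cat * 10 + period)
                assert ps.scores.dtype.kind == "i"
                assert ps.scores.min() >= 0
                assert ps.scores.max() <= 2
                assert not ps.rescue

    def test_zero_effect_zero_noise_stays_at_baseline(self, config):
        cfg = dataclasses.replace(
            config,
            pain_amplitude={"control": 0.0, "er_bup": 0.0},
            pain_noise_half_width=0.0,
        )
        ps = simulate_pain_scores(cfg, 1, 1, seed=0)
        assert np.all(ps.scores == ps.baseline_scores.mean())

    def test_control_auc_exceeds_treated_auc_on_average(self, config):
        """The analgesic arm carries a smaller pain burden (Monte Carlo)."""
        from pawkit.stats import pain_auc_above_baseline

        diffs = []
        for seed in range(300):
            c = simulate_pain_scores(config, 1, 1, seed=seed)  # control period
            t = simulate_pain_scores(config, 1, 2, seed=seed)  # treated period
            diffs.append(
                pain_auc_above_baseline(c.times_h, c.scores, c.baseline)
                - pain_auc_above_baseline(t.times_h, t.scores, t.baseline)
            )
        assert np.mean(diffs) > 0

    def test_fixed_seed_reproducible(self, config):
        a = simulate_pain_scores(config, 2, 1, seed=9)
        b = simulate_pain_scores(config, 2, 1, seed=9)
        assert np.array_equal(a.scores, b.scores)


class TestStudyDataset:
    def test_default_study_counts(self, config):
        ds = simulate_study(config, seed=0)
        assert len(ds.trials) == 4 * 2 * 8 * 20 == 1280
        tt = ds.trial_table()
        assert set(tt.loc[tt.timepoint_h > 0, "timepoint_h"]) == set(KINETIC_TIMEPOINTS_H)
        assert len(ds.pain) == 8
        assert set(ds.pain[0].times_h) == set(PAIN_TIMEPOINTS_H)

    def test_allocation_in_table_matches_schedule(self, small_study):
        tt = small_study.trial_table()
        for cat, periods in DEFAULT_ALLOCATION.items():
            for period, (trt, foot) in periods.items():
                sub = tt[(tt.cat == cat) & (tt.period == period)]
                assert set(sub.treatment) == {trt}
                assert set(sub.operated_limb) == {foot + "F"}

    def test_disjoint_seeds_give_distinct_datasets(self, config):
        a = simulate_study(config, seed=1, n_walk=1, n_land=1)
        b = simulate_study(config, seed=2, n_walk=1, n_land=1)
        ta, tb = a.trial_table(), b.trial_table()
        assert not np.allclose(ta["op_pvf"], tb["op_pvf"])

    def test_trial_render_is_deterministic(self, small_study):
        tr = small_study.trials[0]
        r1 = tr.render(small_study.config)
        r2 = tr.render(small_study.config)
        assert r1.frames.tobytes() == r2.frames.tobytes()
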