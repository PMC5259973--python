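"""Footfall detection, limb classification and kinetic extraction."""

import numpy as np
import pytest

from pawkit.recording import G, Footfall, PressureRecording
from pawkit.extraction import (
    classify_limbs,
    detect_contacts,
    extract_kinetics,
    extract_trial,
)


def _blob_recording(events, shape=(40, 60, 80), fs=60.0):
    """Recording with Gaussian blobs: events = (t0, t1, row, col, force)."""
    frames = np.zeros(shape, dtype=float)
    rr, cc = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    for t0, t1, r, c, f in events:
        k = np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * 1.6**2))
        k /= k.sum()
        frames[t0: t1 + 1] += f * k
    return PressureRecording(frames=frames, frame_rate_hz=fs)


class TestDetectContacts:
    def test_all_zero_recording_gives_no_events(self):
        rec = PressureRecording(frames=np.zeros((10, 20, 20)))
        assert detect_contacts(rec) == []

    def test_empty_recording_gives_no_events(self):
        rec = PressureRecording(frames=np.zeros((0, 20, 20)))
        assert detect_contacts(rec) == []

    def test_single_blob_three_frames_contact_time(self):
        """One blob active frames 10-12 -> one event of 3/60 = 0.05 s."""
        rec = _blob_recording([(10, 12, 30, 40, 10.0)])
        events = detect_contacts(rec, force_threshold=0.05, min_frames=2)
        assert len(events) == 1
        ev = events[0]
        assert ev.strike_time == pytest.approx(10 / 60)
        assert ev.contact_time == pytest.approx(3 / 60)

    def test_two_distant_blobs_overlapping_in_time_stay_separate(self):
        # 10 cm apart = 20 sensels at the default 0.5 cm pitch
        rec = _blob_recording([(5, 15, 20, 30, 8.0), (8, 18, 20, 50, 8.0)])
        events = detect_contacts(rec, force_threshold=0.05)
        assert len(events) == 2

    def test_events_shorter_than_min_frames_dropped(self):
        rec = _blob_recording([(10, 11, 30, 40, 10.0)])
        assert detect_contacts(rec, force_threshold=0.05, min_frames=3) == []

    def test_min_frames_below_two_rejected(self):
        rec = PressureRecording(frames=np.zeros((5, 10, 10)))
        with pytest.raises(ValueError, match="min_frames"):
            detect_contacts(rec, min_frames=1)

    def test_contact_times_are_frame_multiples(self, walking_trial):
        rec, _ = walking_trial
        for ev in detect_contacts(rec):
            n = ev.contact_time * rec.frame_rate_hz
            assert n == pytest.approx(round(n), abs=1e-9)


class TestClassifyLimbs:
    def test_landing_earliest_two_are_forelimbs(self):
        """Strikes at 1.000, 1.017, 1.117, 1.117 s, alternating sides."""
        rec = _blob_recording(
            [
                (60, 68, 36, 40, 10.0),   # t=1.000 left
                (61, 69, 24, 41, 10.0),   # t=1.017 right
                (67, 75, 37, 20, 8.0),    # t=1.117 left, behind
                (67, 75, 23, 20, 8.0),    # t=1.117 right, behind
            ],
            shape=(80, 60, 80),
        )
        feet = detect_contacts(rec, force_threshold=0.05)
        classify_limbs(feet, "land")
        labels = {f.limb for f in feet}
        assert labels == {"LF", "RF", "LH", "RH"}
        fore = sorted(f.strike_time for f in feet if f.limb in ("LF", "RF"))
        hind = sorted(f.strike_time for f in feet if f.limb in ("LH", "RH"))
        assert max(fore) < min(hind)

    def test_single_event_classified_forelimb(self):
        rec = _blob_recording([(10, 20, 30, 40, 10.0)])
        feet = detect_contacts(rec, force_threshold=0.05)
        classify_limbs(feet, "land")
        assert feet[0].limb in ("LF", "RF")

    def test_empty_event_list_rejected(self):
        with pytest.raises(ValueError, match="no contact events"):
            classify_limbs([], "walk")

    def test_walking_labels_match_ground_truth(self, config):
        """>= 95% of footfalls get the generator's limb label across seeds."""
        from pawkit.simulate import simulate_walking_trial

        ok = tot = 0
        for seed in range(10):
            rec, gt = simulate_walking_trial(config, 1 + seed % 4, -24.0, seed=seed)
            feet = extract_trial(rec, gt.body_weight_kg, "walk")
            g = sorted(gt.footfalls, key=lambda f: f.strike_time_s)
            e = sorted(feet, key=lambda f: f.strike_time)
            assert len(g) == len(e)
            tot += len(g)
            ok += sum(gf.limb == ef.limb for gf, ef in zip(g, e))
        assert ok / tot >= 0.95


class TestExtractKinetics:
    def _footfall(self, curve, fs=60.0):
        n = len(curve)
        return Footfall(
            limb="LF",
            strike_time=0.0,
            lift_time=n / fs,
            curve=np.asarray(curve, dtype=float),
            centroid_path=np.zeros((n, 2)),
            frame_rate_hz=fs,
        )

    def test_rectangular_curve(self):
        """Constant 50 %BW for 0.2 s -> PVF 50, VI 10.0 %BW.s."""
        w_kg = 3.0
        level = 0.50 * w_kg * G  # newtons equal to 50 %BW
        ff = self._footfall(np.full(13, level))  # 13 samples span 0.2 s
        extract_kinetics(ff, w_kg)
        assert ff.pvf_pct_bw == pytest.approx(50.0)
        assert ff.vi_pct_bw_s == pytest.approx(10.0)

    def test_triangular_curve(self):
        """Peak 180 %BW, base 0.10 s -> PVF 180, VI 9.0."""
        w_kg = 2.5
        peak = 1.80 * w_kg * G
        tri = peak * (1.0 - np.abs(np.linspace(-1, 1, 7)))  # 7 samples span 0.1 s
        ff = self._footfall(tri)
        extract_kinetics(ff, w_kg)
        assert ff.pvf_pct_bw == pytest.approx(180.0)
        assert ff.vi_pct_bw_s == pytest.approx(9.0)

    def test_zero_curve_gives_zero_kinetics(self):
        ff = self._footfall(np.zeros(5))
        extract_kinetics(ff, 3.0)
        assert ff.pvf_pct_bw == 0.0
        assert ff.vi_pct_bw_s == 0.0

    def test_nonpositive_weight_rejected(self):
        ff = self._footfall(np.ones(5))
        with pytest.raises(ValueError, match="weight"):
            extract_kinetics(ff, 0.0)


class TestOracleEquivalence:
    def test_force_conservation_during_single_limb_contact(self, config):
        """With zero sensor noise, summed mat force equals the limb curve."""
        import dataclasses

        from pawkit.simulate import simulate_landing_trial

        cfg = dataclasses.replace(config, noise_sd=0.0, stagger_prob=0.0)
        rec, gt = simulate_landing_trial(cfg, 1, -24.0, seed=3)
        # frames before the hindlimbs arrive hold exactly the two forelimbs
        first = sorted(gt.footfalls, key=lambda f: f.strike_time_s)[0]
        fs = rec.frame_rate_hz
        i0 = int(round(first.strike_time_s * fs))
        total = rec.frames[i0: i0 + 3].sum(axis=(1, 2))
        fore = [f for f in gt.footfalls if f.limb in ("LF", "RF")]
        from pawkit.simulate import generate_force_curve

        expected = np.zeros_like(total)
        for f in fore:
            c = generate_force_curve(f.peak_pct_bw, f.contact_time_s, fs, f.shape)
            forces = c.samples * gt.body_weight_kg * G / 100.0
            s = int(round(f.strike_time_s * fs))
            for j in range(3):
                idx = i0 + j - s
                if 0 <= idx < len(forces):
                    expected[j] += forces[idx]
        assert total == pytest.approx(expected, rel=1e-5)

    def test_extracted_kinetics_match_ground_truth(self, config):
        """PVF within frame-discretisation error, VI within 2%, on both gaits."""
        from pawkit.simulate import simulate_landing_trial, simulate_walking_trial

        for maker, ttype, seeds in [
            (simulate_walking_trial, "walk", range(3)),
            (simulate_landing_trial, "land", range(6)),
        ]:
            for seed in seeds:
                rec, gt = maker(config, 1 + seed % 4, -24.0, seed=seed)
                feet = extract_trial(rec, gt.body_weight_kg, ttype)
                # pair by strike frame then lateral position: simultaneous
                # strikes (landings) are disambiguated spatially
                g = sorted(gt.footfalls, key=lambda f: (round(f.strike_time_s, 2), f.y_cm))
                e = sorted(feet, key=lambda f: (round(f.strike_time, 2), f.position[1]))
                assert len(g) == len(e)
                for gf, ef in zip(g, e):
                    assert ef.pvf_pct_bw == pytest.approx(
                        gf.peak_pct_bw, abs=max(gf.pvf_tol_pct_bw, 0.02 * gf.peak_pct_bw)
                    )
                    assert ef.vi_pct_bw_s == pytest.approx(gf.vi_pct_bw_s, rel=0.02)
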