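"""Track and pose feature batteries: speed classes, posture, acclimation,
habituation, location measures, and the battery registries."""

import numpy as np
import pytest

from phenocage.assay import CageGeometry
from phenocage.homecage import (POSE52_REGISTRY, TRACK15_REGISTRY,
                                SpeedClassConfig, acclimation, battery_pose52,
                                battery_track15,
                                distance_from_wall, habituation, percent_moved,
                                quadrant_occupancy, sap_fraction,
                                speed_class_fractions, time_near_window)
from conftest import build_recording, track_with_moved_fraction

CFG = SpeedClassConfig()


def steps_track(steps, x0=150.0, y0=120.0):
    """Centroid track with prescribed per-frame displacements (px)."""
    dx = np.asarray(steps, float) * np.where(np.arange(len(steps)) % 2 == 0, 1, -1)
    return np.stack([x0 + np.cumsum(dx), np.full(len(steps), y0)], axis=1)


class TestSpeedClasses:
    def test_frozen_animal_never_moves(self):
        rec = build_recording(np.tile([150.0, 120.0], (600, 1)))
        assert percent_moved(rec, (0, 600)) == 0.0

    def test_every_frame_mover_is_100(self):
        rec = build_recording(steps_track(np.full(600, 5.0)))
        # frame 0 carries zero displacement by convention; measure frames 1+
        assert percent_moved(rec, (1, 600)) == 100.0

    def test_hand_counted_fixture(self):
        moving = np.zeros(601)
        moving[1:38] = 5.0  # 37 moving frames inside a 600-frame interval
        rec = build_recording(steps_track(moving))
        assert percent_moved(rec, (1, 601)) == pytest.approx(100 * 37 / 600)
        assert percent_moved(rec, (1, 601)) == pytest.approx(6.1667, abs=1e-3)

    def test_hand_counted_class_fractions(self):
        # speeds: 0, three in the scoot band, one burst over 5 frames
        rec = build_recording(steps_track([0.0, 0.0, 4.0, 5.0, 6.0, 12.0]))
        out = speed_class_fractions(rec, (1, 6))
        assert out["moved"] == pytest.approx(80.0)
        assert out["scoot"] == pytest.approx(60.0)
        assert out["burst"] == pytest.approx(20.0)

    def test_no_moving_frames_flagged(self):
        rec = build_recording(np.tile([150.0, 120.0], (10, 1)))
        out = speed_class_fractions(rec, (0, 10))
        assert out["mean_speed"] == 0.0 and out["no_moving_frames"]

    def test_empty_interval_rejected(self):
        rec = build_recording(np.tile([150.0, 120.0], (10, 1)))
        with pytest.raises(ValueError):
            speed_class_fractions(rec, (20, 30))

    @pytest.mark.parametrize("seed", range(8))
    def test_band_nesting_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        rec = build_recording(steps_track(rng.exponential(4.0, 300)))
        out = speed_class_fractions(rec, (0, 300))
        assert out["escape"] <= out["burst"] + 1e-12
        assert out["burst"] <= out["moved"] + 1e-12
        assert out["scoot"] + out["burst"] <= out["moved"] + 1e-12
        assert out["moved"] <= 100.0


class TestStretchAttend:
    def test_never_elongated_gives_zero(self):
        rec = build_recording(np.tile([150.0, 120.0], (100, 1)))
        assert sap_fraction(rec, (0, 100)) == 0.0

    def test_elongated_but_fast_frames_excluded(self):
        n = 200
        elong = np.ones(n)
        elong[:80] = 1.35   # elongated during the first 80 frames
        steps = np.zeros(n)
        steps[:40] = 6.0    # but moving during the first 40
        rec = build_recording(steps_track(steps), elongation=elong)
        sap = sap_fraction(rec, (0, n))
        elongated_pct = 100.0 * np.mean(elong > 1.2 * np.median(elong))
        assert sap < elongated_pct
        assert sap == pytest.approx(100 * 40 / 200, abs=1.0)

    def test_missing_nose_keypoint_is_an_error(self):
        rec = build_recording(np.tile([150.0, 120.0], (10, 1)))
        rec.bodyparts = tuple(p if p != "nose" else "snout" for p in rec.bodyparts)
        with pytest.raises(KeyError):
            sap_fraction(rec, (0, 10))


class TestAcclimationHabituation:
    def test_flat_behavior_has_zero_acclimation(self, tl3):
        rec = build_recording(np.tile([150.0, 120.0], (tl3.n_frames, 1)), timeline=tl3)
        assert acclimation(rec, "moved") == 0.0
        assert acclimation(rec, "sap") == 0.0

    def test_acclimation_is_period1_minus_period6(self, tl3):
        n = tl3.n_frames
        track = track_with_moved_fraction([(0, 600, 0.30), (3000, 3600, 0.10)], n)
        rec = build_recording(track, timeline=tl3)
        assert acclimation(rec, "moved") == pytest.approx(20.0, abs=0.5)

    def test_recording_shorter_than_first_hour_rejected(self):
        rec = build_recording(np.zeros((600, 2)))
        with pytest.raises(ValueError):
            acclimation(rec, "moved")

    def test_habituation_index_is_first_minus_third_response(self, tl3):
        n = tl3.n_frames
        windows = []
        for onset_h, frac in zip(tl3.stimulus_onsets, (0.40, 0.25, 0.10)):
            f0 = int(onset_h * 3600)
            windows.append((f0, f0 + 600, frac))
        rec = build_recording(track_with_moved_fraction(windows, n), timeline=tl3)
        out = habituation(rec, "moved")
        assert out["response_1"] == pytest.approx(40.0, abs=0.5)
        assert out["habituation_index"] == pytest.approx(30.0, abs=1.0)

    def test_no_response_anywhere_gives_zero_index(self, tl3):
        rec = build_recording(np.tile([150.0, 120.0], (tl3.n_frames, 1)), timeline=tl3)
        out = habituation(rec, "moved")
        assert out["habituation_index"] == 0.0

    def test_onset_at_recording_edge_rejected(self, tl3):
        from phenocage.assay import AssayTimeline
        tl = AssayTimeline(phases=(("day", 0.0, 1.0),), stimulus_onsets=(0.05,))
        rec = build_recording(np.zeros((3600, 2)), timeline=tl)
        with pytest.raises(ValueError, match="edge"):
            habituation(rec, "moved")


class TestLocation:
    def test_parked_animal_occupies_one_quadrant(self):
        rec = build_recording(np.tile([50.0, 50.0], (100, 1)))
        np.testing.assert_allclose(quadrant_occupancy(rec, (0, 100)),
                                   [100.0, 0.0, 0.0, 0.0])

    def test_occupancy_is_a_partition_of_unity(self):
        rng = np.random.default_rng(0)
        g = CageGeometry()
        rec = build_recording(rng.uniform([0, 0], [g.width, g.height], (500, 2)))
        assert quadrant_occupancy(rec, (0, 500)).sum() == pytest.approx(100.0, abs=1e-9)

    def test_uniform_walk_spreads_over_quadrants(self):
        rng = np.random.default_rng(1)
        g = CageGeometry()
        rec = build_recording(rng.uniform([0, 0], [g.width, g.height], (20000, 2)))
        np.testing.assert_allclose(quadrant_occupancy(rec, (0, 20000)),
                                   [25, 25, 25, 25], atol=2.0)

    def test_wall_distance_geometry(self):
        g = CageGeometry()
        pinned = build_recording(np.tile([0.0, 120.0], (10, 1)))
        assert distance_from_wall(pinned, (0, 10)) == 0.0
        centered = build_recording(np.tile([g.width / 2, g.height / 2], (10, 1)))
        assert distance_from_wall(centered, (0, 10)) == min(g.width, g.height) / 2

    def test_wall_distance_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        g = CageGeometry()
        pts = rng.uniform([0, 0], [g.width, g.height], (200, 2))
        rec = build_recording(pts)
        c = rec.centroid
        brute = np.mean([min(x, g.width - x, y, g.height - y) for x, y in c])
        assert distance_from_wall(rec, (0, 200)) == pytest.approx(brute)

    def test_window_presence(self):
        g = CageGeometry()
        at_window = np.tile(g.window_center, (50, 1))
        rec = build_recording(at_window, geometry=g)
        # nose sits 14 px ahead of the centroid; both are within the radius
        assert time_near_window(rec, (0, 50)) == 100.0
        zero = CageGeometry(window_radius=0.0)
        rec0 = build_recording(np.tile([200.0, 100.0], (50, 1)), geometry=zero)
        assert time_near_window(rec0, (0, 50)) == 0.0

    def test_with_partner_is_a_conjunction(self):
        g = CageGeometry()
        rec = build_recording(np.tile(g.window_center, (50, 1)), geometry=g)
        partner = np.zeros(50, dtype=bool)
        partner[:20] = True
        alone = time_near_window(rec, (0, 50))
        both = time_near_window(rec, (0, 50), partner_near=partner, with_partner=True)
        assert both <= alone
        assert both == pytest.approx(40.0)


class TestBatteries:
    def test_registries_have_the_declared_sizes(self):
        assert len(TRACK15_REGISTRY) == 15
        assert len(POSE52_REGISTRY) == 52
        assert len({n for n, _ in TRACK15_REGISTRY}) == 15
        assert len({n for n, _ in POSE52_REGISTRY}) == 52

    def test_batteries_are_deterministic_and_complete(self, small_cohort):
        _, recs, _, _ = small_cohort
        rec = recs[0]
        t1, t2 = battery_track15(rec), battery_track15(rec)
        p1 = battery_pose52(rec)
        assert list(t1.values) == [n for n, _ in TRACK15_REGISTRY]
        assert list(p1.values) == [n for n, _ in POSE52_REGISTRY]
        assert t1.values == t2.values

    def test_quadrant_entries_sum_to_100(self, small_cohort):
        _, recs, _, _ = small_cohort
        t = battery_track15(recs[3])
        total = sum(t.values[f"quadrant{i}_occupancy"] for i in range(1, 5))
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_fraction_entries_lie_in_0_100(self, small_cohort):
        _, recs, _, _ = small_cohort
        for fv in (battery_track15(recs[5]), battery_pose52(recs[5])):
            for name, val in fv.values.items():
                unit = fv.units[name]
                if unit == "% frames" and np.isfinite(val):
                    assert -1e-9 <= val <= 100.0 + 1e-9, name

    def test_battery_invariant_to_filter_noop(self, small_cohort):
        from phenocage.assay import filter_low_likelihood
        _, recs, _, _ = small_cohort
        rec = recs[2].copy()
        rec.likelihood[:] = 1.0
        before = battery_track15(rec).values
        after = battery_track15(filter_low_likelihood(rec)).values
        assert before == after
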