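"""Synthetic-data generator: archetype geometry, schedules, determinism,
construction guarantees (immobility rule, torpor detectability, Tb anchors)."""

import numpy as np
import pytest

from torporpose import (
    IMMOBILE,
    MOBILE,
    SyntheticCohortConfig,
    TbParams,
    bin_average,
    body_length,
    body_width,
    default_schedule,
    detect_torpor_bouts,
    extract_bouts,
    generate_cohort,
    generate_recording,
    head_angle,
    immobile_bins_10s,
    kde_activity_threshold,
    locomotion,
    make_archetype,
    normalize_01,
    classify_bins,
    tb_trajectory,
)
from torporpose.io import PART_INDEX
from torporpose.simulate import ARCHETYPE_NAMES, StateSchedule, Segment


class TestArchetypes:
    @pytest.mark.parametrize("name", ARCHETYPE_NAMES)
    def test_mean_pose_realizes_geometry_targets_within_2pct(self, name):
        arch = make_archetype(name)
        length, width, angle = arch.realized_geometry()
        assert length == pytest.approx(arch.target_length, rel=0.02)
        assert width == pytest.approx(arch.target_width, rel=0.02)
        assert angle == pytest.approx(arch.target_head_angle, rel=0.02)

    def test_curled_matches_measured_torpor_posture(self):
        arch = make_archetype("curled_up")
        assert body_length(arch.coords) == pytest.approx(42.32, rel=0.02)
        assert body_width(arch.coords) == pytest.approx(33.99, rel=0.02)
        assert head_angle(arch.coords) == pytest.approx(117.75, rel=0.02)

    def test_stretched_matches_measured_amp_posture(self):
        arch = make_archetype("stretched")
        assert body_length(arch.coords) == pytest.approx(59.09, rel=0.02)
        assert body_width(arch.coords) == pytest.approx(31.11, rel=0.02)
        assert head_angle(arch.coords) == pytest.approx(63.21, rel=0.02)

    def test_lying_sides_are_mirror_images(self):
        left = make_archetype("lying_left").coords
        right = make_archetype("lying_right").coords
        assert body_length(left) == pytest.approx(body_length(right))
        # mirror about the body axis: flip x and swap left/right part labels
        mirrored = right.copy()
        mirrored[:, 0] *= -1
        for a, b in (("right_ear", "left_ear"), ("right_hip", "left_hip")):
            i, j = PART_INDEX[a], PART_INDEX[b]
            mirrored[[i, j]] = mirrored[[j, i]]
        np.testing.assert_allclose(left, mirrored)

    def test_overrides_replace_keypoints_and_fields(self):
        arch = make_archetype(
            "curled_up", {"tail_base": (1.0, -20.0), "nose_movement_rate": 0.3}
        )
        np.testing.assert_allclose(
            arch.coords[PART_INDEX["tail_base"]], [1.0, -20.0]
        )
        assert arch.nose_movement_rate == 0.3

    def test_unknown_names_rejected(self):
        with pytest.raises(ValueError, match="unknown archetype"):
            make_archetype("sphinx")
        with pytest.raises(ValueError, match="unknown override"):
            make_archetype("curled_up", {"whiskers": (0, 0)})


class TestSchedules:
    @pytest.mark.parametrize("condition,hours", [
        ("torpor", 24), ("sleep", 24), ("cold", 12), ("amp", 12), ("torpor", 3),
    ])
    def test_segments_fill_the_recording(self, condition, hours):
        sched = default_schedule(condition, hours)
        assert sched.total_duration == pytest.approx(hours * 3600)
        # 300-s alignment keeps 5-min bins homogeneous
        for seg in sched.segments:
            assert seg.duration % 300 == 0

    def test_torpor_schedule_contains_tb_drops(self):
        sched = default_schedule("torpor", 24)
        assert sum(s.tb_drop for s in sched.segments) >= 2

    def test_sleep_and_cold_have_no_drops(self):
        for condition in ("sleep", "cold"):
            assert not any(s.tb_drop for s in default_schedule(condition, 12).segments)


class TestTbTrajectory:
    def test_transition_temperatures_anchored(self):
        sched = StateSchedule(
            segments=[
                Segment(MOBILE, "active", 7200),
                Segment(IMMOBILE, "curled_up", 10800, tb_drop=True),
                Segment(MOBILE, "active", 7200),
            ]
        )
        p = sched.tb
        t = np.arange(0.0, sched.total_duration + 1, 10.0)
        tb = tb_trajectory(t, sched, rng=None)
        entry = tb[t == 7200.0][0]
        exit_ = tb[t == 18000.0][0]
        assert entry == pytest.approx(p.entry_tb, abs=0.05)
        assert exit_ == pytest.approx(p.exit_tb, abs=0.15)
        assert tb.min() < 34.0
        assert tb[0] == pytest.approx(p.baseline, abs=0.01)

    def test_invalid_anchor_rejected(self):
        sched = StateSchedule(
            segments=[Segment(IMMOBILE, "curled_up", 600, tb_drop=True)],
            tb=TbParams(entry_tb=37.5),
        )
        with pytest.raises(ValueError):
            tb_trajectory(np.arange(0, 601, 300.0), sched)


class TestGenerateRecording:
    def test_frame_and_sample_counts(self):
        track, tb, truth = generate_recording("sleep", duration_h=1, fps=12, seed=0)
        assert track.n_frames == 3600 * 12
        assert tb.n_samples == 13  # hourly recording, 5-min sampling
        assert len(truth) == 360

    def test_24h_at_12fps_frame_count(self):
        # frame count only; no need to build the array
        assert int(24 * 3600 * 12) == 1_036_800

    def test_same_seed_bit_identical(self):
        a = generate_recording("torpor", duration_h=2, fps=2, seed=42)
        b = generate_recording("torpor", duration_h=2, fps=2, seed=42)
        np.testing.assert_array_equal(a[0].coords, b[0].coords)
        np.testing.assert_array_equal(a[1].temp_c, b[1].temp_c)

    def test_schedule_duration_mismatch_rejected(self):
        sched = StateSchedule(segments=[Segment(MOBILE, "active", 600)])
        with pytest.raises(ValueError, match="schedule"):
            generate_recording("sleep", duration_h=1, fps=2, schedule=sched)

    def test_immobility_rule_holds_by_construction(self, torpor_recording):
        """Immobile truth bins pass the <50 px rule at rate >= 0.99; mobile
        bins violate it at rate >= 0.95."""
        track, _, truth = torpor_recording
        labels = immobile_bins_10s(track)
        truth_states = truth["state"].to_numpy()
        imm = truth_states == IMMOBILE
        assert (labels[imm] == IMMOBILE).mean() >= 0.99
        assert (labels[~imm] == MOBILE).mean() >= 0.95

    def test_torpor_bouts_detectable_from_generated_tb(self, torpor_recording):
        track, tb, truth = torpor_recording
        loco = normalize_01(bin_average(locomotion(track), 300.0))
        model = kde_activity_threshold(loco)
        bouts = extract_bouts(
            classify_bins(loco, model), min_consecutive=1, bin_duration=300.0
        )
        found = detect_torpor_bouts(bouts, tb)
        assert len(found) >= 1
        for t in found:
            assert t.min_tb < 34.0
            assert t.bout.duration >= 1800

    def test_entry_exit_tb_recovered_near_generator_anchors(self, torpor_recording):
        track, tb, truth = torpor_recording
        loco = normalize_01(bin_average(locomotion(track), 300.0))
        model = kde_activity_threshold(loco)
        bouts = extract_bouts(
            classify_bins(loco, model), min_consecutive=1, bin_duration=300.0
        )
        found = detect_torpor_bouts(bouts, tb)
        entries = np.array([t.entry_tb for t in found])
        exits = np.array([t.exit_tb for t in found])
        assert entries.mean() == pytest.approx(35.19, abs=0.3)
        assert exits.mean() == pytest.approx(33.45, abs=0.3)
        assert entries.mean() - exits.mean() == pytest.approx(1.74, abs=0.5)


class TestGenerateCohort:
    def test_animal_counts_and_ids(self):
        cfg = SyntheticCohortConfig(
            n_torpor=2, n_sleep=3, fps=2,
            duration_h={"torpor": 1, "sleep": 1, "cold": 1, "amp": 1},
        )
        cohort = generate_cohort(cfg, seed=0)
        assert len(cohort) == 5
        ids = [a.animal_id for a in cohort]
        assert ids == ["T1", "T2", "S1", "S2", "S3"]

    def test_same_seed_identical_cohorts(self):
        cfg = SyntheticCohortConfig(
            n_torpor=1, n_sleep=1, fps=2,
            duration_h={"torpor": 1, "sleep": 1, "cold": 1, "amp": 1},
        )
        c1 = generate_cohort(cfg, seed=9)
        c2 = generate_cohort(cfg, seed=9)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.track.coords, b.track.coords)
            np.testing.assert_array_equal(a.tb.temp_c, b.tb.temp_c)

    def test_empty_config_rejected(self):
        cfg = SyntheticCohortConfig(n_torpor=0, n_sleep=0)
        with pytest.raises(ValueError, match="empty"):
            generate_cohort(cfg, seed=0)

    def test_round_trip_through_disk_formats(self, tmp_path):
        from torporpose import read_pose_track, read_tb_series, write_pose_track, write_tb_series

        track, tb, _ = generate_recording("sleep", duration_h=0.5, fps=2, seed=3)
        write_pose_track(track, tmp_path / "pose.csv")
        write_tb_series(tb, tmp_path / "tb.csv")
        rt = read_pose_track(tmp_path / "pose.csv", fps=2)
        np.testing.assert_array_equal(rt.coords, track.coords)
        rtb = read_tb_series(tmp_path / "tb.csv")
        np.testing.assert_array_equal(rtb.temp_c, tb.temp_c)

    def test_cli_writes_expected_files(self, tmp_path):
        from torporpose._cli import main

        rc = main([
            "--condition", "sleep", "--hours", "0.5", "--fps", "2",
            "--seed", "1", "--out", str(tmp_path),
        ])
        assert rc == 0
        assert (tmp_path / "sleep_seed1_pose.csv").exists()
        assert (tmp_path / "sleep_seed1_tb.csv").exists()
        assert (tmp_path / "sleep_seed1_truth.csv").exists()
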