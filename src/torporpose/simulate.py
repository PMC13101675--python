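"""Synthetic keypoint trajectories, Tb traces and ground-truth state labels.

The generator emulates the statistical structure the analysis pipeline
assumes — not rodent biomechanics.  Each recording is a sequence of mobile
and immobile segments.  During mobile segments the back point performs a
bounded, heading-persistent random walk inside the cage while the body keeps
a rigid "active" pose; during immobile segments the animal holds a posture
archetype (curled-up, left/right lying, forward-facing, stretched) at a fixed
location and orientation.  Isotropic Gaussian jitter is added to every
keypoint each frame, and the nose receives extra archetype-specific noise so
that mean frame-to-frame nose displacement carries state information
(forward-facing scanning, cold-induced head movements).

Core body temperature follows a baseline with, for flagged torpor segments, a
sigmoid descent toward a nadir and a faster sigmoid rewarming, parameterized
so that Tb at the mobile->immobile transition is ``entry_tb`` and Tb at the
immobile->mobile transition is ``exit_tb``.

Default archetype geometry reproduces the measured posture of torpid
(curled-up: body length 42.32 mm, width 33.99 mm, head angle 117.75 deg) and
AMP-injected (stretched: 59.09 mm, 31.11 mm, 63.21 deg) mice; default cohort
sizes follow the recording design (torpor n=5, sleep n=6, cold n=6, each
recorded at 12 fps in a 259 x 234 mm cage).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import N_PARTS, PART_INDEX, PoseTrack, TbSeries
from .metrics import body_length, body_width, head_angle
from .segmentation import IMMOBILE, MOBILE

CONDITIONS = ("torpor", "sleep", "cold", "amp")

#: physical cage floor, mm (width x depth)
CAGE_MM = (259.0, 234.0)


# ---------------------------------------------------------------------------
# posture archetypes
# ---------------------------------------------------------------------------


@dataclass
class PostureArchetype:
    """A canonical body configuration in the egocentric frame.

    ``coords`` are (7, 2) mean keypoint positions in mm, math convention
    (y up), back at the origin and nose on the positive y axis.
    """

    name: str
    coords: np.ndarray
    jitter_sd: float = 0.1  # mm per keypoint per frame
    nose_movement_rate: float = 0.0  # extra mean nose displacement, mm/frame
    target_length: float = 0.0
    target_width: float = 0.0
    target_head_angle: float = 0.0

    def realized_geometry(self) -> tuple[float, float, float]:
        c = self.coords
        return float(body_length(c)), float(body_width(c)), float(head_angle(c))


def _symmetric_pose(
    length: float,
    width: float,
    head_angle_deg: float,
    nose_frac: float = 0.55,
    hip_y_frac: float = -0.20,
    ear_dist: float = 12.0,
) -> np.ndarray:
    """Mirror-symmetric pose realizing the three geometry targets exactly."""
    nose_y = nose_frac * length
    half = np.radians(head_angle_deg / 2.0)
    coords = np.zeros((N_PARTS, 2))
    coords[PART_INDEX["nose"]] = (0.0, nose_y)
    coords[PART_INDEX["right_ear"]] = (
        ear_dist * np.sin(half),
        nose_y - ear_dist * np.cos(half),
    )
    coords[PART_INDEX["left_ear"]] = (
        -ear_dist * np.sin(half),
        nose_y - ear_dist * np.cos(half),
    )
    coords[PART_INDEX["right_hip"]] = (width / 2.0, hip_y_frac * length)
    coords[PART_INDEX["left_hip"]] = (-width / 2.0, hip_y_frac * length)
    coords[PART_INDEX["tail_base"]] = (0.0, nose_y - length)
    return coords


def _lying_pose(side: str) -> np.ndarray:
    """A laterally displaced (side-lying) pose; left is the mirror of right."""
    base = _symmetric_pose(length=44.0, width=33.0, head_angle_deg=110.0)
    sign = 1.0 if side == "right" else -1.0
    shift = np.zeros((N_PARTS, 2))
    shift[PART_INDEX["right_ear"], 0] = sign * 6.0
    shift[PART_INDEX["left_ear"], 0] = sign * 6.0
    shift[PART_INDEX["right_hip"], 0] = sign * 5.0
    shift[PART_INDEX["left_hip"], 0] = sign * 5.0
    shift[PART_INDEX["tail_base"], 0] = sign * 8.0
    return base + shift


def _archetype_builders() -> dict[str, PostureArchetype]:
    curled = _symmetric_pose(42.32, 33.99, 117.75)
    stretched = _symmetric_pose(59.09, 31.11, 63.21)
    forward = _symmetric_pose(62.0, 24.0, 55.0)
    active = _symmetric_pose(58.0, 30.0, 75.0)
    table = {
        "curled_up": PostureArchetype(
            "curled_up", curled, nose_movement_rate=0.05, target_length=42.32,
            target_width=33.99, target_head_angle=117.75,
        ),
        "stretched": PostureArchetype(
            "stretched", stretched, target_length=59.09,
            target_width=31.11, target_head_angle=63.21,
        ),
        "forward_facing": PostureArchetype(
            "forward_facing", forward, nose_movement_rate=0.7
        ),
        "lying_right": PostureArchetype("lying_right", _lying_pose("right")),
        "lying_left": PostureArchetype("lying_left", _lying_pose("left")),
        "active": PostureArchetype("active", active),
    }
    for arch in table.values():
        if arch.target_length == 0.0:
            arch.target_length, arch.target_width, arch.target_head_angle = (
                arch.realized_geometry()
            )
    return table


ARCHETYPE_NAMES = tuple(_archetype_builders())


def make_archetype(name: str, overrides: dict | None = None) -> PostureArchetype:
    """Build a named archetype, optionally overriding keypoints or noise fields.

    ``overrides`` keys may be body-part names (value: (x, y) in egocentric mm)
    or the scalar fields ``jitter_sd`` / ``nose_movement_rate``.
    """
    table = _archetype_builders()
    if name not in table:
        raise ValueError(f"unknown archetype {name!r}; choose from {ARCHETYPE_NAMES}")
    arch = table[name]
    if overrides:
        coords = arch.coords.copy()
        kwargs: dict = {}
        for key, value in overrides.items():
            if key in PART_INDEX:
                coords[PART_INDEX[key]] = value
            elif key in ("jitter_sd", "nose_movement_rate"):
                kwargs[key] = float(value)
            else:
                raise ValueError(f"unknown override {key!r}")
        arch = replace(arch, coords=coords, **kwargs)
    return arch


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    state: str  # MOBILE or IMMOBILE
    archetype: str
    duration: float  # seconds; kept to multiples of 300 s by the builders
    overrides: dict | None = None
    tb_drop: bool = False  # torpor-style Tb excursion spans this segment


@dataclass
class TbParams:
    """Sigmoid entry/exit Tb trajectory parameters.

    Rewarming is faster than entry (``tau_exit`` < ``tau_entry``), and the
    sigmoids are anchored so Tb equals ``entry_tb`` at immobility onset and
    ``exit_tb`` at immobility offset of each flagged segment.
    """

    baseline: float = 36.5  # degC
    nadir: float = 31.0  # degC
    tau_entry: float = 1200.0  # s
    tau_exit: float = 480.0  # s
    entry_tb: float = 35.19  # degC at mobile->immobile transition
    exit_tb: float = 33.45  # degC at immobile->mobile transition
    noise_sd: float = 0.05  # degC measurement noise


@dataclass
class StateSchedule:
    segments: list[Segment]
    tb: TbParams = field(default_factory=TbParams)
    mobile_speed: float = 25.0  # mm/s of the back point during mobile segments

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)


def _minutes(plan: list[tuple[str, str, float, bool]]) -> list[Segment]:
    return [
        Segment(
            state=state,
            archetype=arch,
            duration=minutes * 60.0,
            tb_drop=drop,
        )
        for state, arch, minutes, drop in plan
    ]


# condition-specific immobile-archetype overrides: sleep curled-up bouts sit
# slightly less tightly curled (tail base ~2 mm less tucked) with more nose
# movement; cold curled-up bouts carry strong nose/head movement.  The
# condition contrast is deliberately subtle relative to the between-archetype
# geometry, so it lives in low-variance directions beyond PC1-PC2.
_SLEEP_CURL = {"tail_base": (0.0, -18.1), "nose_movement_rate": 0.22}
_COLD_CURL = {"tail_base": (0.0, -18.3), "nose_movement_rate": 0.9}


def _cycle(condition: str) -> list[tuple[str, str, float, bool]]:
    if condition == "torpor":  # 6-h cycle with two Tb-drop bouts
        return [
            (MOBILE, "active", 45, False),
            (IMMOBILE, "forward_facing", 15, False),
            (MOBILE, "active", 15, False),
            (IMMOBILE, "curled_up", 105, True),
            (MOBILE, "active", 30, False),
            (IMMOBILE, "curled_up", 20, False),
            (MOBILE, "active", 10, False),
            (IMMOBILE, "forward_facing", 15, False),
            (MOBILE, "active", 10, False),
            (IMMOBILE, "curled_up", 75, True),
            (MOBILE, "active", 20, False),
        ]
    if condition == "sleep":  # 2-h cycle mixing lying and curled bouts
        return [
            (MOBILE, "active", 20, False),
            (IMMOBILE, "lying_right", 25, False),
            (MOBILE, "active", 10, False),
            (IMMOBILE, "curled_up", 20, False),
            (MOBILE, "active", 10, False),
            (IMMOBILE, "lying_left", 20, False),
            (MOBILE, "active", 5, False),
            (IMMOBILE, "curled_up", 10, False),
        ]
    if condition == "cold":  # 1-h cycle of brief curled bouts
        return [
            (MOBILE, "active", 10, False),
            (IMMOBILE, "curled_up", 5, False),
            (MOBILE, "active", 5, False),
            (IMMOBILE, "curled_up", 10, False),
            (MOBILE, "active", 10, False),
            (IMMOBILE, "curled_up", 5, False),
            (MOBILE, "active", 15, False),
        ]
    if condition == "amp":  # 12-h cycle with one long stretched drop
        return [
            (MOBILE, "active", 120, False),
            (IMMOBILE, "forward_facing", 15, False),
            (MOBILE, "active", 45, False),
            (IMMOBILE, "stretched", 240, True),
            (MOBILE, "active", 120, False),
            (IMMOBILE, "stretched", 60, False),
            (MOBILE, "active", 120, False),
        ]
    raise ValueError(f"unknown condition {condition!r}; choose from {CONDITIONS}")


def default_schedule(condition: str, duration_h: float) -> StateSchedule:
    """The built-in segment plan for a condition, trimmed to the duration.

    Cycles repeat until the recording is filled; a segment straddling the end
    is truncated (durations stay multiples of 300 s when the duration is).
    """
    total = duration_h * 3600.0
    cycle = _cycle(condition)
    segments: list[Segment] = []
    elapsed = 0.0
    i = 0
    while elapsed < total - 1e-9:
        state, arch, minutes, drop = cycle[i % len(cycle)]
        seg = Segment(state, arch, min(minutes * 60.0, total - elapsed), tb_drop=drop)
        if condition == "sleep" and arch == "curled_up":
            seg.overrides = dict(_SLEEP_CURL)
        if condition == "cold" and arch == "curled_up":
            seg.overrides = dict(_COLD_CURL)
        segments.append(seg)
        elapsed += seg.duration
        i += 1
    return StateSchedule(segments=segments)


# ---------------------------------------------------------------------------
# Tb trajectory
# ---------------------------------------------------------------------------


def _logit(q: float) -> float:
    return float(np.log(q / (1.0 - q)))


def tb_trajectory(
    times: np.ndarray, schedule: StateSchedule, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Evaluate the schedule's Tb model at the given times (seconds)."""
    p = schedule.tb
    depth = p.baseline - p.nadir
    q_entry = (p.baseline - p.entry_tb) / depth
    q_exit = (p.baseline - p.exit_tb) / depth
    if not (0 < q_entry < 1 and 0 < q_exit < 1):
        raise ValueError("entry_tb and exit_tb must lie between nadir and baseline")
    temps = np.full_like(np.asarray(times, float), p.baseline)
    elapsed = 0.0
    for seg in schedule.segments:
        if seg.tb_drop:
            t0, t1 = elapsed, elapsed + seg.duration
            c1 = t0 - p.tau_entry * _logit(q_entry)
            c2 = t1 + p.tau_exit * _logit(q_exit)
            entry = 1.0 / (1.0 + np.exp(-(times - c1) / p.tau_entry))
            exit_ = 1.0 / (1.0 + np.exp(-(c2 - times) / p.tau_exit))
            temps = temps - depth * entry * exit_
        elapsed += seg.duration
    if rng is not None and p.noise_sd > 0:
        temps = temps + rng.normal(0.0, p.noise_sd, size=temps.shape)
    return temps


# ---------------------------------------------------------------------------
# recording generation
# ---------------------------------------------------------------------------


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect an unbounded walk into [lo, hi] (triangle-wave folding)."""
    width = hi - lo
    y = np.mod(x - lo, 2 * width)
    return lo + np.where(y > width, 2 * width - y, y)


def generate_recording(
    condition: str,
    duration_h: float = 24.0,
    fps: float = 12.0,
    schedule: StateSchedule | None = None,
    seed: int | np.random.SeedSequence = 0,
    px_per_mm: float = 2.0,
    animal_coord_sd: float = 0.6,
    bout_pose_sd: float = 0.8,
) -> tuple[PoseTrack, TbSeries, pd.DataFrame]:
    """Generate one animal's recording: pose track, Tb series, truth labels.

    Returns
    -------
    track : :class:`PoseTrack` in pixels, image convention, at ``fps``.
    tb : :class:`TbSeries` sampled every 5 min over the recording.
    truth : per-10-s-bin DataFrame with columns ``bin_start``, ``state``,
        ``archetype`` and ``segment`` (ground-truth labels).
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if schedule is None:
        schedule = default_schedule(condition, duration_h)
    total = duration_h * 3600.0
    if abs(schedule.total_duration - total) > 1e-6:
        raise ValueError(
            f"schedule covers {schedule.total_duration:.0f} s but the recording "
            f"lasts {total:.0f} s"
        )
    rng = np.random.default_rng(seed)
    n_frames = int(round(total * fps))

    # per-animal idiosyncrasy: stable keypoint offsets and a size factor
    offsets = rng.normal(0.0, animal_coord_sd, size=(N_PARTS, 2))
    size = float(np.exp(rng.normal(0.0, 0.03)))
    nose_scale = float(rng.normal(1.0, 0.05))

    margin = 45.0
    bounds_x = (margin, CAGE_MM[0] - margin)
    bounds_y = (margin, CAGE_MM[1] - margin)

    coords_mm = np.empty((n_frames, N_PARTS, 2))
    frame_of = lambda t: int(round(t * fps))  # noqa: E731
    elapsed = 0.0
    position = np.array(
        [rng.uniform(*bounds_x), rng.uniform(*bounds_y)]
    )
    heading = float(rng.uniform(0, 2 * np.pi))
    seg_rows = []
    for seg_id, seg in enumerate(schedule.segments):
        f0, f1 = frame_of(elapsed), frame_of(elapsed + seg.duration)
        nf = f1 - f0
        arch = make_archetype(seg.archetype, seg.overrides)
        # bout-to-bout posture variation: the archetype is held rigidly within
        # a segment but realized slightly differently each time it is adopted
        bout_jitter = rng.normal(0.0, bout_pose_sd, size=(N_PARTS, 2))
        pose = (arch.coords + offsets + bout_jitter) * size
        if seg.state == MOBILE:
            dtheta = rng.normal(0.0, 0.6 / np.sqrt(fps), size=nf)
            theta = heading + np.cumsum(dtheta)
            speed = np.abs(
                rng.normal(schedule.mobile_speed, schedule.mobile_speed / 4, size=nf)
            )
            steps = (speed / fps)[:, None] * np.stack(
                [np.cos(theta), np.sin(theta)], axis=1
            )
            path = position + np.cumsum(steps, axis=0)
            walk = np.stack(
                [
                    _fold(path[:, 0], *bounds_x),
                    _fold(path[:, 1], *bounds_y),
                ],
                axis=1,
            )
            # rotate the pose so its +y axis points along the heading
            rot = np.empty((nf, N_PARTS, 2))
            px, py = pose[:, 0], pose[:, 1]
            rot[..., 0] = (
                np.cos(theta - np.pi / 2)[:, None] * px
                - np.sin(theta - np.pi / 2)[:, None] * py
            )
            rot[..., 1] = (
                np.sin(theta - np.pi / 2)[:, None] * px
                + np.cos(theta - np.pi / 2)[:, None] * py
            )
            coords_mm[f0:f1] = walk[:, None, :] + rot
            position = walk[-1]
            heading = float(theta[-1])
        else:
            position = np.array([rng.uniform(*bounds_x), rng.uniform(*bounds_y)])
            heading = float(rng.uniform(0, 2 * np.pi))
            a = heading - np.pi / 2
            rot_pose = pose @ np.array(
                [[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]]
            )
            coords_mm[f0:f1] = position + rot_pose
        # per-frame isotropic jitter; extra nose noise realizes the
        # archetype's mean frame-to-frame nose displacement
        coords_mm[f0:f1] += rng.normal(0.0, arch.jitter_sd, size=(nf, N_PARTS, 2))
        # bout-level variability in micro-movement intensity
        rate = arch.nose_movement_rate * nose_scale * float(np.exp(rng.normal(0, 0.2)))
        if rate > 0:
            sigma_n = rate / (np.sqrt(2.0) * np.sqrt(np.pi / 2.0))
            coords_mm[f0:f1, PART_INDEX["nose"], :] += rng.normal(
                0.0, sigma_n, size=(nf, 2)
            )
        seg_rows.append(
            {
                "segment": seg_id,
                "state": seg.state,
                "archetype": seg.archetype,
                "start": elapsed,
                "end": elapsed + seg.duration,
                "tb_drop": seg.tb_drop,
            }
        )
        elapsed += seg.duration

    # math mm -> image px (y down)
    coords_px = coords_mm * px_per_mm
    coords_px[..., 1] = CAGE_MM[1] * px_per_mm - coords_px[..., 1]
    track = PoseTrack(
        frame_times=np.arange(n_frames) / fps,
        coords=coords_px,
        fps=fps,
        meta={"condition": condition, "px_per_mm": px_per_mm},
    )

    tb_times = np.arange(0.0, total + 1e-9, 300.0)
    tb = TbSeries(
        times=tb_times,
        temp_c=tb_trajectory(tb_times, schedule, rng),
        native_interval=300.0,
    )

    n_bins = int(np.floor(total / 10.0 + 1e-9))
    bin_starts = 10.0 * np.arange(n_bins)
    mid = bin_starts + 5.0
    seg_table = pd.DataFrame(seg_rows)
    seg_idx = np.searchsorted(seg_table["end"].to_numpy(), mid, side="right")
    seg_idx = np.clip(seg_idx, 0, len(seg_table) - 1)
    truth = pd.DataFrame(
        {
            "bin_start": bin_starts,
            "state": seg_table["state"].to_numpy()[seg_idx],
            "archetype": seg_table["archetype"].to_numpy()[seg_idx],
            "segment": seg_idx,
        }
    )
    return track, tb, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohortConfig:
    """Cohort layout; defaults follow the recording design (torpor and sleep
    recorded for 24 h, AMP and cold for 12 h, all at 12 fps)."""

    n_torpor: int = 5
    n_sleep: int = 6
    n_cold: int = 0
    n_amp: int = 0
    fps: float = 12.0
    px_per_mm: float = 2.0
    duration_h: dict = field(
        default_factory=lambda: {"torpor": 24.0, "sleep": 24.0, "cold": 12.0, "amp": 12.0}
    )
    #: condition label -> schedule family; remap to build null-control cohorts
    #: (e.g. {"torpor": "sleep"} gives torpor-labelled animals sleep schedules)
    schedule_for: dict = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {
            "torpor": self.n_torpor,
            "sleep": self.n_sleep,
            "cold": self.n_cold,
            "amp": self.n_amp,
        }


@dataclass
class AnimalRecording:
    animal_id: str
    condition: str
    track: PoseTrack
    tb: TbSeries
    truth: pd.DataFrame


@dataclass
class SyntheticCohort:
    animals: list[AnimalRecording]
    config: SyntheticCohortConfig
    seed: int

    def __iter__(self):
        return iter(self.animals)

    def __len__(self) -> int:
        return len(self.animals)


_ID_PREFIX = {"torpor": "T", "sleep": "S", "cold": "C", "amp": "A"}


def generate_cohort(
    config: SyntheticCohortConfig | None = None, seed: int = 0
) -> SyntheticCohort:
    """Generate a multi-animal, multi-condition cohort with ground truth.

    Per-animal seeds are spawned deterministically from the global seed, so
    the same seed always yields a bit-identical cohort.
    """
    config = config or SyntheticCohortConfig()
    counts = config.counts()
    if sum(counts.values()) == 0:
        raise ValueError("empty cohort config")
    root = np.random.SeedSequence(seed)
    animals: list[AnimalRecording] = []
    children = iter(root.spawn(sum(counts.values())))
    for condition in CONDITIONS:
        family = config.schedule_for.get(condition, condition)
        for i in range(counts[condition]):
            hours = config.duration_h[condition]
            track, tb, truth = generate_recording(
                condition,
                duration_h=hours,
                fps=config.fps,
                schedule=default_schedule(family, hours),
                seed=next(children),
                px_per_mm=config.px_per_mm,
            )
            animals.append(
                AnimalRecording(
                    animal_id=f"{_ID_PREFIX[condition]}{i + 1}",
                    condition=condition,
                    track=track,
                    tb=tb,
                    truth=truth,
                )
            )
    return SyntheticCohort(animals=animals, config=config, seed=seed)
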