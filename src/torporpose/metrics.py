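"""Per-frame locomotion and pre-defined posture metrics.

Three scalar descriptors summarize the top-down silhouette of the mouse:

* body length — Euclidean distance nose <-> tail base; shortens as the animal
  curls up at low body temperature,
* body width — distance between the hips; widens in the curled posture,
* head angle — angle at the nose formed by the segments to the two ears; small
  when the animal faces forward, large when the head is tucked in.

A fourth, body-bend angle (nose-back-tail base), captures spine flexion.
Locomotion is the per-frame displacement of the back point.  All metrics are
computed in the track's current units (px or mm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import PART_INDEX, PoseTrack

logger = logging.getLogger(__name__)


@dataclass
class MetricSeries:
    """A per-frame (or per-bin) scalar metric with units."""

    times: np.ndarray
    values: np.ndarray
    metric_name: str
    units: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")


@dataclass
class BinnedSeries:
    """Non-overlapping, contiguous fixed-duration bin aggregates."""

    bin_duration: float
    bin_starts: np.ndarray
    values: np.ndarray
    n_frames_per_bin: np.ndarray
    metric_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.bin_starts = np.asarray(self.bin_starts, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_frames_per_bin = np.asarray(self.n_frames_per_bin, dtype=int)

    @property
    def n_bins(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# geometry primitives (accept a single frame (7, 2) or a stack (n, 7, 2))
# ---------------------------------------------------------------------------


def _dist(coords: np.ndarray, a: str, b: str) -> np.ndarray:
    pa = coords[..., PART_INDEX[a], :]
    pb = coords[..., PART_INDEX[b], :]
    return np.linalg.norm(pa - pb, axis=-1)


def body_length(coords: np.ndarray) -> np.ndarray:
    """Nose-to-tail-base Euclidean distance."""
    return _dist(np.asarray(coords, float), "nose", "tail_base")


def body_width(coords: np.ndarray) -> np.ndarray:
    """Right-hip-to-left-hip Euclidean distance."""
    return _dist(np.asarray(coords, float), "right_hip", "left_hip")


def angle_at(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Angle (degrees) at vertex ``p2`` between the rays to ``p1`` and ``p3``.

    The two rays are normalized to unit vectors and the angle taken as the
    arc cosine of their dot product, clamped to [-1, 1] to absorb
    floating-point overshoot; the result lies in [0, 180].
    """
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("degenerate angle: zero-length vector at the vertex")
    cos = np.sum(v1 * v2, axis=-1) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def head_angle(coords: np.ndarray) -> np.ndarray:
    """Angle at the nose between the segments to the right and left ears."""
    coords = np.asarray(coords, float)
    return angle_at(
        coords[..., PART_INDEX["right_ear"], :],
        coords[..., PART_INDEX["nose"], :],
        coords[..., PART_INDEX["left_ear"], :],
    )


def body_bend_angle(coords: np.ndarray) -> np.ndarray:
    """Angle at the back between the segments to the nose and the tail base."""
    coords = np.asarray(coords, float)
    return angle_at(
        coords[..., PART_INDEX["nose"], :],
        coords[..., PART_INDEX["back"], :],
        coords[..., PART_INDEX["tail_base"], :],
    )


# ---------------------------------------------------------------------------
# track-level series
# ---------------------------------------------------------------------------


def locomotion(track: PoseTrack, use_nose_mix: bool = False) -> MetricSeries:
    """Per-frame displacement of the back point (frame 0 = 0).

    ``use_nose_mix=True`` enables a sensitivity variant that pairs the
    previous back x with the current nose x.
    """
    if track.n_frames < 2:
        raise ValueError("locomotion needs at least 2 frames")
    back = track.part("back")
    if use_nose_mix:
        nose = track.part("nose")
        dx = back[:-1, 0] - nose[1:, 0]
        dy = back[:-1, 1] - back[1:, 1]
        steps = np.hypot(dx, dy)
    else:
        steps = np.linalg.norm(np.diff(back, axis=0), axis=1)
    values = np.concatenate([[0.0], steps])
    return MetricSeries(
        times=track.frame_times,
        values=values,
        metric_name="locomotion",
        units=f"{track.units}/frame",
    )


def metric_series(track: PoseTrack, name: str) -> MetricSeries:
    """Compute a named posture metric over every frame of a track."""
    funcs = {
        "body_length": (body_length, track.units),
        "body_width": (body_width, track.units),
        "head_angle": (head_angle, "deg"),
        "body_bend_angle": (body_bend_angle, "deg"),
    }
    if name not in funcs:
        raise KeyError(f"unknown metric {name!r}; choose from {sorted(funcs)}")
    fn, units = funcs[name]
    return MetricSeries(
        times=track.frame_times, values=fn(track.coords), metric_name=name, units=units
    )


def bin_average(series: MetricSeries, bin_duration: float) -> BinnedSeries:
    """Average a frame-level series into fixed-duration bins.

    Bin count = floor(total duration / bin_duration); a trailing partial bin
    is dropped and logged.  Total duration counts one frame interval past the
    last sample, so a nominal 24 h recording fills exactly 288 five-minute
    bins.
    """
    if bin_duration <= 0:
        raise ValueError("bin_duration must be positive")
    t = series.times - series.times[0]
    if len(t) > 1:
        frame_interval = float(np.median(np.diff(t)))
    else:
        frame_interval = 0.0
    if frame_interval > 0 and bin_duration < frame_interval:
        raise ValueError("bin shorter than the frame interval")
    total = t[-1] + frame_interval if len(t) else 0.0
    n_bins = int(np.floor(total / bin_duration + 1e-9))
    if n_bins == 0:
        raise ValueError("series shorter than one bin")
    idx = np.floor(t / bin_duration + 1e-9).astype(int)
    in_range = idx < n_bins
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info("bin_average: dropped %d frames in trailing partial bin", n_dropped)
    sums = np.bincount(idx[in_range], weights=series.values[in_range], minlength=n_bins)
    counts = np.bincount(idx[in_range], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    return BinnedSeries(
        bin_duration=float(bin_duration),
        bin_starts=series.times[0] + bin_duration * np.arange(n_bins),
        values=means,
        n_frames_per_bin=counts,
        metric_name=series.metric_name,
        units=series.units,
    )


def normalize_01(series: BinnedSeries) -> BinnedSeries:
    """Min-max normalize a binned series to [0, 1] over the full recording."""
    v = series.values
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        warnings.warn("constant series: normalized values set to 0", stacklevel=2)
        normed = np.zeros_like(v)
    else:
        normed = (v - lo) / (hi - lo)
    return BinnedSeries(
        bin_duration=series.bin_duration,
        bin_starts=series.bin_starts,
        values=normed,
        n_frames_per_bin=series.n_frames_per_bin,
        metric_name=series.metric_name,
        units="normalized",
    )
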