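"""Egocentric alignment and the 12-dimensional posture feature set.

Each frame is translated so the back point sits at the origin and rotated so
the nose lies on the positive body axis, removing cage position and heading.
Because the back is the origin and the nose x is zero by construction, 11
informative coordinates remain (nose_y; x and y of both ears, both hips and
the tail base).  Mean frame-to-frame nose displacement — sensitive to subtle
sniffing/scanning movements invisible to whole-body metrics — is appended as
a 12th feature.

Input coordinates use the image convention (y down); alignment first flips to
a math-oriented frame (y up), so "nose up" means +y.  The rotation is proper
(no reflection): a mirror-image pose flips the sign of ear/hip x-coordinates
and stays distinguishable, which is what keeps left- and right-lying postures
apart downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PART_INDEX, PoseTrack
from .segmentation import BoutSet

#: Frozen feature order; classifier weights are reported against these names.
FEATURE_NAMES: tuple[str, ...] = (
    "nose_y",
    "right_ear_x",
    "right_ear_y",
    "left_ear_x",
    "left_ear_y",
    "right_hip_x",
    "right_hip_y",
    "left_hip_x",
    "left_hip_y",
    "tail_base_x",
    "tail_base_y",
    "nose_movement",
)

#: The 11 aligned-coordinate features (everything but nose_movement).
ALIGNED_COORD_NAMES: tuple[str, ...] = FEATURE_NAMES[:-1]

# (part, axis) pairs, in feature order, for the 11 aligned coordinates
_COORD_SELECT: list[tuple[int, int]] = [
    (PART_INDEX["nose"], 1),
    (PART_INDEX["right_ear"], 0),
    (PART_INDEX["right_ear"], 1),
    (PART_INDEX["left_ear"], 0),
    (PART_INDEX["left_ear"], 1),
    (PART_INDEX["right_hip"], 0),
    (PART_INDEX["right_hip"], 1),
    (PART_INDEX["left_hip"], 0),
    (PART_INDEX["left_hip"], 1),
    (PART_INDEX["tail_base"], 0),
    (PART_INDEX["tail_base"], 1),
]


@dataclass
class AlignedPose:
    """The 11 egocentric coordinates of a single frame (back at origin,
    nose on the positive y axis)."""

    values: np.ndarray  # (11,), ordered as ALIGNED_COORD_NAMES

    def __getitem__(self, name: str) -> float:
        return float(self.values[ALIGNED_COORD_NAMES.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(ALIGNED_COORD_NAMES, self.values.tolist()))


def align_frames(coords: np.ndarray) -> np.ndarray:
    """Egocentrically align a stack of frames.

    Parameters
    ----------
    coords : (n, 7, 2) or (7, 2) array in image convention (y down).

    Returns
    -------
    (n, 11) or (11,) array of aligned coordinates in feature order.
    """
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    # image y-down -> math y-up, then translate back to origin
    xy = coords.copy()
    xy[..., 1] *= -1.0
    xy -= xy[:, PART_INDEX["back"], None, :]
    nose = xy[:, PART_INDEX["nose"], :]
    r = np.linalg.norm(nose, axis=1)
    if np.any(r == 0):
        raise ValueError("degenerate heading: back and nose coincide")
    # proper rotation sending the nose vector (a, b) to (0, r)
    c = nose[:, 1] / r
    s = nose[:, 0] / r
    rx = c[:, None] * xy[..., 0] - s[:, None] * xy[..., 1]
    ry = s[:, None] * xy[..., 0] + c[:, None] * xy[..., 1]
    rot = np.stack([rx, ry], axis=-1)
    out = np.stack([rot[:, p, a] for p, a in _COORD_SELECT], axis=1)
    return out[0] if single else out


def align_pose(frame: np.ndarray) -> AlignedPose:
    """Align a single (7, 2) frame; see :func:`align_frames`."""
    return AlignedPose(values=align_frames(frame))


def nose_movement(track: PoseTrack, window: slice | np.ndarray | None = None) -> float:
    """Mean frame-to-frame Euclidean nose displacement over a frame window.

    Computed on raw (unaligned) coordinates: during immobile bouts global
    motion is negligible, so raw displacement reflects local nose movements.
    """
    nose = track.part("nose")
    if window is not None:
        nose = nose[window]
    if len(nose) < 2:
        raise ValueError("nose_movement needs a window of at least 2 frames")
    return float(np.mean(np.linalg.norm(np.diff(nose, axis=0), axis=1)))


def bin_features(
    track: PoseTrack, bin_duration: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin 12-dimensional posture feature vectors.

    Within each bin the 11 aligned coordinates are computed per frame and
    averaged coordinate-wise; nose movement is averaged over the bin's
    frame-to-frame displacements.  A trailing partial bin is dropped (the
    same convention as the 10-s immobility labels, so bins stay aligned).

    Returns
    -------
    features : (n_bins, 12) array in :data:`FEATURE_NAMES` order.
    bin_starts : (n_bins,) bin start times in seconds.
    """
    n_bins = int(np.floor(track.duration / bin_duration + 1e-9))
    if n_bins < 1:
        raise ValueError("track spans less than one bin")
    t = track.frame_times - track.frame_times[0]
    idx = np.floor(t / bin_duration + 1e-9).astype(int)
    in_range = idx < n_bins

    aligned = align_frames(track.coords)
    counts = np.bincount(idx[in_range], minlength=n_bins).astype(float)
    feats = np.empty((n_bins, 12), dtype=float)
    for j in range(11):
        sums = np.bincount(idx[in_range], weights=aligned[in_range, j], minlength=n_bins)
        feats[:, j] = sums / counts

    nose = track.part("nose")
    steps = np.linalg.norm(np.diff(nose, axis=0), axis=1)
    step_idx = idx[1:]  # attribute each step to the bin of the later frame
    ok = in_range[1:]
    step_sums = np.bincount(step_idx[ok], weights=steps[ok], minlength=n_bins)
    step_counts = np.bincount(step_idx[ok], minlength=n_bins).astype(float)
    with np.errstate(invalid="ignore"):
        feats[:, 11] = np.where(step_counts > 0, step_sums / np.maximum(step_counts, 1), 0.0)

    bin_starts = track.frame_times[0] + bin_duration * np.arange(n_bins)
    return feats, bin_starts


def bout_average_features(bouts: BoutSet, bin_feats: np.ndarray) -> np.ndarray:
    """Average per-bin feature vectors over each bout's bins.

    Returns an (n_bouts, 12) array, one bout-mean posture vector per bout.
    """
    bin_feats = np.asarray(bin_feats, dtype=float)
    out = np.empty((len(bouts), bin_feats.shape[1]), dtype=float)
    for i, bout in enumerate(bouts):
        if bout.end_bin >= len(bin_feats):
            raise ValueError(
                f"bout bins [{bout.start_bin}, {bout.end_bin}] exceed the "
                f"{len(bin_feats)} available feature bins"
            )
        out[i] = bin_feats[bout.start_bin : bout.end_bin + 1].mean(axis=0)
    return out
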