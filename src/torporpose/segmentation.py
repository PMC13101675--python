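"""Mobile/immobile segmentation, bout extraction and torpor-bout detection.

Two granularities are used, matching the two halves of the analysis:

* 5-min bins — normalized locomotion is bimodal (mobile vs immobile modes);
  a per-animal threshold is placed at the inflection point of a Gaussian KDE
  just right of the low-activity peak.  Long immobile bouts that reach core
  body temperature < 34 degC qualify as torpor bouts.
* 10-s bins — a bin is immobile when the cumulative back-point displacement
  within it is < 50 px; runs of >= 4 consecutive immobile bins (the "40-s
  rule") form the bouts used for posture clustering and classification.

Ties sit on the mobile side of every cutoff (immobility requires strictly
below threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .io import PoseTrack, TbSeries, interpolate_tb
from .metrics import BinnedSeries

MOBILE = "mobile"
IMMOBILE = "immobile"


@dataclass
class ActivityThresholdModel:
    """Per-animal KDE-based activity threshold on 5-min binned locomotion."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    threshold: float
    lower_peak: float


@dataclass
class Bout:
    """A maximal run of consecutive same-state bins (inclusive indices)."""

    start_bin: int
    end_bin: int
    state: str
    bin_duration: float
    animal_id: str = ""
    condition: str = ""

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_duration

    @property
    def start_time(self) -> float:
        return self.start_bin * self.bin_duration

    @property
    def end_time(self) -> float:
        return (self.end_bin + 1) * self.bin_duration


@dataclass
class BoutSet:
    """Ordered, non-overlapping bouts extracted from one label sequence."""

    bouts: list[Bout]
    bin_duration: float
    n_bins: int
    animal_id: str = ""
    condition: str = ""

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    def __getitem__(self, i):
        return self.bouts[i]


@dataclass
class TorporBout:
    """An immobile bout meeting the torpor rule, with its Tb landmarks."""

    bout: Bout
    min_tb: float
    entry_tb: float
    exit_tb: float


# ---------------------------------------------------------------------------
# KDE threshold
# ---------------------------------------------------------------------------


def kde_activity_threshold(
    loco_5min: BinnedSeries | np.ndarray, n_grid: int = 1000
) -> ActivityThresholdModel:
    """Fit a per-animal activity threshold from 5-min binned locomotion.

    A Gaussian KDE (Scott's-rule bandwidth) is evaluated on ``n_grid`` points
    spanning the data range.  The low-activity mode is the leftmost local
    maximum of the density; the threshold is the first inflection point right
    of it, located as the first sign change of the discrete second difference
    of the density.
    """
    values = loco_5min.values if isinstance(loco_5min, BinnedSeries) else np.asarray(
        loco_5min, float
    )
    if len(values) < 20:
        raise ValueError("need at least 20 bins to estimate an activity threshold")
    if np.ptp(values) == 0:
        raise ValueError("constant locomotion: no activity structure to threshold")

    kde = gaussian_kde(values, bw_method="scott")
    bandwidth = float(np.sqrt(kde.covariance[0, 0]))
    # pad the grid by 3 bandwidths so the evaluated density carries ~all mass
    grid = np.linspace(
        values.min() - 3 * bandwidth, values.max() + 3 * bandwidth, n_grid
    )
    density = kde(grid)

    d1 = np.diff(density)
    interior = np.where((d1[:-1] > 0) & (d1[1:] <= 0))[0] + 1
    if density[0] > density[1]:  # mode clipped at the left grid edge
        interior = np.concatenate([[0], interior])
    if len(interior) == 0:
        raise ValueError("no bimodal structure: density has no local maximum")
    peak_idx = int(interior[0])

    d2 = np.diff(density, 2)  # d2[i] ~ f''(grid[i+1])
    # at the peak f'' < 0; the first crossing to >= 0 right of it is the
    # inflection where the low-activity mode shoulders off
    crossing = None
    for i in range(max(peak_idx - 1, 0), len(d2) - 1):
        if d2[i] < 0 and d2[i + 1] >= 0:
            crossing = i + 2  # grid index of the first point past the crossing
            break
    if crossing is None:
        raise ValueError(
            "no bimodal structure: no inflection right of the low-activity peak "
            f"(peak at {grid[peak_idx]:.4g}, bandwidth {bandwidth:.4g})"
        )
    return ActivityThresholdModel(
        grid=grid,
        density=density,
        bandwidth=bandwidth,
        threshold=float(grid[crossing]),
        lower_peak=float(grid[peak_idx]),
    )


def classify_bins(
    loco_5min: BinnedSeries | np.ndarray, model: ActivityThresholdModel
) -> np.ndarray:
    """Label each 5-min bin mobile/immobile by the fitted threshold (< = immobile)."""
    values = loco_5min.values if isinstance(loco_5min, BinnedSeries) else np.asarray(
        loco_5min, float
    )
    return np.where(values < model.threshold, IMMOBILE, MOBILE)


# ---------------------------------------------------------------------------
# 10-s displacement rule
# ---------------------------------------------------------------------------


def immobile_bins_10s(
    track: PoseTrack,
    bin_duration: float = 10.0,
    displacement_cutoff: float = 50.0,
) -> np.ndarray:
    """Label 10-s bins immobile when cumulative back displacement < cutoff (px).

    The frame-to-frame step entering each bin is attributed to the bin of the
    later frame; a trailing partial bin is dropped.
    """
    if bin_duration > track.duration:
        raise ValueError("bin longer than the recording")
    back = track.part("back")
    steps = np.concatenate(
        [[0.0], np.linalg.norm(np.diff(back, axis=0), axis=1)]
    )
    t = track.frame_times - track.frame_times[0]
    n_bins = int(np.floor(track.duration / bin_duration + 1e-9))
    idx = np.floor(t / bin_duration + 1e-9).astype(int)
    in_range = idx < n_bins
    sums = np.bincount(idx[in_range], weights=steps[in_range], minlength=n_bins)
    return np.where(sums < displacement_cutoff, IMMOBILE, MOBILE)


# ---------------------------------------------------------------------------
# bout extraction
# ---------------------------------------------------------------------------


def extract_bouts(
    labels: np.ndarray,
    min_consecutive: int = 1,
    target_state: str = IMMOBILE,
    bin_duration: float = 10.0,
    animal_id: str = "",
    condition: str = "",
) -> BoutSet:
    """Extract maximal runs of ``target_state`` with length >= ``min_consecutive``."""
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    labels = np.asarray(labels)
    is_target = labels == target_state
    bouts: list[Bout] = []
    padded = np.concatenate([[False], is_target, [False]])
    changes = np.flatnonzero(np.diff(padded.astype(int)))
    for start, end in zip(changes[0::2], changes[1::2]):
        if end - start >= min_consecutive:
            bouts.append(
                Bout(
                    start_bin=int(start),
                    end_bin=int(end - 1),
                    state=target_state,
                    bin_duration=bin_duration,
                    animal_id=animal_id,
                    condition=condition,
                )
            )
    return BoutSet(
        bouts=bouts,
        bin_duration=bin_duration,
        n_bins=len(labels),
        animal_id=animal_id,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# torpor bouts
# ---------------------------------------------------------------------------


def detect_torpor_bouts(
    bouts: BoutSet,
    tb: TbSeries,
    min_duration: float = 30 * 60,
    tb_ceiling: float = 34.0,
    interp_interval: float = 10.0,
) -> list[TorporBout]:
    """Keep immobile bouts lasting >= ``min_duration`` s whose minimum Tb drops
    below ``tb_ceiling`` degC.

    Tb is linearly interpolated to ``interp_interval`` s; entry/exit Tb are
    read at the bin boundaries entering and leaving immobility.
    """
    fine = interpolate_tb(tb, interp_interval) if tb.native_interval != interp_interval else tb
    out: list[TorporBout] = []
    for bout in bouts:
        if bout.state != IMMOBILE or bout.duration < min_duration:
            continue
        t0, t1 = bout.start_time, bout.end_time
        if t0 < fine.times[0] - interp_interval or t1 > fine.times[-1] + interp_interval:
            warnings.warn(
                f"Tb series does not cover bout [{t0:.0f}, {t1:.0f}] s; skipped",
                stacklevel=2,
            )
            continue
        mask = (fine.times >= t0) & (fine.times <= t1)
        if not mask.any():
            warnings.warn(f"no Tb samples within bout [{t0:.0f}, {t1:.0f}] s; skipped")
            continue
        min_tb = float(fine.temp_c[mask].min())
        if min_tb >= tb_ceiling:
            continue
        out.append(
            TorporBout(
                bout=bout,
                min_tb=min_tb,
                entry_tb=float(fine.at(t0)),
                exit_tb=float(fine.at(t1)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# peri-bout profiles
# ---------------------------------------------------------------------------


@dataclass
class PeriBoutProfile:
    """Per-animal peri-bout trajectories on a normalized [0, 1] timescale."""

    norm_time: np.ndarray
    tb_mean: np.ndarray
    loco_mean: np.ndarray
    n_bouts: int
    truncated: bool = False


def peri_bout_profile(
    torpor_bouts: list[TorporBout],
    loco: BinnedSeries,
    tb: TbSeries,
    pad: float = 20 * 60,
    n_points: int = 101,
) -> PeriBoutProfile:
    """Average peri-bout Tb and locomotion trajectories for one animal.

    Each bout window spans ``pad`` seconds before onset to ``pad`` seconds
    after offset, resampled onto a common normalized [0, 1] grid, then
    averaged across the animal's bouts.  Windows reaching past the recording
    are truncated (clamped to the recorded range) and flagged.
    """
    if not torpor_bouts:
        raise ValueError("need at least one accepted torpor bout")
    grid = np.linspace(0.0, 1.0, n_points)
    loco_t = loco.bin_starts + loco.bin_duration / 2
    tb_traces, loco_traces = [], []
    truncated = False
    for tbout in torpor_bouts:
        w0 = tbout.bout.start_time - pad
        w1 = tbout.bout.end_time + pad
        lo = min(tb.times[0], loco_t[0])
        hi = max(tb.times[-1], loco_t[-1])
        if w0 < lo or w1 > hi:
            truncated = True
        times = np.clip(w0 + grid * (w1 - w0), lo, hi)
        tb_traces.append(np.interp(times, tb.times, tb.temp_c))
        loco_traces.append(np.interp(times, loco_t, loco.values))
    return PeriBoutProfile(
        norm_time=grid,
        tb_mean=np.mean(tb_traces, axis=0),
        loco_mean=np.mean(loco_traces, axis=0),
        n_bouts=len(torpor_bouts),
        truncated=truncated,
    )


def grand_mean_profile(per_animal: list[PeriBoutProfile]) -> PeriBoutProfile:
    """Average per-animal peri-bout profiles into a cohort grand mean."""
    if not per_animal:
        raise ValueError("no per-animal profiles")
    return PeriBoutProfile(
        norm_time=per_animal[0].norm_time,
        tb_mean=np.mean([p.tb_mean for p in per_animal], axis=0),
        loco_mean=np.mean([p.loco_mean for p in per_animal], axis=0),
        n_bouts=sum(p.n_bouts for p in per_animal),
        truncated=any(p.truncated for p in per_animal),
    )
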