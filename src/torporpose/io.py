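"""Reading, validation and unit handling for keypoint tables and Tb logger series.

Keypoint tables follow the DeepLabCut CSV dialect (three header rows:
scorer / bodyparts / coords, one ``x``/``y``/``likelihood`` column triple per
body part) or an equivalent flat table with ``<part>_x``, ``<part>_y`` and
optional ``<part>_likelihood`` columns.  Body-temperature logger series are
two-column timestamp/temperature tables sampled every 5 min by the implant.

Coordinates are kept in the image convention (y increases downward) at I/O;
conversion to a math-oriented egocentric frame happens only in
:mod:`torporpose.features`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path


import numpy as np
import pandas as pd

#: Canonical body-part order used for the third axis of every coordinate array.
BODY_PARTS: tuple[str, ...] = (
    "nose",
    "right_ear",
    "left_ear",
    "back",
    "right_hip",
    "left_hip",
    "tail_base",
)

#: name -> index into the part axis
PART_INDEX: dict[str, int] = {p: i for i, p in enumerate(BODY_PARTS)}

N_PARTS = len(BODY_PARTS)


class FormatError(ValueError):
    """Raised when an input table does not match the expected dialect."""


@dataclass
class PoseTrack:
    """Time-indexed (x, y) coordinates of the seven tracked body parts.

    Attributes
    ----------
    frame_times : (n_frames,) seconds since recording start, strictly increasing.
    coords : (n_frames, 7, 2) float array, parts ordered as :data:`BODY_PARTS`,
        in pixels (image convention, y down) or millimetres after
        :func:`scale_to_mm`.
    fps : frame rate of the recording.
    confidence : optional (n_frames, 7) per-part estimation confidence in [0, 1].
    scale_mm_per_px : set once the track has been converted to millimetres.
    interpolated_fraction : fraction of (frame, part) samples replaced by
        gap-filling at read time.
    """

    frame_times: np.ndarray
    coords: np.ndarray
    fps: float
    confidence: np.ndarray | None = None
    scale_mm_per_px: float | None = None
    interpolated_fraction: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_PARTS, 2):
            raise ValueError(
                f"coords must have shape (n, {N_PARTS}, 2), got {self.coords.shape}"
            )
        if len(self.frame_times) != len(self.coords):
            raise ValueError("frame_times and coords length mismatch")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.scale_mm_per_px is not None and self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be positive when set")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    @property
    def units(self) -> str:
        return "mm" if self.scale_mm_per_px is not None else "px"

    def part(self, name: str) -> np.ndarray:
        """(n_frames, 2) coordinates of one named body part."""
        return self.coords[:, PART_INDEX[name], :]

    @property
    def duration(self) -> float:
        """Nominal recording duration in seconds (frame count / fps)."""
        return self.n_frames / self.fps


@dataclass
class TbSeries:
    """Core body-temperature series from an intraperitoneal logger.

    ``native_interval`` is the sampling step of the source data in seconds
    (300 s for the logger); interpolated series keep the interval they were
    resampled to.
    """

    times: np.ndarray
    temp_c: np.ndarray
    native_interval: float

    PLAUSIBLE_RANGE_C: tuple[float, float] = (10.0, 45.0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if self.times.shape != self.temp_c.shape:
            raise ValueError("times and temp_c must have the same shape")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.temp_c)):
            raise ValueError("temperature values must be finite")
        lo, hi = self.PLAUSIBLE_RANGE_C
        if np.any((self.temp_c < lo) | (self.temp_c > hi)):
            warnings.warn(
                f"temperature outside the plausibility band [{lo}, {hi}] degC",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Temperature linearly interpolated at time(s) ``t`` (seconds)."""
        return np.interp(t, self.times, self.temp_c)


# ---------------------------------------------------------------------------
# pose track I/O
# ---------------------------------------------------------------------------


def _interp_low_confidence(
    coords: np.ndarray, confidence: np.ndarray, cutoff: float
) -> tuple[np.ndarray, float]:
    """Replace sub-cutoff samples by linear interpolation between flanking
    confident frames; edge gaps take the nearest confident value."""
    coords = coords.copy()
    n = len(coords)
    n_replaced = 0
    idx = np.arange(n)
    for p in range(coords.shape[1]):
        good = confidence[:, p] >= cutoff
        bad = ~good
        if not bad.any():
            continue
        if not good.any():
            raise FormatError(
                f"no frame of part '{BODY_PARTS[p]}' meets the confidence cutoff"
            )
        for axis in range(2):
            coords[bad, p, axis] = np.interp(
                idx[bad], idx[good], coords[good, p, axis]
            )
        n_replaced += int(bad.sum())
    return coords, n_replaced / (n * coords.shape[1])


def _parse_dlc_header(path: Path) -> pd.DataFrame | None:
    """Return the table if the file is in the DeepLabCut 3-header dialect."""
    head = pd.read_csv(path, nrows=3, header=None)
    first_col = [str(v).strip().lower() for v in head.iloc[:, 0]]
    if first_col[:3] == ["scorer", "bodyparts", "coords"]:
        return pd.read_csv(path, header=[0, 1, 2], index_col=0, float_precision="round_trip")
    return None


def read_pose_track(
    path: str | Path,
    confidence_cutoff: float = 0.6,
    fps: float = 12.0,
) -> PoseTrack:
    """Read a keypoint table into a :class:`PoseTrack`.

    Accepts the DeepLabCut CSV dialect or a flat table with ``<part>_x``,
    ``<part>_y`` and optional ``<part>_likelihood`` columns.  Samples whose
    confidence falls below ``confidence_cutoff`` are replaced by linear
    interpolation between the flanking confident frames (edge gaps: nearest
    confident value); the replaced fraction is recorded on the track.
    """
    if not 0.0 <= confidence_cutoff <= 1.0:
        raise ValueError("confidence_cutoff must lie in [0, 1]")
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"empty file: {path}")

    dlc = _parse_dlc_header(path)
    if dlc is not None:
        # columns: (scorer, bodypart, coord); body part names may use spaces
        bodyparts = {str(c[1]).strip().lower().replace(" ", "_") for c in dlc.columns}
        cols: dict[str, dict[str, np.ndarray]] = {}
        for scorer, part, coord in dlc.columns:
            key = str(part).strip().lower().replace(" ", "_")
            cols.setdefault(key, {})[str(coord).strip().lower()] = dlc[
                (scorer, part, coord)
            ].to_numpy(dtype=float)
        frame_index = dlc.index.to_numpy(dtype=float)
    else:
        flat = pd.read_csv(path, float_precision="round_trip")
        cols = {}
        for part in BODY_PARTS:
            entry = {}
            for coord in ("x", "y", "likelihood"):
                name = f"{part}_{coord}"
                if name in flat.columns:
                    entry[coord] = flat[name].to_numpy(dtype=float)
            if entry:
                cols[part] = entry
        frame_index = (
            flat["frame"].to_numpy(dtype=float)
            if "frame" in flat.columns
            else np.arange(len(flat), dtype=float)
        )

    for part in BODY_PARTS:
        if part not in cols or "x" not in cols[part] or "y" not in cols[part]:
            raise FormatError(f"missing body part column(s) for '{part}'")

    n = len(frame_index)
    if n == 0:
        raise FormatError(f"no frames in {path}")
    if n > 1 and not np.all(np.diff(frame_index) > 0):
        raise FormatError("frame index is not strictly increasing")

    coords = np.empty((n, N_PARTS, 2), dtype=float)
    confidence = np.ones((n, N_PARTS), dtype=float)
    has_conf = False
    for i, part in enumerate(BODY_PARTS):
        coords[:, i, 0] = cols[part]["x"]
        coords[:, i, 1] = cols[part]["y"]
        if "likelihood" in cols[part]:
            confidence[:, i] = cols[part]["likelihood"]
            has_conf = True

    interp_frac = 0.0
    if has_conf:
        coords, interp_frac = _interp_low_confidence(
            coords, confidence, confidence_cutoff
        )

    return PoseTrack(
        frame_times=frame_index / fps,
        coords=coords,
        fps=fps,
        confidence=confidence if has_conf else None,
        interpolated_fraction=interp_frac,
        meta={"source": str(path)},
    )


def write_pose_track(
    track: PoseTrack, path: str | Path, scorer: str = "torporpose"
) -> None:
    """Write a track in the DeepLabCut CSV dialect (round-trips exactly)."""
    columns = pd.MultiIndex.from_tuples(
        [
            (scorer, part, coord)
            for part in BODY_PARTS
            for coord in ("x", "y", "likelihood")
        ],
        names=["scorer", "bodyparts", "coords"],
    )
    conf = (
        track.confidence
        if track.confidence is not None
        else np.ones((track.n_frames, N_PARTS))
    )
    data = np.empty((track.n_frames, N_PARTS * 3), dtype=float)
    data[:, 0::3] = track.coords[:, :, 0]
    data[:, 1::3] = track.coords[:, :, 1]
    data[:, 2::3] = conf
    frame = pd.DataFrame(data, columns=columns)
    frame.index = np.round(track.frame_times * track.fps).astype(int)
    frame.to_csv(path, index_label=None, float_format="%.17g")


# ---------------------------------------------------------------------------
# body-temperature I/O
# ---------------------------------------------------------------------------


def read_tb_series(
    path: str | Path,
    time_column: str | None = None,
    temp_column: str | None = None,
) -> TbSeries:
    """Read a logger CSV (timestamp + temperature columns) into a :class:`TbSeries`.

    Timestamps may be elapsed seconds or ISO-8601; ISO timestamps are converted
    to seconds since the first sample.  The native sampling interval is
    inferred from the median spacing.
    """
    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    if table.shape[1] < 2:
        raise FormatError("logger table needs a timestamp and a temperature column")
    tcol = time_column or table.columns[0]
    vcol = temp_column or table.columns[1]
    if table.shape[0] < 2:
        raise FormatError("logger table needs at least 2 rows")

    temps = pd.to_numeric(table[vcol], errors="coerce")
    if temps.isna().any():
        row = int(np.argmax(temps.isna().to_numpy()))
        raise FormatError(
            f"non-numeric temperature {table[vcol].iloc[row]!r} at row {row}"
        )

    raw_times = table[tcol]
    numeric = pd.to_numeric(raw_times, errors="coerce")
    if numeric.notna().all():
        times = numeric.to_numpy(dtype=float)
    else:
        stamps = pd.to_datetime(raw_times, errors="coerce")
        if stamps.isna().any():
            row = int(np.argmax(stamps.isna().to_numpy()))
            raise FormatError(f"unparsable timestamp at row {row}")
        times = (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy()

    native = float(np.median(np.diff(times)))
    return TbSeries(times=times, temp_c=temps.to_numpy(dtype=float), native_interval=native)


def write_tb_series(tb: TbSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": tb.times, "temp_c": tb.temp_c}).to_csv(
        path, index=False, float_format="%.17g"
    )


def interpolate_tb(tb: TbSeries, interval: float = 10.0) -> TbSeries:
    """Resample a Tb series to a regular grid by linear interpolation.

    The grid runs from the first to the last native time in steps of
    ``interval`` seconds; native endpoints are preserved exactly.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if tb.n_samples < 2:
        raise ValueError("need at least 2 samples to interpolate")
    n_steps = int(np.floor((tb.times[-1] - tb.times[0]) / interval + 1e-9))
    grid = tb.times[0] + interval * np.arange(n_steps + 1)
    values = np.interp(grid, tb.times, tb.temp_c)
    return TbSeries(times=grid, temp_c=values, native_interval=interval)


def scale_to_mm(track: PoseTrack, cage_px: float, cage_mm: float) -> PoseTrack:
    """Convert a pixel-space track to millimetres from the on-screen cage size.

    Slight camera-height differences between sessions change the pixel scale;
    dividing the physical cage dimension by its on-screen extent gives the
    session-specific mm/px factor applied to every coordinate.
    """
    if cage_px <= 0 or cage_mm <= 0:
        raise ValueError("cage_px and cage_mm must be positive")
    if track.scale_mm_per_px is not None:
        raise ValueError("track is already in millimetres")
    factor = cage_mm / cage_px
    return replace(track, coords=track.coords * factor, scale_mm_per_px=factor)
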