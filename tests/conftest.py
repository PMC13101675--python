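import numpy as np
import pytest

from torporpose import PoseTrack
from torporpose.io import BODY_PARTS, PART_INDEX


def make_track(coords, fps=12.0, **kw):
    coords = np.asarray(coords, dtype=float)
    return PoseTrack(
        frame_times=np.arange(len(coords)) / fps, coords=coords, fps=fps, **kw
    )


def frame_from_dict(parts: dict) -> np.ndarray:
    """Build a (7, 2) frame from a {part: (x, y)} dict (missing parts at 0)."""
    frame = np.zeros((len(BODY_PARTS), 2))
    for name, xy in parts.items():
        frame[PART_INDEX[name]] = xy
    return frame


@pytest.fixture(scope="session")
def small_cohort():
    """A small torpor+sleep cohort shared by pipeline-level tests."""
    import torporpose as tp

    cfg = tp.SyntheticCohortConfig(
        n_torpor=3,
        n_sleep=3,
        fps=2.0,
        duration_h={"torpor": 12.0, "sleep": 12.0, "cold": 12.0, "amp": 12.0},
    )
    return tp.generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def torpor_recording():
    """One 12-h torpor recording at 2 fps with its Tb series and truth."""
    import torporpose as tp

    return tp.generate_recording("torpor", duration_h=12, fps=2.0, seed=5)
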