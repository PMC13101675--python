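"""Compute the pre-defined posture metrics on a synthetic recording.

Body length (nose-tail base), body width (hip-hip) and head angle (at the
nose, between the ears) summarize the silhouette: a torpid mouse is short,
wide and has a large head angle; an AMP-injected (stretched) mouse is long
with a small head angle.
"""

import numpy as np

import torporpose as tp

for condition in ("torpor", "amp"):
    track, tb, truth = tp.generate_recording(condition, duration_h=6, fps=2, seed=3)
    # convert pixels to mm from the on-screen cage size (259 mm wide)
    track_mm = tp.scale_to_mm(track, cage_px=518, cage_mm=259)
    # restrict to frames where the interpolated Tb is below 34 degC
    tb10 = tp.interpolate_tb(tb, 10.0)
    mask = tb10.at(track_mm.frame_times) < 34.0
    coords = track_mm.coords[mask]
    print(f"{condition}: {mask.sum()} frames with Tb < 34 degC")
    print(f"  body length {np.mean(tp.body_length(coords)):6.2f} mm")
    print(f"  body width  {np.mean(tp.body_width(coords)):6.2f} mm")
    print(f"  head angle  {np.mean(tp.head_angle(coords)):6.2f} deg")
# Torpor prints near 42 mm / 34 mm / 118 deg (curled up) and AMP near
# 59 mm / 31 mm / 63 deg (stretched): same hypothermia, opposite posture.
# A single animal deviates by a few mm / degrees (individual pose variation);
# cohort averages converge on the archetype geometry.
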