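"""Generate a synthetic fasting (torpor) recording and inspect its parts.

A recording is a 7-keypoint pose track (DeepLabCut-style coordinates, image
convention), a core body-temperature series sampled every 5 min, and
ground-truth 10-s state labels.
"""

import torporpose as tp

track, tb, truth = tp.generate_recording("torpor", duration_h=6, fps=2, seed=7)

print(f"frames: {track.n_frames} at {track.fps} fps ({track.duration / 3600:.0f} h)")
print(f"Tb samples: {tb.n_samples} every {tb.native_interval:.0f} s")
print(f"Tb range: {tb.temp_c.min():.1f}-{tb.temp_c.max():.1f} degC "
      "(the dip below 34 degC marks torpor bouts)")
print(truth["state"].value_counts().to_string())
print("truth archetypes:", sorted(truth["archetype"].unique()))
# The immobile bins with a curled_up archetype and low Tb are the torpor
# episodes every downstream analysis tries to find from the data alone.
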