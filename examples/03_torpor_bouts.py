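"""Segment locomotion, detect torpor bouts, and read entry/exit temperatures.

Locomotion (back-point displacement) is averaged into 5-min bins and
normalized; a per-animal KDE threshold splits the bimodal distribution into
mobile and immobile bins.  Immobile bouts lasting >= 30 min whose Tb drops
below 34 degC are torpor bouts.
"""

import torporpose as tp

track, tb, _ = tp.generate_recording("torpor", duration_h=12, fps=2, seed=5)

loco = tp.normalize_01(tp.bin_average(tp.locomotion(track), 300.0))
model = tp.kde_activity_threshold(loco)
print(f"KDE activity threshold: {model.threshold:.3f} "
      f"(low-activity peak at {model.lower_peak:.3f})")

labels = tp.classify_bins(loco, model)
bouts = tp.extract_bouts(labels, min_consecutive=1, bin_duration=300.0)
torpor_bouts = tp.detect_torpor_bouts(bouts, tb)
print(f"immobile bouts: {len(bouts)}; torpor bouts: {len(torpor_bouts)}")
for t in torpor_bouts:
    print(
        f"  bout {t.bout.start_time / 3600:.1f}-{t.bout.end_time / 3600:.1f} h: "
        f"min Tb {t.min_tb:.2f}, entry {t.entry_tb:.2f}, exit {t.exit_tb:.2f} degC"
    )
# Entry Tb (~35.2 degC) exceeds exit Tb (~33.5 degC): the mouse stops moving
# while still warm and resumes only after partial rewarming.

profile = tp.peri_bout_profile(torpor_bouts, loco, tb)
print(f"peri-bout profile: {len(profile.norm_time)} points, "
      f"Tb {profile.tb_mean.min():.1f}-{profile.tb_mean.max():.1f} degC")
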