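"""Generate one synthetic quiet-stance trial and summarize its sway.

The simulator produces ground-truth segment angles, six body-frame IMU
streams, and force-plate channels that are all physically consistent with
one another.  The printed numbers are the classic stabilogram summary
statistics of the ground-truth CoM: maximum sway range and RMS sway, in mm,
for the anteroposterior (AP) and mediolateral (ML) axes.
"""
import numpy as np

from comsway import SimConfig, make_trial, sway_stats

trial = make_trial(SimConfig(seed=1, duration=120.0, stance="narrow"))

for axis in ("ap", "ml"):
    series = trial.truth_com.axis(axis)
    rng_mm, rms_mm = sway_stats(series)
    print(f"{axis.upper()} truth CoM: range = {rng_mm:5.2f} mm, "
          f"RMS = {rms_mm:4.2f} mm")

fz = trial.bundle.forceplate.force[:, 2]
print(f"plate vertical load: {np.mean(-fz):.1f} N "
      f"(participant mass {trial.config.participant.mass:.0f} kg)")
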