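"""Simulate one participant and run the signal-cleaning cascade.

Shows the raw-channel statistics, what each pupil filter stage removed,
and the fully interpolated mean-pupil signal.
"""

import numpy as np

import stereovr as sv
from stereovr.simulate import CONTROL_PROFILE, simulate_participant

part = simulate_participant("C00", "control", CONTROL_PROFILE, np.random.SeedSequence(0))
log = part.log
print(f"simulated run: {len(log.t)} frames, {log.t[-1]:.1f} s, "
      f"{len(log.events)} stimuli, {part.truth['n_blinks']} blinks injected")

signals = sv.clean(log)
print(f"blink samples masked: {int(signals.blink_mask.sum())}")
for eye, stages in (("left", signals.stages_l), ("right", signals.stages_r)):
    counts = stages.rejected_counts()
    kept = int(stages.final.sum())
    print(f"{eye} pupil: rejected per stage {counts}; retained {kept}/{len(log.t)}")

# After merging both eyes and PCHIP interpolation there are no gaps left.
assert np.isfinite(signals.pupil_mean).all()
print(f"mean pupil: {signals.pupil_mean.mean():.2f} mm "
      f"(range {signals.pupil_mean.min():.2f}-{signals.pupil_mean.max():.2f} mm), no missing samples")
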