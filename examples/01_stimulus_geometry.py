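"""Stimulus geometry: disparity quantum, near-ball distance, schedule.

Builds the default 81-stimulus design and prints the solved viewing
geometry for each difficulty level.
"""

import stereovr as sv
from stereovr.geometry import recovered_disparity_arcsec

headset = sv.HeadsetSpec()  # 110° FoV, 1440 px, 90 Hz, 6.3 cm IPD
dd_min = sv.min_disparity_difference(headset)
print(f"disparity quantum: {dd_min:.1f}\" per pixel")
print(f"(with a 107° FoV it would be {sv.min_disparity_difference(sv.HeadsetSpec(fov_deg=107)):.1f}\")")
print()

# The near ball sits at distance D < 200 cm so that the disparity
# difference against the three far balls equals the requested multiple
# of the quantum.  Larger disparity = nearer ball = easier task.
print("Θ (arcsec)   D (cm)    Δd (cm)   size scale s   round-trip Θ")
for theta in (275.0, 550.0, 1100.0):
    sol = sv.solve_target_distance(theta, ipd_cm=6.3, D_total_cm=200.0)
    print(
        f"{theta:10.0f} {sol.D_cm:9.2f} {sol.delta_d_cm:9.2f} {sol.scale_s:12.4f}"
        f" {recovered_disparity_arcsec(sol):14.3f}"
    )
print()

schedule = sv.build_trial_schedule(seed=0)
print(f"schedule: {len(schedule)} stimuli "
      f"({len(schedule.disparities)} disparities x {len(schedule.positions)} positions x "
      f"{schedule.repetitions} repetitions), seeded random order")
first = schedule.stimuli[0]
print(f"first stimulus: {first.disparity_arcsec:.0f}\" at {first.position_label}, "
      f"near ball = {first.target_ball}")
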