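"""From raw 3D centre-out reaches to an epoch-level adaptation series.

Synthetic reaches to the 8 corners of a 10 cm cube carry a known injected
aiming angle; the preprocessing chain (onset detection at 3 cm/s, 50-step
duration normalisation, projection into the perturbed plane, baseline
correction, angle at half distance, 8-trial epochs) recovers it.
"""

import numpy as np

from adapt2state.preprocessing import process_trajectories
from adapt2state.surrogate import synth_trajectories

baseline = synth_trajectories(40, aim_angle=0.0, plane="coronal",
                              noise_sd=0.15, seed=1, phase="baseline")
adapted = synth_trajectories(24, aim_angle=22.0, plane="coronal",
                             noise_sd=0.15, seed=2, phase="perturbation",
                             start_trial=40)

run = process_trajectories(baseline + adapted, plane="coronal")
pert = [y for y, lab in zip(run.y, run.schedule.phase) if lab == "perturbation"]
print(f"trials in: {len(baseline) + len(adapted)}  ->  epochs out: {len(run)}")
print("epoch angles (deg):", np.round(run.y, 2))
print(f"mean perturbation-phase angle: {np.mean(pert):.2f} deg "
      "(injected ground truth: 22.00 deg)")
print("\nBaseline epochs sit near 0 by construction of the baseline "
      "correction; perturbation epochs recover the injected re-aim angle.")
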