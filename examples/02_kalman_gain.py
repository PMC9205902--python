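"""Steady-state Kalman gain from planning and measurement variabilities.

The gain K weights how much of the experienced error an optimal learner
should correct: planning noise (uncertainty injected at the state update)
raises K, sensory measurement noise lowers it.
"""

from adapt2state import steady_state_kalman_gain, steady_state_variance

cases = [
    ("typical observer", 1.5, 6.0),
    ("noisy planner   ", 6.0, 1.5),
    ("noisy senses    ", 0.5, 12.0),
]
print("condition           sigma_x^2  sigma_u^2   sigma_X+^2      K")
for label, vx, vu in cases:
    v_plus = steady_state_variance(vx, vu)
    gain = steady_state_kalman_gain(vx, vu)
    print(f"{label}   {vx:8.1f}  {vu:9.1f}   {v_plus:9.3f}  {gain:6.3f}")
print("\nK near 1: trust the error and correct fast; K near 0: distrust "
      "the (noisy) feedback and adapt slowly.")
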