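"""Recover injected per-step response delays by set-point reconstruction.

A synthetic joystick response is built by delaying the first target step by
150 ms and the second by 400 ms, smoothing through a first-order lag and
adding 5% measurement noise.  Stage 1 shifts the step instants to optimize
a zero-dead-time LTI fit and recovers the two delays.
"""

import numpy as np
from scipy.signal import lfilter

from ictrack import make_step_sequence
from ictrack.reconstruction import reconstruct_trial, render_steps

DT = 0.001
seq = make_step_sequence("rev_RL", isi=0.3)
injected = np.array([0.150, 0.400])

n = round((seq.step_times[-1] + 1.2) / DT)
shifted = render_steps(np.asarray(seq.step_times) + injected, seq.step_levels, DT, n)
a1 = np.exp(-DT / 0.05)  # 50 ms neuromuscular-style lag
rng = np.random.default_rng(0)
u = lfilter([1 - a1], [1, -a1], shifted) + rng.normal(0, 0.05, n)

rec = reconstruct_trial(u, seq, DT)
print(f"injected delays : RT1 = {injected[0]:.3f} s, RT2 = {injected[1]:.3f} s")
print(f"recovered       : RT1 = {rec.delays[0]:.3f} s, RT2 = {rec.delays[1]:.3f} s")
print(f"time-invariant (common) delay stage gave {rec.common_delay:.3f} s;")
print("the per-step stage splits it into the two true latencies "
      "(10 ms reconstruction grid).")
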