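"""The semi-synchronous division wave after growth-factor stimulation.

Quiescent cells need to exit G0 (~8 h) and traverse a full cycle (~21 h)
before the first division, so the population birth rate b(t) stays low for
~20 h, peaks near 30 h and decays again. This script simulates 100 wells at
saturating dose, averages the smoothed per-well rate curves and prints the
wave timing.
"""

import numpy as np

import kirscreen as ks
from kirscreen.kinetics import average_rate_timecourse

cfg = ks.SimConfig()
trajs = [
    ks.simulate_well(cfg, ks.WellCondition(growth_factor="FGF2", gf_dose=50.0), seed=s)
    for s in range(100)
]
curve = average_rate_timecourse(trajs, smoothing_hours=10.0)

peak_i = int(np.nanargmax(curve.b_t))
half = curve.b_t[peak_i] / 2.0
rise = curve.times[np.argmax(curve.b_t > half)]
print(f"birth rate peaks at {curve.times[peak_i]:.0f} h "
      f"(b = {curve.b_t[peak_i]:.4f} /cell/h)")
print(f"rise above half-max at ~{rise:.0f} h post stimulation")
print("\nhour  b(t)/h")
for t, b in zip(curve.times[::2], curve.b_t[::2]):
    bar = "#" * int(round(b * 4000))
    print(f"{t:4.0f}  {b:7.4f} {bar}")

print(
    "\nThe wave reflects synchronous G0 exit: low birth before ~20 h, a peak "
    "near 30 h, and decay once the committed fraction has divided."
)
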