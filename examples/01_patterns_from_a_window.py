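"""Extract the patterns-over-time of a single sensor window.

Builds one 64-sample window mixing a rising ramp with a fast oscillation,
splits it into oscillatory / steady segments, and prints the variation
values and range features the canvas encoding is built from.
"""

import numpy as np

from imucanvas import SensorWindow, classify_segments, extract

t = np.arange(64)
values = np.where(t < 32, 0.1 * t, 3.2 + 0.8 * (-1.0) ** t)  # ramp, then alternation
window = SensorWindow(window_index=0, axis="sx", values=values, label="demo")

print("segments (kind, start, end):")
for seg in classify_segments(values):
    print(f"  {seg.kind:<12} [{seg.start:2d}, {seg.end:2d}]  k={seg.k}")

pv = extract(window)
print(f"\nvp_osc     = {pv.vp_osc:.4f}   # mean |step| inside oscillatory runs")
print(f"vp_steady  = {pv.vp_steady:.4f}   # mean |step| inside monotone runs")
print(f"range_max  = {pv.range_max:.4f}, range_min = {pv.range_min:.4f}, "
      f"range_diff = {pv.range_diff:.4f}")
print("\nThe ramp contributes ~0.1 per step to the steady value; the "
      "alternating tail flips by 1.6 per step, which dominates vp_osc.")
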