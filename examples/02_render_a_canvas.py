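"""Render one neighbor-colored canvas image from a synthetic stream.

Generates a short 3-axis stream, windows it, calibrates the value->pixel
mapping, renders the window at index 5 with the alternating CCW/CW fill
schedule, and writes the PNG (with provenance metadata) to scratch/.
"""

from pathlib import Path

import numpy as np

from imucanvas import CanvasSpec, WindowSpec, baseline_layout, read_image
from imucanvas.pipeline import calibrate_on, prepare_patterns, render_window
from imucanvas.synthetic import AxisParams, ClassSpec, generate_stream

cspec = ClassSpec(label="walk-like", axes={
    a: AxisParams(osc_amplitude=amp, osc_period=4, noise_sd=0.05)
    for a, amp in (("sx", 1.2), ("sy", 0.9), ("sz", 1.5))
})
stream = generate_stream(cspec, 10 * 128, np.random.default_rng(0))
patterns = prepare_patterns([stream], WindowSpec(128))
stats = calibrate_on(patterns, range(len(patterns)))

canvas = CanvasSpec(Px=20, Py=20, C=3)  # 120 x 120 px image
img = render_window(patterns, 5, baseline_layout(), canvas, stats, "neighbor")

out = Path("scratch/example_canvas.png")
out.parent.mkdir(exist_ok=True)
from imucanvas import write_image

write_image(img, out)
back = read_image(out)

print(f"wrote {out}: {img.width}x{img.height}, {img.channels} channels")
print(f"provenance: {back.provenance}")
mask = render_window(patterns, 5, baseline_layout(), canvas, stats, "bw")
marked = int((mask.pixels > 0).sum())
print(f"{marked} of {img.width * img.height} pixels are marked;")
print("each 20x20 region's marked-area size encodes one pattern value of one")
print("axis for spans u (two windows before), w (current), v (two after).")
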