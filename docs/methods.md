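# Methods

This note documents the model behind `imucanvas`, the parameters that
matter, the numerical choices, what the synthetic benchmark does and does
not establish, and the design decisions taken where the design was open.

## Signal model and windowing

Input is a multivariate inertial time series (one or more sensors, up to
three axes each) with per-sample activity labels. Windows are
**non-overlapping** and index-based; timestamps are carried as metadata
only. The window length is a required configuration parameter (default 128
samples, a common HAR choice at 50 Hz ≈ 2.5 s); the encoding itself is
length-agnostic. A window's label is the majority of its sample labels,
ties broken by the lexicographically first label so that the pipeline is
deterministic.

Each window is viewed with its four nearest neighbors: spans *u* = {w−2,
w−1}, *w* = {w₀}, *v* = {w+1, w+2}. At stream boundaries, absent neighbors
contribute pattern value 0 (the minimum after calibration) and are flagged
in image provenance; this keeps edge windows usable instead of discarding
them.

## Patterns over time

Every interior sample is classified by its 3-point triple: strict local
extremum → oscillatory; anything else (strictly monotone, or any equality)
→ steady. Plateaus land in "steady" because oscillation requires *strict*
extrema, leaving steady as the residual class; plateau steps contribute 0
to the value, so this choice only affects bookkeeping, not magnitudes.
Maximal runs of one kind become segments spanning one point on either side
of the run, so adjacent segments of different kinds share their boundary
points and every segment has k ≥ 3 points.

The variation value pools all segments of one kind:
`vp = Σ|d_i − d_{i−1}| / Σ(k_seg − 1)`, differences taken within segments
only. Differences are **absolute**: the signed sum would telescope to
(d_k − d_1)/(k − 1), which is ~0 for any oscillation and would make the
oscillatory pattern carry no information. `vp` is invariant under constant
shifts, scales linearly with the signal, and is bounded by the window's
largest absolute step — all property-tested.

Range features are the window max, min, and max−min. Only max and max−min
receive canvas regions; min is computed and exposed but not placed, since
max and max−min already determine it.

## Canvas, calibration, and filling

The default canvas is 6×6 regions in four 3×3 quadrants (osc, steady,
range-max, range-diff), rows = axes, columns = spans u/w/v. The mapping
from pattern value to marked-pixel count is linear between per-(kind, axis)
bounds `minp/maxp` estimated on the **training split only**; values outside
the bounds (possible on test data) are clamped, and degenerate bounds
(maxp = minp) map to `minpx`. The per-window interpretation of min/max
would be degenerate — a single scalar per window — so calibration-set
statistics are used. The pixel budget defaults to [0, Px·Py].

Fill paths are full permutations of a region's pixels:

- **CCW** — outward counterclockwise spiral (up, left, down, right) from
  the center pixel; for even dimensions the start is (Py//2, Px//2), the
  off-center pixel from which the up-first spiral stays 4-connected inside
  a square region (the ⌈·/2⌉−1 alternative walks out of bounds and would
  break the continuous-edge property the encoding exists for).
- **CW** — inward clockwise spiral from the top-left corner.
- **Diag** — 45° anti-diagonals from the top-left corner, each traversed
  upward-rightward.
- **Strk** — strokes across each row-triple of regions: reverse diagonals,
  then horizontal lines, then diagonals; lines are drawn left to right and
  stacked alternately one above, one below the first line; in regions 2
  and 3 the path starts next to the topmost marked pixel of the previous
  region's last column (top-left corner if there is none, rows clamped to
  region bounds). Exhausted sides of the alternation are skipped so the
  path still covers every pixel.

The default schedule alternates CCW, CW per region. The schedule is
resolved by each region content's *baseline* position rather than its
physical position, so a layout variant permutes rendered blocks verbatim;
the inherently spatial Strokes strategy is the exception and is scheduled
positionally. Non-square regions keep the permutation property for all
strategies, but the spiral paths are only guaranteed 4-connected on square
regions.

## Coloring

- **Per-span channels**: R/G/B hold the full-canvas render restricted to
  span u/w/v respectively.
- **Neighbor coloring** (default): all channels share the current window's
  mask; per region, with p′ⱼ the pattern value of the region's (kind, axis)
  at window w₀+j scaled to [0, 255] by the same calibration, marked pixels
  get R = p′₋₂, G = p′₀, B = p′₊₂ and unmarked pixels R = 255 − p′₋₁,
  G = 255 − p′₀, B = 255 − p′₊₁. The p′ⱼ are taken from the single window
  at offset j (the span structure is already in the geometry); this keeps
  the scheme inside the w−2…w+2 neighborhood. Identical neighboring
  windows therefore produce a grayscale image.
- **Per-sensor channels**: up to three sensors, one B&W canvas each; more
  sensors go to the augmented canvas (per-sensor tiles, row-major,
  configurable tiling width; empty slots all-unmarked).

## Layout variants

Robustness variants permute the 36 baseline region contents: top/bottom
halves switched, left/right halves switched, the two diagonal quadrant
swaps, and "flattened quadrants", which refills the 6×6 grid row-major with
the quadrant contents concatenated (TL, TR, BL, BR) — dissolving the
quadrant structure entirely while keeping the canvas size. Every variant is
a bijection; rendered variant images are exact per-region block
permutations of the baseline image, and global marked-pixel counts are
unchanged.

## Classifier

conv(128 filters, 3×3, ReLU) → maxpool(2×2, stride 2) → conv(128, 3×3,
ReLU) → maxpool → dense(256, ReLU) → softmax, cross-entropy loss, Adam.
Implemented in NumPy (im2col convolutions, float32, He initialization, all
randomness through one seeded generator), so identical seeds give identical
weights, shuffles, and fitted models. Unstated training hyperparameters are
explicit configuration: batch size 32, learning rate 1e-3, up to 100
epochs, early stopping on validation loss with patience 10 and
best-weights restore. Images enter the network scaled to [0, 1].

Split protocols are seeded and stratified: k-fold (per-class round-robin,
fold sizes within ±1 per class) or train/(val/)test fractions. When a
protocol has no explicit validation part, 10% of the training split is held
out for early stopping. Metrics are computed per class from one-vs-rest
confusion counts (accuracy, precision, recall, F1) and macro-averaged for
the headline number; with the balanced synthetic benchmark, macro and
overall accuracy nearly coincide.

## Synthetic benchmark

Each class is, per axis, `base + slope·t + amplitude·tri(t/period) +
N(0, sd²)` with a triangle wave as the oscillation primitive — chosen
because the patterns then have exact closed forms (a period-2 triangle of
amplitude a gives vp_osc = 2a noise-free; with noise the expectation is a
folded-normal mean computed analytically and recorded in the dataset
manifest for oracle tests). The default benchmark (seed 17) has 4 classes
× 400 windows of 128 samples (4 subjects × 100 windows), 3 axes with
amplitude scalings (1.0, 0.75, 1.25):

| class | amplitude | period | slope | base | noise sd |
|---|---|---|---|---|---|
| jog-like | 2.0 | 2 | 0 | 0 | 0.10 |
| walk-like | 1.2 | 4 | 0 | 0 | 0.05 |
| stairs-like | 0.5 | 2 | 0.002 | 0 | 0.05 |
| stand-like | 0.12 | 2 | 0 | 9.8 | 0.02 |

Classes are separable through the pattern features alone by construction
(1-NN on (vp_osc, vp_steady) errs < 1% at these noise levels). That is the
point — the benchmark validates the *mechanics* of the encoding and the
pipeline, not HAR difficulty. Real accelerometer data has non-stationary
waveforms, cross-axis correlation, label noise, and between-subject
variability that this generator deliberately omits, so accuracy here says
nothing about accuracy on field datasets; those require the generic CSV
loader and external data.

## Problem sizes and numerics

Experiments and the acceptance script use 5×5-pixel regions (30×30
canvases) rather than the 20×20 default (120×120): the mapping then
resolves pattern values into 26 levels per region, which the benchmark's
class separations exceed comfortably, and the CNN trains in minutes on one
CPU core. The end-to-end run uses the full 128-filter architecture (10
epochs, patience 3); the 6-layout robustness sweep uses a 32-filter
reduction (8 epochs) since it compares layouts against each other under one
fixed protocol. The label-shuffle control trains the same pipeline on
permuted labels and is expected at chance (0.25) within 3 binomial standard
errors of the test-set size.

Floor/clamp behavior of the pixel mapping guarantees M(minp) = minpx and
M(maxp) = maxpx exactly and monotonicity in between. PNG output is 8-bit,
written by Pillow with provenance (window index, layout, coloring, config
hash) in a PNG text chunk; writes are byte-stable.

## Known limitations

- The spiral 4-connectivity guarantee holds for square regions; non-square
  regions keep only the permutation property.
- Quadrants hold exactly 3 axes; sensors with more channels must be split
  across augmented-canvas tiles.
- k-fold driving is available in `classifier.train`, but the experiment
  driver (`pipeline.run_experiment`) implements fraction splits only, so
  that calibration can always be restricted to the training part without
  re-rendering per fold.
- The NumPy CNN targets small canvases; it is not optimized for 100k+
  image corpora or large filter counts.
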