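"""Train the baseline CNN end-to-end on a small synthetic benchmark.

Generates a shrunk version of the default 4-class fixture (1 subject x 40
windows per class), encodes neighbor-colored canvases, trains a reduced
CNN under a stratified 80/20 split, and prints the test metrics.
Runs in well under a minute on one CPU.
"""

import dataclasses

from imucanvas import CNNConfig
from imucanvas.pipeline import run_experiment
from imucanvas.synthetic import default_benchmark

dspec = default_benchmark(seed=17)
dspec = dataclasses.replace(
    dspec, n_subjects=1,
    classes=tuple(dataclasses.replace(c, duration=40) for c in dspec.classes),
)

res = run_experiment(
    dataset_spec=dspec,
    coloring="neighbor",
    cnn=CNNConfig(conv_filters=(32, 32), max_epochs=8, patience=3, seed=17),
    seed=17,
)

print(f"windows encoded : {res.n_images}")
print(f"test accuracy   : {res.accuracy:.4f}")
print(f"macro F1        : {res.macro_f1:.4f}")
for cls, m in res.train_result.metrics.per_class.items():
    print(f"  {cls:<12} precision={m['precision']:.3f} recall={m['recall']:.3f}")
print("\nHigh accuracy (chance level is 0.25) is expected even at this small")
print("training size: the synthetic classes differ exactly in the")
print("oscillation/drift/range features the canvas quadrants encode.")
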