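"""End-to-end pipeline: streams -> windows -> patterns -> images -> CNN.

The stages are importable on their own; this module wires them together the
way the experiments use them:

1. cut every stream into non-overlapping windows and extract the per-window
   :class:`~imucanvas.patterns.PatternVector` per axis;
2. calibrate the value -> pixel mapping on the *training* windows only;
3. render one canvas image per window (any layout variant / coloring);
4. train and evaluate the baseline CNN under a stratified split protocol.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .classifier import CNNConfig, TrainResult, train
from .layout import CanvasSpec, RegionAssignment, variant_layout
from .patterns import PatternVector, extract
from .render import (
    DEFAULT_SCHEDULE,
    CalibrationStats,
    PixelBudget,
    RenderedImage,
    calibrate,
    color_neighbor,
    color_simple_spans,
    read_image,
    render_bw,
    write_image,
)
from .streams import SensorStream, WindowSpec, segment
from . import synthetic

__all__ = [
    "PatternSet",
    "ExperimentResult",
    "config_hash",
    "prepare_patterns",
    "calibrate_on",
    "render_window",
    "render_dataset",
    "encode_to_dir",
    "load_image_dir",
    "run_experiment",
]

COLORINGS = ("bw", "simple_spans", "neighbor")


@dataclass
class PatternSet:
    """Per-window pattern vectors of a whole dataset, neighborhood-ready.

    ``neighborhoods[i]`` maps axis -> 5-tuple of PatternVectors at offsets
    (-2..+2) within the same stream; ``None`` marks stream-boundary
    neighbors.
    """

    labels: np.ndarray
    subjects: np.ndarray
    neighborhoods: list[dict[str, tuple[PatternVector | None, ...]]]
    axes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.labels)

    def all_vectors(self, indices: Sequence[int] | None = None) -> list[PatternVector]:
        idx = range(len(self)) if indices is None else indices
        out = []
        for i in idx:
            for axis in self.axes:
                pv = self.neighborhoods[i][axis][2]
                assert pv is not None
                out.append(pv)
        return out


@dataclass
class ExperimentResult:
    """Outcome of one end-to-end classification experiment."""

    accuracy: float
    macro_f1: float
    train_result: TrainResult
    n_images: int
    config: dict = field(default_factory=dict)


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration dict (for image provenance)."""
    blob = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def prepare_patterns(
    streams: Sequence[SensorStream], wspec: WindowSpec
) -> PatternSet:
    """Window all streams and extract pattern vectors with neighborhoods."""
    labels: list[str] = []
    subjects: list[str] = []
    neighborhoods = []
    axes: tuple[str, ...] | None = None
    for stream in streams:
        if axes is None:
            axes = stream.axes
        windows = segment(stream, wspec)
        n = len(windows[stream.axes[0]])
        pvs = {a: [extract(w) for w in windows[a]] for a in stream.axes}
        for i in range(n):
            labels.append(windows[stream.axes[0]][i].label)
            subjects.append(stream.subject_id)
            neighborhoods.append({
                a: tuple(
                    pvs[a][i + off] if 0 <= i + off < n else None
                    for off in (-2, -1, 0, 1, 2)
                )
                for a in stream.axes
            })
    assert axes is not None, "no streams given"
    return PatternSet(
        labels=np.array(labels),
        subjects=np.array(subjects),
        neighborhoods=neighborhoods,
        axes=axes,
    )


def calibrate_on(pattern_set: PatternSet, indices: Sequence[int]) -> CalibrationStats:
    """Calibration bounds from the training windows only."""
    return calibrate(pattern_set.all_vectors(indices))


_RENDERERS = {
    "bw": render_bw,
    "simple_spans": color_simple_spans,
    "neighbor": color_neighbor,
}


def render_window(
    pattern_set: PatternSet,
    index: int,
    assignment: RegionAssignment,
    spec: CanvasSpec,
    stats: CalibrationStats,
    coloring: str = "neighbor",
    schedule: Sequence[str] = DEFAULT_SCHEDULE,
    budget: PixelBudget | None = None,
    provenance: dict | None = None,
) -> RenderedImage:
    if coloring not in _RENDERERS:
        raise ValueError(f"unknown coloring {coloring!r}; known: {COLORINGS}")
    return _RENDERERS[coloring](
        pattern_set.neighborhoods[index], assignment, spec, stats,
        budget=budget, schedule=schedule, provenance=provenance,
    )


def render_dataset(
    pattern_set: PatternSet,
    assignment: RegionAssignment,
    spec: CanvasSpec,
    stats: CalibrationStats,
    coloring: str = "neighbor",
    schedule: Sequence[str] = DEFAULT_SCHEDULE,
    budget: PixelBudget | None = None,
) -> np.ndarray:
    """Render every window into one uint8 array (N, H, W[, 3])."""
    images = [
        render_window(
            pattern_set, i, assignment, spec, stats, coloring, schedule, budget
        ).pixels
        for i in range(len(pattern_set))
    ]
    return np.stack(images, axis=0)


def encode_to_dir(
    pattern_set: PatternSet,
    out_dir: str | Path,
    assignment: RegionAssignment,
    spec: CanvasSpec,
    stats: CalibrationStats,
    coloring: str = "neighbor",
    schedule: Sequence[str] = DEFAULT_SCHEDULE,
    budget: PixelBudget | None = None,
    config: dict | None = None,
) -> list[Path]:
    """Write one PNG per window under ``<out>/<label>/<subject>_<window>.png``."""
    out_dir = Path(out_dir)
    chash = config_hash(config or {})
    paths = []
    per_stream_counter: dict[str, int] = {}
    for i in range(len(pattern_set)):
        subject = str(pattern_set.subjects[i])
        k = per_stream_counter.get(subject, 0)
        per_stream_counter[subject] = k + 1
        img = render_window(
            pattern_set, i, assignment, spec, stats, coloring, schedule, budget,
            provenance={"config_hash": chash, "subject": subject},
        )
        path = out_dir / str(pattern_set.labels[i]) / f"{subject}_{k:05d}.png"
        paths.append(write_image(img, path))
    return paths


def load_image_dir(root: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back a ``<label>/<name>.png`` tree into (images, labels)."""
    root = Path(root)
    images, labels = [], []
    for label_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for png in sorted(label_dir.glob("*.png")):
            images.append(read_image(png).pixels)
            labels.append(label_dir.name)
    if not images:
        raise FileNotFoundError(f"no PNGs under {root}")
    return np.stack(images, axis=0), np.array(labels)


def run_experiment(
    streams: Sequence[SensorStream] | None = None,
    dataset_spec: synthetic.DatasetSpec | None = None,
    window_spec: WindowSpec | None = None,
    variant: str = "baseline",
    coloring: str = "neighbor",
    canvas: CanvasSpec | None = None,
    schedule: Sequence[str] = DEFAULT_SCHEDULE,
    cnn: CNNConfig | None = None,
    split: dict | None = None,
    seed: int = 0,
    shuffle_label_seed: int | None = None,
    pattern_set: PatternSet | None = None,
) -> ExperimentResult:
    """One full experiment: encode a dataset, train the CNN, evaluate.

    Provide either ``streams``, a synthetic ``dataset_spec`` (generated in
    memory), or a precomputed ``pattern_set``.  Calibration always uses the
    training part of the split.  ``shuffle_label_seed`` permutes the window
    labels first (null-model control).
    """
    from .classifier import stratified_fractions

    if pattern_set is None:
        if streams is None:
            if dataset_spec is None:
                raise ValueError("provide streams, dataset_spec, or pattern_set")
            streams = synthetic.generate_streams(dataset_spec)
        wspec = window_spec or WindowSpec(
            length=dataset_spec.window_length if dataset_spec else 128
        )
        pattern_set = prepare_patterns(streams, wspec)

    labels = pattern_set.labels
    if shuffle_label_seed is not None:
        labels = synthetic.shuffle_labels(labels, shuffle_label_seed)

    split = split or {"fractions": (0.8, 0.2)}
    if "fractions" not in split:
        raise ValueError("run_experiment drives fraction splits; "
                         "use classifier.train directly for k-fold")
    parts = stratified_fractions(labels, split["fractions"], seed)
    train_idx = parts[0]

    canvas = canvas or CanvasSpec(Px=5, Py=5, C=3 if coloring != "bw" else 1)
    assignment = variant_layout(variant, axes=pattern_set.axes)
    stats = calibrate_on(pattern_set, train_idx)
    images = render_dataset(
        pattern_set, assignment, canvas, stats, coloring, schedule
    )

    cnn = cnn or CNNConfig()
    result = train(cnn, images, labels, split, seed=seed)
    config = {
        "variant": variant,
        "coloring": coloring,
        "canvas": [canvas.Rx, canvas.Ry, canvas.Px, canvas.Py, canvas.C],
        "schedule": list(schedule),
        "split": {k: list(v) if isinstance(v, tuple) else v for k, v in split.items()},
        "seed": seed,
    }
    return ExperimentResult(
        accuracy=result.metrics.overall_accuracy,
        macro_f1=result.metrics.macro["f1"],
        train_result=result,
        n_images=len(images),
        config=config,
    )
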