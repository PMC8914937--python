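"""Synthetic labeled IMU streams with analytically known pattern values.

Each activity class is a per-axis mix of a triangle-wave oscillation, a
linear drift, a base level, and Gaussian noise:

    value(t) = base + slope * t + amplitude * tri(t / period) + N(0, sd^2)

The triangle wave (rather than a sinusoid) is the oscillation primitive
because the patterns-over-time then have exact closed forms: a period-2
triangle of amplitude ``a`` alternates -a, +a, so the oscillatory variation
value is exactly ``2a`` without noise, and with noise the expected value is
a folded-normal mean which this module computes for oracle tests.  Classes
that differ in amplitude, period, drift slope, or base level are therefore
separable through the pattern quadrants of the canvas by construction.

The generator writes plain CSV (one file per subject, all classes as
consecutive blocks) plus a JSON manifest recording the specs, the seed, and
the analytic per-class expectations.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .streams import SensorStream

__all__ = [
    "AxisParams",
    "ClassSpec",
    "DatasetSpec",
    "CSV_SCHEMA",
    "triangle_wave",
    "generate_stream",
    "generate_streams",
    "generate_dataset",
    "default_benchmark",
    "expected_vp_osc",
    "shuffle_labels",
]

DEFAULT_AXES = ("sx", "sy", "sz")

#: column-role schema of the CSVs this module writes (see streams.load_csv)
CSV_SCHEMA = {
    "timestamp": "t",
    "subject": "subject",
    "label": "label",
    "axes": {"sx": "sx", "sy": "sy", "sz": "sz"},
    "sensor_id": "acc",
}


@dataclass(frozen=True)
class AxisParams:
    """Signal parameters of one class on one axis."""

    osc_amplitude: float = 0.0
    osc_period: int = 2  # samples; >= 2
    drift_slope: float = 0.0  # units per sample
    base_level: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.osc_period < 2:
            raise ValueError(f"osc_period must be >= 2, got {self.osc_period}")
        if self.noise_sd < 0 or self.osc_amplitude < 0:
            raise ValueError("noise_sd and osc_amplitude must be >= 0")


@dataclass(frozen=True)
class ClassSpec:
    """One activity class: per-axis parameters and windows per subject."""

    label: str
    axes: dict[str, AxisParams]
    duration: int = 100  # windows per subject


@dataclass(frozen=True)
class DatasetSpec:
    """A full synthetic dataset: classes x subjects at one sampling rate."""

    classes: tuple[ClassSpec, ...]
    n_subjects: int = 4
    sampling_rate: float = 50.0
    window_length: int = 128
    seed: int = 17

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")


def triangle_wave(t: np.ndarray, period: int) -> np.ndarray:
    """Unit triangle wave: -1 at phase 0, +1 at phase period/2, linear between."""
    x = np.mod(np.asarray(t, dtype=float), period) / period
    return 1.0 - 4.0 * np.abs(x - 0.5)


def generate_stream(
    cspec: ClassSpec,
    n_samples: int,
    rng: np.random.Generator,
    subject_id: str = "s0",
    sensor_id: str = "acc",
    sampling_rate: float = 50.0,
) -> SensorStream:
    """One constant-label stream following the class's per-axis model."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    t = np.arange(n_samples)
    samples = {}
    for axis, p in cspec.axes.items():
        clean = (
            p.base_level
            + p.drift_slope * t
            + p.osc_amplitude * triangle_wave(t, p.osc_period)
        )
        noise = rng.normal(0.0, p.noise_sd, size=n_samples) if p.noise_sd else 0.0
        samples[axis] = clean + noise
    return SensorStream(
        sensor_id=sensor_id,
        axes=tuple(cspec.axes),
        samples=samples,
        sampling_rate=sampling_rate,
        subject_id=subject_id,
        labels=np.array([cspec.label] * n_samples),
        timestamps=t / sampling_rate,
    )


def generate_streams(dspec: DatasetSpec) -> list[SensorStream]:
    """One stream per subject: the classes as consecutive labeled blocks.

    Class blocks are whole multiples of the window length, so windows never
    straddle a class change (neighboring windows across a boundary still
    belong to different classes, as in real recordings).
    """
    rng = np.random.default_rng(dspec.seed)
    streams = []
    for s in range(dspec.n_subjects):
        subject = f"subj{s:02d}"
        chunks, labels = [], []
        for cspec in dspec.classes:
            n = cspec.duration * dspec.window_length
            block = generate_stream(
                cspec, n, rng, subject_id=subject,
                sampling_rate=dspec.sampling_rate,
            )
            chunks.append(block)
            labels.append(block.labels)
        axes = chunks[0].axes
        samples = {
            a: np.concatenate([c.samples[a] for c in chunks]) for a in axes
        }
        all_labels = np.concatenate(labels)
        n_total = len(all_labels)
        streams.append(
            SensorStream(
                sensor_id="acc",
                axes=axes,
                samples=samples,
                sampling_rate=dspec.sampling_rate,
                subject_id=subject,
                labels=all_labels,
                timestamps=np.arange(n_total) / dspec.sampling_rate,
            )
        )
    return streams


def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def _folded_normal_mean(mu: float, sd: float) -> float:
    """E|X| for X ~ N(mu, sd^2)."""
    if sd == 0.0:
        return abs(mu)
    return sd * math.sqrt(2.0 / math.pi) * math.exp(
        -(mu ** 2) / (2 * sd ** 2)
    ) + mu * (1.0 - 2.0 * _phi(-mu / sd))


def expected_vp_osc(p: AxisParams) -> float | None:
    """Analytic expected oscillatory variation value, where tractable.

    For a period-2 triangle the successive differences alternate
    ``slope +/- 2*amplitude`` plus a N(0, 2*sd^2) noise difference, and as
    long as the oscillation dominates slope and noise every interior point
    is a strict extremum, so the window is a single oscillatory segment and

        E[vp_osc] = 0.5 * ( E|N(s+2a, 2sd^2)| + E|N(s-2a, 2sd^2)| ).

    Returns ``None`` for longer periods or when the dominance condition
    (2a > |s| + 6*sd*sqrt(2)) does not clearly hold.
    """
    if p.osc_period != 2:
        return None
    step = 2.0 * p.osc_amplitude
    if step <= abs(p.drift_slope) + 6.0 * p.noise_sd * math.sqrt(2.0):
        return None
    sd = p.noise_sd * math.sqrt(2.0)
    return 0.5 * (
        _folded_normal_mean(p.drift_slope + step, sd)
        + _folded_normal_mean(p.drift_slope - step, sd)
    )


def default_benchmark(seed: int = 17) -> DatasetSpec:
    """The default 4-class benchmark fixture: 400 windows of 128 samples per
    class (4 subjects x 100 windows), 3 axes, 50 Hz.

    Classes emulate the signal features real activities differ in: a large
    fast oscillation (jog-like), a moderate slower oscillation that mixes
    oscillatory and steady runs (walk-like), a small oscillation on top of a
    monotone drift (stairs-like), and a near-constant gravity-level signal
    (stand-like).  Per-axis amplitude scalings mimic a dominant movement
    axis.
    """
    scales = {"sx": 1.0, "sy": 0.75, "sz": 1.25}

    def cls(label, amp, period, slope, base, noise):
        return ClassSpec(
            label=label,
            axes={
                a: AxisParams(
                    osc_amplitude=amp * s,
                    osc_period=period,
                    drift_slope=slope,
                    base_level=base,
                    noise_sd=noise,
                )
                for a, s in scales.items()
            },
        )

    return DatasetSpec(
        classes=(
            cls("jog-like", amp=2.0, period=2, slope=0.0, base=0.0, noise=0.10),
            cls("walk-like", amp=1.2, period=4, slope=0.0, base=0.0, noise=0.05),
            cls("stairs-like", amp=0.5, period=2, slope=0.002, base=0.0, noise=0.05),
            cls("stand-like", amp=0.12, period=2, slope=0.0, base=9.8, noise=0.02),
        ),
        n_subjects=4,
        sampling_rate=50.0,
        window_length=128,
        seed=seed,
    )


def generate_dataset(dspec: DatasetSpec, out_dir: str | Path) -> dict:
    """Write one CSV per subject plus ``manifest.json``; returns the manifest.

    The manifest records the full spec, the seed, and the analytic expected
    ``vp_osc`` per class and axis where a closed form exists (``null``
    otherwise).
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    streams = generate_streams(dspec)
    paths = []
    for stream in streams:
        df = pd.DataFrame({"t": stream.timestamps, "subject": stream.subject_id,
                           "label": stream.labels})
        for axis in stream.axes:
            df[axis] = stream.samples[axis]
        path = out_dir / f"{stream.subject_id}.csv"
        df.to_csv(path, index=False)
        paths.append(str(path.name))
    manifest = {
        "seed": dspec.seed,
        "n_subjects": dspec.n_subjects,
        "sampling_rate": dspec.sampling_rate,
        "window_length": dspec.window_length,
        "schema": CSV_SCHEMA,
        "files": paths,
        "classes": {c.label: {a: asdict(p) for a, p in c.axes.items()}
                    for c in dspec.classes},
        "expected_vp_osc": {
            c.label: {a: expected_vp_osc(p) for a, p in c.axes.items()}
            for c in dspec.classes
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def shuffle_labels(labels: np.ndarray, seed: int) -> np.ndarray:
    """Permute a label vector with a recorded seed (null-model fixture)."""
    rng = np.random.default_rng(seed)
    return rng.permutation(np.asarray(labels))
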