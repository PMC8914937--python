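"""Sensor streams, fixed-length windowing, and window neighborhoods.

A :class:`SensorStream` holds the raw multivariate samples of one inertial
sensor worn by one subject.  Streams are cut into **non-overlapping**
fixed-length :class:`SensorWindow` segments (the unit from which the
patterns-over-time are computed), and each window can be viewed together with
its four nearest neighbors as a :class:`WindowNeighborhood` covering the
spans *u* (the two windows before), *w* (the current window) and *v* (the two
windows after).

Timestamps are carried as metadata only; all computation is index based.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorStream",
    "WindowSpec",
    "SensorWindow",
    "WindowNeighborhood",
    "SchemaError",
    "EmptyInputError",
    "load_csv",
    "segment",
    "neighborhood",
]


class SchemaError(ValueError):
    """The CSV does not contain the columns the schema requires."""


class EmptyInputError(ValueError):
    """The input file contains no data rows."""


@dataclass
class SensorStream:
    """Raw samples of one sensor for one subject.

    Parameters
    ----------
    sensor_id:
        Name of the physical sensor (e.g. ``"acc"``).
    axes:
        Ordered axis labels, e.g. ``("sx", "sy", "sz")``.
    samples:
        Mapping axis label -> 1-D float array; all axes equal length.
    sampling_rate:
        Samples per second; must be positive.
    subject_id:
        Identifier of the wearer.
    labels:
        Per-sample activity label, same length as the samples.
    timestamps:
        Optional per-sample timestamps (metadata only).
    """

    sensor_id: str
    axes: tuple[str, ...]
    samples: dict[str, np.ndarray]
    sampling_rate: float
    subject_id: str
    labels: np.ndarray
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        self.axes = tuple(self.axes)
        lengths = {axis: len(self.samples[axis]) for axis in self.axes}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"axes have unequal lengths: {lengths}")
        self.samples = {a: np.asarray(self.samples[a], dtype=float) for a in self.axes}
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.n_samples:
            raise ValueError(
                f"labels length {len(self.labels)} != samples length {self.n_samples}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples[self.axes[0]]) if self.axes else 0


@dataclass(frozen=True)
class WindowSpec:
    """Non-overlapping windowing parameters.

    ``length`` must be at least 5 so a window can hold one 3-point variation
    triple plus neighbors on both sides.  ``overlap`` is fixed at 0.
    """

    length: int = 128
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.length < 5:
            raise ValueError(f"window length must be >= 5, got {self.length}")
        if self.overlap != 0:
            raise ValueError("windows are non-overlapping; overlap must be 0")


@dataclass
class SensorWindow:
    """One fixed-length segment of one sensor axis."""

    window_index: int
    axis: str
    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class WindowNeighborhood:
    """The w-2 .. w+2 view around one window, per axis.

    ``windows[axis]`` is a 5-tuple ``(w-2, w-1, w0, w+1, w+2)``; out-of-range
    neighbors are ``None`` and additionally flagged in ``absent`` (offsets
    relative to the current window).
    """

    index: int
    windows: dict[str, tuple[SensorWindow | None, ...]]
    absent: tuple[int, ...] = field(default_factory=tuple)

    OFFSETS = (-2, -1, 0, 1, 2)

    @property
    def label(self) -> str:
        axis = next(iter(self.windows))
        center = self.windows[axis][2]
        assert center is not None
        return center.label


def _majority_label(labels: np.ndarray) -> str:
    """Most frequent label; ties broken by lexicographically first label."""
    counts = Counter(labels.tolist())
    best = max(counts.items(), key=lambda kv: (kv[1], ), default=(None, 0))
    top = best[1]
    return str(sorted(k for k, v in counts.items() if v == top)[0])


def load_csv(path: str | Path, schema: Mapping[str, object]) -> list[SensorStream]:
    """Load sensor streams from a plain CSV file.

    ``schema`` maps roles to column names::

        {"timestamp": "t", "subject": "subject", "label": "label",
         "axes": {"sx": "ax", "sy": "ay", "sz": "az"},
         "sensor_id": "acc", "sampling_rate": 50.0}

    Returns one :class:`SensorStream` per subject found in the file, with the
    original sample order preserved.  Non-numeric axis cells are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    for role in ("timestamp", "subject", "label", "axes"):
        if role not in schema:
            raise SchemaError(f"schema is missing the {role!r} role")
    axes_map: Mapping[str, str] = schema["axes"]  # type: ignore[assignment]
    if not axes_map:
        raise SchemaError("schema must name at least one axis column")

    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} contains no data") from None
    if df.empty:
        raise EmptyInputError(f"{path} contains no data rows")

    needed = [schema["timestamp"], schema["subject"], schema["label"], *axes_map.values()]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")

    for axis_label, col in axes_map.items():
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"non-numeric value(s) in axis column {col!r} "
                f"(first at row {int(np.flatnonzero(bad)[0])})"
            )
        df[col] = converted

    sensor_id = str(schema.get("sensor_id", "sensor0"))
    rate = float(schema.get("sampling_rate", 1.0))

    streams: list[SensorStream] = []
    for subject, group in df.groupby(schema["subject"], sort=True):
        ts = group[schema["timestamp"]].to_numpy()
        if len(ts) > 1 and not np.all(np.diff(ts.astype(float)) >= 0):
            warnings.warn(
                f"non-monotone timestamps for subject {subject}; order kept as-is",
                stacklevel=2,
            )
        streams.append(
            SensorStream(
                sensor_id=sensor_id,
                axes=tuple(axes_map),
                samples={a: group[c].to_numpy(dtype=float) for a, c in axes_map.items()},
                sampling_rate=rate,
                subject_id=str(subject),
                labels=group[schema["label"]].to_numpy(),
                timestamps=ts,
            )
        )
    return streams


def segment(stream: SensorStream, spec: WindowSpec) -> dict[str, list[SensorWindow]]:
    """Cut a stream into non-overlapping windows, per axis.

    Produces ``floor(N / length)`` windows per axis; trailing remainder
    samples are dropped.  Each window's label is the majority of its sample
    labels (ties -> lexicographically first).
    """
    n = stream.n_samples
    length = spec.length
    n_windows = n // length
    if n_windows == 0:
        warnings.warn(
            f"stream of {n} samples shorter than one window ({length}); no output",
            stacklevel=2,
        )
        return {axis: [] for axis in stream.axes}

    window_labels = [
        _majority_label(stream.labels[i * length:(i + 1) * length])
        for i in range(n_windows)
    ]
    out: dict[str, list[SensorWindow]] = {}
    for axis in stream.axes:
        data = stream.samples[axis]
        out[axis] = [
            SensorWindow(
                window_index=i,
                axis=axis,
                values=data[i * length:(i + 1) * length],
                label=window_labels[i],
            )
            for i in range(n_windows)
        ]
    return out


def neighborhood(
    windows: Mapping[str, Sequence[SensorWindow]], index: int
) -> WindowNeighborhood:
    """Return the ``w-2 .. w+2`` neighborhood of window ``index``.

    Out-of-range neighbors are ``None`` and their offsets are listed in
    ``absent`` (they contribute pattern value 0 downstream).
    """
    axes = list(windows)
    n = len(windows[axes[0]])
    if not 0 <= index < n:
        raise IndexError(f"window index {index} out of range [0, {n})")
    absent = tuple(
        off for off in WindowNeighborhood.OFFSETS if not 0 <= index + off < n
    )
    per_axis = {
        axis: tuple(
            windows[axis][index + off] if 0 <= index + off < n else None
            for off in WindowNeighborhood.OFFSETS
        )
        for axis in axes
    }
    return WindowNeighborhood(index=index, windows=per_axis, absent=absent)
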