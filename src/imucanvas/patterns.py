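"""Patterns over time: oscillatory/steady segmentation and pattern values.

Each window of a univariate signal is summarized by a small set of scalar
"patterns over time":

* **oscillatory variation** — runs where the signal alternates, i.e. every
  interior point of the run is a strict local maximum or minimum of its
  3-point triple;
* **steady variation** — runs where the signal moves consistently up or down
  (strictly monotone triples); plateaus (equal consecutive values) are
  absorbed here as the residual class;
* **range** — the window's maximum, minimum and max-minus-min.

The value of a variation pattern (``vp``) is the mean absolute successive
difference pooled over all segments of that kind:

    vp = ( sum_j sum_i |d_i - d_{i-1}| ) / ( sum_j (k_j - 1) )

where segment ``j`` has ``k_j`` points and the inner sum runs within the
segment.  Differences are never taken across segment boundaries.  A segment
needs at least 3 points, so ``k_j >= 3`` always holds.  Where an oscillatory
and a steady run meet, the boundary points belong to both segments
(inclusive 3-point triples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .streams import SensorWindow

__all__ = [
    "Segment",
    "PatternVector",
    "PATTERN_KINDS",
    "classify_segments",
    "variation_value",
    "range_features",
    "extract",
]

Kind = Literal["oscillatory", "steady"]

#: pattern kinds that can be placed on a canvas region
PATTERN_KINDS = ("osc", "steady", "range_max", "range_diff")


@dataclass(frozen=True)
class Segment:
    """A maximal run of one variation kind inside a window.

    ``start``/``end`` are inclusive indices into the window; ``k`` is the
    number of points, always >= 3.
    """

    kind: Kind
    start: int
    end: int

    @property
    def k(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PatternVector:
    """The per-window pattern values of one axis."""

    window_index: int
    axis: str
    vp_osc: float
    vp_steady: float
    range_max: float
    range_min: float
    range_diff: float

    def value(self, kind: str) -> float:
        """Pattern value by canvas kind name (one of PATTERN_KINDS)."""
        return {
            "osc": self.vp_osc,
            "steady": self.vp_steady,
            "range_max": self.range_max,
            "range_diff": self.range_diff,
        }[kind]


def _triple_kinds(values: np.ndarray) -> list[str]:
    """Classify each interior index by its 3-point triple.

    Strict local extremum -> oscillatory; anything else (strictly monotone or
    containing a plateau step) -> steady.
    """
    a, b, c = values[:-2], values[1:-1], values[2:]
    osc = ((b > a) & (b > c)) | ((b < a) & (b < c))
    return ["oscillatory" if o else "steady" for o in osc]


def classify_segments(values: Sequence[float] | np.ndarray) -> list[Segment]:
    """Split a window into maximal oscillatory / steady segments.

    Every interior point is classified by its triple; maximal runs of one
    kind become a :class:`Segment` spanning from one point before the run to
    one point after it, so adjacent segments of different kinds share their
    boundary points.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError(f"need at least 3 data points, got {values.size}")
    kinds = _triple_kinds(values)
    segments: list[Segment] = []
    run_start = 0  # index into kinds
    for i in range(1, len(kinds) + 1):
        if i == len(kinds) or kinds[i] != kinds[run_start]:
            # interior run [run_start, i-1] -> points [run_start, i+1]
            segments.append(
                Segment(kind=kinds[run_start], start=run_start, end=i + 1)  # type: ignore[arg-type]
            )
            run_start = i
    return segments


def variation_value(
    values: Sequence[float] | np.ndarray, segments: Sequence[Segment]
) -> float:
    """Mean absolute successive difference pooled over the given segments.

    All segments should be of one kind.  Returns 0.0 when no segment is
    given.  Differences are taken within each segment only.
    """
    values = np.asarray(values, dtype=float)
    num = 0.0
    den = 0
    for seg in segments:
        d = np.abs(np.diff(values[seg.start:seg.end + 1]))
        num += float(d.sum())
        den += seg.k - 1
    return num / den if den else 0.0


def range_features(values: Sequence[float] | np.ndarray) -> tuple[float, float, float]:
    """(max, min, max - min) of the window."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("window is empty")
    hi = float(values.max())
    lo = float(values.min())
    return hi, lo, hi - lo


def extract(window: SensorWindow) -> PatternVector:
    """Compute the full :class:`PatternVector` of one window."""
    values = window.values
    segments = classify_segments(values)
    vp_osc = variation_value(values, [s for s in segments if s.kind == "oscillatory"])
    vp_steady = variation_value(values, [s for s in segments if s.kind == "steady"])
    hi, lo, diff = range_features(values)
    return PatternVector(
        window_index=window.window_index,
        axis=window.axis,
        vp_osc=vp_osc,
        vp_steady=vp_steady,
        range_max=hi,
        range_min=lo,
        range_diff=diff,
    )
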