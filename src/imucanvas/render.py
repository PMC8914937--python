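"""Rendering: pattern values -> marked pixels -> filled, colored canvases.

A pattern value ``pa`` is turned into a number of *marked* pixels of its
region through a linear map calibrated on training data,

    M(pa) = floor( minpx + (maxpx - minpx) * (pa - minp) / (maxp - minp) ),

with ``pa`` clamped to the calibration bounds ``[minp, maxp]`` and
``[minpx, maxpx]`` the region's pixel budget.  The first ``M(pa)`` pixels
along a deterministic *fill path* are set to 255 (marked), the rest stay 0,
so the mark boundary forms a continuous, well-localized edge.

Four fill strategies are provided: an outward counterclockwise spiral from
the region center (CCW), an inward clockwise spiral from the top-left corner
(CW), 45-degree anti-diagonals (Diag), and cross-region strokes (Strk) whose
line family changes every region and whose start pixel chains to the highest
marked pixel of the region to the left.

Three coloring schemes lift the single-channel canvas to RGB: per-span
channels (u/w/v on R/G/B), neighbor-window coloring (all channels share the
current window's mask while the marked/unmarked intensities encode the
pattern values of windows w-2 .. w+2), and per-sensor channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image
from PIL.PngImagePlugin import PngInfo

from .layout import AugmentedCanvas, CanvasSpec, RegionAssignment
from .patterns import PATTERN_KINDS, PatternVector, extract
from .streams import WindowNeighborhood

__all__ = [
    "STRATEGIES",
    "CalibrationStats",
    "PixelBudget",
    "FillPath",
    "StrokesContext",
    "RenderedImage",
    "calibrate",
    "map_to_pixels",
    "fill_path",
    "render_region",
    "render_bw",
    "color_simple_spans",
    "color_neighbor",
    "color_multi_sensor",
    "compose_tiles",
    "write_image",
    "read_image",
]

STRATEGIES = ("CCW", "CW", "Diag", "Strk")

#: per-axis 5-tuple of pattern vectors at offsets (-2, -1, 0, +1, +2);
#: ``None`` marks an absent neighbor (contributes pattern value 0)
NeighborhoodPatterns = Mapping[str, Sequence[PatternVector | None]]


class CalibrationError(RuntimeError):
    """Rendering was attempted without calibration for a (kind, axis) pair."""


@dataclass
class CalibrationStats:
    """Per-(pattern_kind, axis) value bounds estimated from training data."""

    bounds: dict[tuple[str, str], tuple[float, float]]

    def get(self, kind: str, axis: str) -> tuple[float, float]:
        try:
            return self.bounds[(kind, axis)]
        except KeyError:
            raise CalibrationError(
                f"no calibration for pattern {kind!r} on axis {axis!r}; "
                "run calibrate() on training pattern vectors first"
            ) from None

    def is_flat(self, kind: str, axis: str) -> bool:
        lo, hi = self.get(kind, axis)
        return hi == lo


@dataclass(frozen=True)
class PixelBudget:
    """Minimum / maximum number of pixels that may be marked in a region."""

    minpx: int
    maxpx: int

    def __post_init__(self) -> None:
        if not 0 <= self.minpx <= self.maxpx:
            raise ValueError(f"need 0 <= minpx <= maxpx, got {self}")


@dataclass(frozen=True)
class StrokesContext:
    """Cross-region state for the Strokes strategy.

    ``position_in_triple`` selects the line family (0 = reverse diagonals,
    1 = horizontal lines, 2 = diagonals); ``prev_mask`` is the already
    rendered mask of the region directly to the left, used to choose the
    start pixel.
    """

    position_in_triple: int = 0
    prev_mask: np.ndarray | None = None


@dataclass(frozen=True)
class FillPath:
    """A deterministic ordering of all pixels of one ``Py x Px`` region."""

    strategy: str
    Px: int
    Py: int
    pixels: tuple[tuple[int, int], ...]  # (row, col), 0-based, origin top-left

    def __post_init__(self) -> None:
        if len(self.pixels) != self.Px * self.Py:
            raise ValueError("path must visit every pixel exactly once")

    def flat(self) -> np.ndarray:
        """Row-major flat pixel indices along the path."""
        rc = np.asarray(self.pixels)
        return rc[:, 0] * self.Px + rc[:, 1]


@dataclass
class RenderedImage:
    """A rendered raster plus its provenance."""

    pixels: np.ndarray  # (H, W) uint8 for C=1, (H, W, 3) for C=3
    provenance: dict = field(default_factory=dict)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


# ---------------------------------------------------------------------------
# calibration and value -> pixel-count mapping


def calibrate(pattern_vectors: Iterable[PatternVector]) -> CalibrationStats:
    """Min/max of each pattern kind per axis over a training set."""
    bounds: dict[tuple[str, str], tuple[float, float]] = {}
    n = 0
    for pv in pattern_vectors:
        n += 1
        for kind in PATTERN_KINDS:
            val = pv.value(kind)
            key = (kind, pv.axis)
            if key in bounds:
                lo, hi = bounds[key]
                bounds[key] = (min(lo, val), max(hi, val))
            else:
                bounds[key] = (val, val)
    if n == 0:
        raise ValueError("cannot calibrate on an empty set of pattern vectors")
    return CalibrationStats(bounds=bounds)


def map_to_pixels(
    pa: float, stats_entry: tuple[float, float], budget: PixelBudget
) -> int:
    """Number of marked pixels for pattern value ``pa`` (clamped, floored)."""
    minp, maxp = stats_entry
    if maxp == minp:
        return budget.minpx
    pa = min(max(pa, minp), maxp)
    frac = (pa - minp) / (maxp - minp)
    m = int(np.floor(budget.minpx + (budget.maxpx - budget.minpx) * frac))
    return min(max(m, budget.minpx), budget.maxpx)


# ---------------------------------------------------------------------------
# fill paths


def _ccw_path(Px: int, Py: int) -> tuple[tuple[int, int], ...]:
    # Outward counterclockwise spiral from the center pixel; for even
    # dimensions the start is the pixel just past the geometric center
    # (Py//2, Px//2) -- the unique off-center choice that keeps the up-first
    # counterclockwise spiral 4-connected within a square region.  Walked on
    # a virtual unbounded grid; out-of-bounds cells are skipped.
    r, c = Py // 2, Px // 2
    total = Px * Py
    out: list[tuple[int, int]] = []
    if 0 <= r < Py and 0 <= c < Px:
        out.append((r, c))
    # counterclockwise direction cycle: up, left, down, right
    dirs = ((-1, 0), (0, -1), (1, 0), (0, 1))
    run, d = 1, 0
    while len(out) < total:
        for _ in range(2):  # run length grows every second direction change
            dr, dc = dirs[d % 4]
            for _ in range(run):
                r, c = r + dr, c + dc
                if 0 <= r < Py and 0 <= c < Px:
                    out.append((r, c))
                    if len(out) == total:
                        return tuple(out)
            d += 1
        run += 1
    return tuple(out)


def _cw_path(Px: int, Py: int) -> tuple[tuple[int, int], ...]:
    # Inward clockwise spiral from the top-left corner.
    top, bottom, left, right = 0, Py - 1, 0, Px - 1
    out: list[tuple[int, int]] = []
    while top <= bottom and left <= right:
        out.extend((top, c) for c in range(left, right + 1))
        out.extend((r, right) for r in range(top + 1, bottom + 1))
        if top < bottom:
            out.extend((bottom, c) for c in range(right - 1, left - 1, -1))
        if left < right:
            out.extend((r, left) for r in range(bottom - 1, top, -1))
        top, bottom, left, right = top + 1, bottom - 1, left + 1, right - 1
    return tuple(out)


def _diag_path(Px: int, Py: int) -> tuple[tuple[int, int], ...]:
    # Anti-diagonals from the top-left corner, each running upward-rightward.
    out: list[tuple[int, int]] = []
    for d in range(Px + Py - 1):
        r = min(d, Py - 1)
        while r >= 0 and d - r < Px:
            out.append((r, d - r))
            r -= 1
    return tuple(out)


def _line_pixels(family: int, line_id: int, Px: int, Py: int) -> list[tuple[int, int]]:
    """Pixels of one stroke line, drawn left to right."""
    if family == 0:  # reverse diagonals: r - c = line_id, down-rightward
        return [
            (line_id + c, c)
            for c in range(Px)
            if 0 <= line_id + c < Py
        ]
    if family == 1:  # horizontal: r = line_id
        return [(line_id, c) for c in range(Px)] if 0 <= line_id < Py else []
    # family == 2, diagonals: r + c = line_id, up-rightward
    return [
        (line_id - c, c)
        for c in range(Px)
        if 0 <= line_id - c < Py
    ]


def _strokes_path(
    Px: int, Py: int, family: int, start_row: int
) -> tuple[tuple[int, int], ...]:
    # First the line through the start pixel (start_row, 0), then the lines
    # stacked alternately one above, one below, with growing offsets; an
    # exhausted side is skipped so the path still covers every pixel.
    if family == 0:
        line0 = start_row  # r - c at (start_row, 0)
        lo, hi = -(Px - 1), Py - 1
    elif family == 1:
        line0 = start_row
        lo, hi = 0, Py - 1
    else:
        line0 = start_row  # r + c at (start_row, 0)
        lo, hi = 0, Px + Py - 2
    out: list[tuple[int, int]] = []
    out.extend(_line_pixels(family, line0, Px, Py))
    offset = 1
    while len(out) < Px * Py:
        above, below = line0 - offset, line0 + offset
        if above >= lo:
            out.extend(_line_pixels(family, above, Px, Py))
        if below <= hi:
            out.extend(_line_pixels(family, below, Px, Py))
        if above < lo and below > hi:  # pragma: no cover - loop guard
            break
        offset += 1
    return tuple(out)


@lru_cache(maxsize=None)
def _cached_path(strategy: str, Px: int, Py: int, family: int, start_row: int):
    if strategy == "CCW":
        return _ccw_path(Px, Py)
    if strategy == "CW":
        return _cw_path(Px, Py)
    if strategy == "Diag":
        return _diag_path(Px, Py)
    if strategy == "Strk":
        return _strokes_path(Px, Py, family, start_row)
    raise ValueError(f"unknown filling strategy {strategy!r}; known: {STRATEGIES}")


def _strokes_start_row(prev_mask: np.ndarray | None, Py: int) -> int:
    """Row of the start pixel chained from the previous region's mask.

    The start pixel sits next to the highest (topmost) marked pixel of the
    previous region's last column; with no such pixel the path starts at the
    top-left corner.  The row is clamped to the region bounds.
    """
    if prev_mask is None:
        return 0
    marked_rows = np.flatnonzero(prev_mask[:, -1])
    if marked_rows.size == 0:
        return 0
    return int(min(max(int(marked_rows[0]), 0), Py - 1))


def fill_path(
    strategy: str, Px: int, Py: int, context: StrokesContext | None = None
) -> FillPath:
    """Build the pixel ordering of one region for the given strategy."""
    if strategy == "Strk":
        ctx = context or StrokesContext()
        family = ctx.position_in_triple % 3
        start_row = _strokes_start_row(ctx.prev_mask, Py) if family else 0
        pixels = _cached_path("Strk", Px, Py, family, start_row)
    else:
        pixels = _cached_path(strategy, Px, Py, 0, 0)
    return FillPath(strategy=strategy, Px=Px, Py=Py, pixels=pixels)


def render_region(path: FillPath, m: int) -> np.ndarray:
    """Mask with the first ``m`` path pixels marked (255), the rest 0."""
    if not 0 <= m <= path.Px * path.Py:
        raise ValueError(f"marked count {m} outside [0, {path.Px * path.Py}]")
    mask = np.zeros(path.Py * path.Px, dtype=np.uint8)
    mask[path.flat()[:m]] = 255
    return mask.reshape(path.Py, path.Px)


# ---------------------------------------------------------------------------
# whole-canvas rendering


def _as_patterns(
    neigh: WindowNeighborhood | NeighborhoodPatterns,
) -> tuple[NeighborhoodPatterns, dict]:
    """Accept a raw neighborhood or precomputed pattern 5-tuples."""
    if isinstance(neigh, WindowNeighborhood):
        patterns = {
            axis: tuple(None if w is None else extract(w) for w in ws)
            for axis, ws in neigh.windows.items()
        }
        prov = {"window_index": neigh.index, "absent_neighbors": list(neigh.absent)}
        return patterns, prov
    first = next(iter(neigh.values()))
    center = first[2]
    prov = {
        "window_index": None if center is None else center.window_index,
        "absent_neighbors": [
            off
            for off, pv in zip(WindowNeighborhood.OFFSETS, first)
            if pv is None
        ],
    }
    return neigh, prov


def _span_value(five: Sequence[PatternVector | None], kind: str, span: str) -> float:
    """Region value for one span; absent neighbors contribute 0."""
    def val(pv: PatternVector | None) -> float:
        return 0.0 if pv is None else pv.value(kind)

    if span == "w":
        return val(five[2])
    if span == "u":
        return 0.5 * (val(five[0]) + val(five[1]))
    if span == "v":
        return 0.5 * (val(five[3]) + val(five[4]))
    raise ValueError(f"unknown span {span!r}")


def _strategy_name(
    assignment: RegionAssignment,
    pos_index: int,
    content: tuple[str, str, str],
    schedule: Sequence[str],
) -> str:
    # The CCW/CW/... schedule follows each region content's baseline
    # position, so layout variants permute rendered blocks verbatim.  The
    # Strokes strategy is inherently spatial and is scheduled by physical
    # position instead.
    if "Strk" in schedule:
        return schedule[pos_index % len(schedule)]
    return schedule[assignment.baseline_order[content] % len(schedule)]


def _render_masks(
    patterns: NeighborhoodPatterns,
    assignment: RegionAssignment,
    spec: CanvasSpec,
    stats: CalibrationStats,
    budget: PixelBudget,
    schedule: Sequence[str],
    span_filter: str | None = None,
) -> np.ndarray:
    """Render the full canvas mask; optionally only regions of one span."""
    canvas = np.zeros((spec.Ry * spec.Py, spec.Rx * spec.Px), dtype=np.uint8)
    prev_mask: np.ndarray | None = None
    for idx, (r, c) in enumerate(assignment.positions()):
        content = assignment.mapping[(r, c)]
        kind, axis, span = content
        strategy = _strategy_name(assignment, idx, content, schedule)
        if strategy == "Strk":
            pos = c % 3
            ctx = StrokesContext(
                position_in_triple=pos, prev_mask=prev_mask if pos else None
            )
        else:
            ctx = None
        value = _span_value(patterns[axis], kind, span)
        m = map_to_pixels(value, stats.get(kind, axis), budget)
        path = fill_path(strategy, spec.Px, spec.Py, ctx)
        mask = render_region(path, m)
        prev_mask = mask
        if span_filter is None or span == span_filter:
            canvas[
                r * spec.Py:(r + 1) * spec.Py, c * spec.Px:(c + 1) * spec.Px
            ] = mask
    return canvas


def _default_budget(spec: CanvasSpec) -> PixelBudget:
    return PixelBudget(minpx=0, maxpx=spec.pixels_per_region)


DEFAULT_SCHEDULE = ("CCW", "CW")


def render_bw(
    neigh: WindowNeighborhood | NeighborhoodPatterns,
    assignment: RegionAssignment,
    spec: CanvasSpec,
    stats: CalibrationStats,
    budget: PixelBudget | None = None,
    schedule: Sequence[str] = DEFAULT_SCHEDULE,
    provenance: dict | None = None,
) -> RenderedImage:
    """Single-channel render: every region filled per its assigned content."""
    patterns, prov = _as_patterns(neigh)
    budget = budget or _default_budget(spec)
    canvas = _render_masks(patterns, assignment, spec, stats, budget, schedule)
    prov.update(provenance or {})
    prov.setdefault("layout", assignment.name)
    prov.setdefault("coloring", "bw")
    return RenderedImage(pixels=canvas, provenance=prov)


def color_simple_spans(
    neigh: WindowNeighborhood | NeighborhoodPatterns,
    assignment: RegionAssignment,
    spec: CanvasSpec,
    stats: CalibrationStats,
    budget: PixelBudget | None = None,
    schedule: Sequence[str] = DEFAULT_SCHEDULE,
    provenance: dict | None = None,
) -> RenderedImage:
    """RGB render with span u on red, w on green, v on blue."""
    patterns, prov = _as_patterns(neigh)
    budget = budget or _default_budget(spec)
    channels = [
        _render_masks(patterns, assignment, spec, stats, budget, schedule, span)
        for span in ("u", "w", "v")
    ]
    prov.update(provenance or {})
    prov.setdefault("layout", assignment.name)
    prov.setdefault("coloring", "simple_spans")
    return RenderedImage(pixels=np.stack(channels, axis=-1), provenance=prov)


_COLOR_BUDGET = PixelBudget(minpx=0, maxpx=255)


def color_neighbor(
    neigh: WindowNeighborhood | NeighborhoodPatterns,
    assignment: RegionAssignment,
    spec: CanvasSpec,
    stats: CalibrationStats,
    budget: PixelBudget | None = None,
    schedule: Sequence[str] = DEFAULT_SCHEDULE,
    provenance: dict | None = None,
) -> RenderedImage:
    """Neighbor-window coloring: shared mask, intensities from w-2 .. w+2.

    All three channels share the current window's marked/unmarked mask.  Per
    region, the pattern values of windows at offsets j in {-2..+2} are scaled
    to p'_j in [0, 255] with the same calibration bounds, and

        marked:   R = p'_{-2}   G = p'_0        B = p'_{+2}
        unmarked: R = 255-p'_{-1}  G = 255-p'_0  B = 255-p'_{+1}
    """
    patterns, prov = _as_patterns(neigh)
    budget = budget or _default_budget(spec)
    mask = _render_masks(patterns, assignment, spec, stats, budget, schedule)
    out = np.zeros((spec.Ry * spec.Py, spec.Rx * spec.Px, 3), dtype=np.uint8)
    for r, c in assignment.positions():
        kind, axis, _span = assignment.mapping[(r, c)]
        entry = stats.get(kind, axis)
        p = [
            map_to_pixels(
                0.0 if pv is None else pv.value(kind), entry, _COLOR_BUDGET
            )
            for pv in patterns[axis]
        ]  # p'_{-2} .. p'_{+2}
        sl = np.s_[r * spec.Py:(r + 1) * spec.Py, c * spec.Px:(c + 1) * spec.Px]
        marked = mask[sl] > 0
        block = np.empty((spec.Py, spec.Px, 3), dtype=np.uint8)
        for ch, (m_val, u_val) in enumerate(
            ((p[0], 255 - p[1]), (p[2], 255 - p[2]), (p[4], 255 - p[3]))
        ):
            block[..., ch] = np.where(marked, m_val, u_val)
        out[sl] = block
    prov.update(provenance or {})
    prov.setdefault("layout", assignment.name)
    prov.setdefault("coloring", "neighbor")
    return RenderedImage(pixels=out, provenance=prov)


def color_multi_sensor(
    neighs: Mapping[str, WindowNeighborhood | NeighborhoodPatterns],
    assignment: RegionAssignment,
    spec: CanvasSpec,
    stats_by_sensor: Mapping[str, CalibrationStats],
    budget: PixelBudget | None = None,
    schedule: Sequence[str] = DEFAULT_SCHEDULE,
    provenance: dict | None = None,
) -> RenderedImage:
    """RGB render with each sensor's B&W canvas on its own channel."""
    if len(neighs) > 3:
        raise ValueError(
            f"{len(neighs)} sensors exceed the 3 color channels; "
            "use an augmented canvas (layout.augmented_layout) instead"
        )
    budget = budget or _default_budget(spec)
    channels = []
    prov: dict = {"sensors": list(neighs)}
    for sensor, neigh in neighs.items():
        patterns, p0 = _as_patterns(neigh)
        prov.setdefault("window_index", p0.get("window_index"))
        channels.append(
            _render_masks(
                patterns, assignment, spec, stats_by_sensor[sensor], budget, schedule
            )
        )
    while len(channels) < 3:
        channels.append(np.zeros_like(channels[0]))
    prov.update(provenance or {})
    prov.setdefault("layout", assignment.name)
    prov.setdefault("coloring", "multi_sensor")
    return RenderedImage(pixels=np.stack(channels, axis=-1), provenance=prov)


def compose_tiles(
    images: Sequence[RenderedImage], aug: AugmentedCanvas
) -> RenderedImage:
    """Tile per-sensor renders row-major onto the augmented canvas.

    Unused tile slots stay all-unmarked (zero).
    """
    if len(images) != len(aug.tiles):
        raise ValueError(f"expected {len(aug.tiles)} tiles, got {len(images)}")
    th, tw = aug.tile_spec.height, aug.tile_spec.width
    nch = images[0].channels
    shape = (aug.tiles_y * th, aug.tiles_x * tw) + ((nch,) if nch == 3 else ())
    canvas = np.zeros(shape, dtype=np.uint8)
    for i, img in enumerate(images):
        if img.pixels.shape[:2] != (th, tw):
            raise ValueError("all tiles must share the tile canvas size")
        ty, tx = divmod(i, aug.tiles_x)
        canvas[ty * th:(ty + 1) * th, tx * tw:(tx + 1) * tw] = img.pixels
    prov = {
        "tiling": [aug.tiles_x, aug.tiles_y],
        "sensors": [s for s, _ in aug.tiles],
        "tile_provenance": images[0].provenance,
    }
    return RenderedImage(pixels=canvas, provenance=prov)


# ---------------------------------------------------------------------------
# PNG I/O


def write_image(img: RenderedImage, path: str | Path) -> Path:
    """Write an 8-bit grayscale / RGB PNG with provenance in a text chunk."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mode = "L" if img.channels == 1 else "RGB"
    pil = Image.fromarray(img.pixels, mode=mode)
    info = PngInfo()
    info.add_text("imucanvas", json.dumps(img.provenance, sort_keys=True))
    pil.save(path, format="PNG", pnginfo=info)
    return path


def read_image(path: str | Path) -> RenderedImage:
    """Read a PNG written by :func:`write_image`, provenance included."""
    with Image.open(path) as pil:
        pixels = np.asarray(pil)
        raw = pil.text.get("imucanvas", "{}")
    return RenderedImage(pixels=pixels, provenance=json.loads(raw))
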