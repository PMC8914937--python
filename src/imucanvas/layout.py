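"""Canvas geometry and region semantics.

The image is an empty *canvas* of ``Ry x Rx`` regions, each ``Py x Px``
pixels.  The default canvas is 6x6 regions grouped into four 3x3
*quadrants*, one per pattern kind:

* top-left: oscillatory variation, top-right: steady variation,
* bottom-left: range maximum, bottom-right: range max-min difference.

Within a quadrant, rows are the sensor axes (sx, sy, sz top to bottom) and
columns are the window spans (u = two windows before, w = current, v = two
windows after; left to right).

Robustness *layout variants* permute the 36 region contents (half swaps,
quadrant swaps, or flattening the quadrants over the rows); every variant is
a bijection of the baseline contents.  For sensors beyond one, per-sensor
canvases are tiled side by side into an *augmented canvas*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = [
    "CanvasSpec",
    "RegionAssignment",
    "AugmentedCanvas",
    "SPANS",
    "VARIANT_NAMES",
    "baseline_layout",
    "variant_layout",
    "augmented_layout",
]

#: window spans, left-to-right column order within a quadrant
SPANS = ("u", "w", "v")

#: quadrant pattern kinds in (top-left, top-right, bottom-left, bottom-right) order
_QUADRANT_KINDS = ("osc", "steady", "range_max", "range_diff")

VARIANT_NAMES = (
    "baseline",
    "bottom_top_switched",
    "flattened_quadrants",
    "left_right_switched",
    "tl_br_switched",
    "tr_bl_switched",
)

Content = tuple[str, str, str]  # (pattern_kind, axis, span)


@dataclass(frozen=True)
class CanvasSpec:
    """Geometry of one per-sensor canvas.

    ``Rx``/``Ry`` are region grid columns/rows, ``Px``/``Py`` pixels per
    region (width/height), ``C`` the channel count (1 = B&W, 3 = RGB).
    """

    Rx: int = 6
    Ry: int = 6
    Px: int = 20
    Py: int = 20
    C: int = 1

    def __post_init__(self) -> None:
        if min(self.Rx, self.Ry, self.Px, self.Py) < 1:
            raise ValueError("Rx, Ry, Px, Py must all be >= 1")
        if self.C not in (1, 3):
            raise ValueError(f"C must be 1 or 3, got {self.C}")

    @property
    def width(self) -> int:
        return self.Rx * self.Px

    @property
    def height(self) -> int:
        return self.Ry * self.Py

    @property
    def pixels_per_region(self) -> int:
        return self.Px * self.Py


@dataclass(frozen=True)
class RegionAssignment:
    """Total mapping region position (row, col) -> (pattern_kind, axis, span).

    ``baseline_order`` maps each content triple to its row-major index in the
    *baseline* layout; fill-strategy schedules are resolved through it so a
    layout variant permutes rendered blocks without changing how each block
    is filled.
    """

    name: str
    rows: int
    cols: int
    mapping: dict[tuple[int, int], Content]
    baseline_order: dict[Content, int] = field(repr=False)

    def __post_init__(self) -> None:
        expected = {(r, c) for r in range(self.rows) for c in range(self.cols)}
        if set(self.mapping) != expected:
            raise ValueError("mapping must be total over the region grid")
        contents = list(self.mapping.values())
        if len(set(contents)) != len(contents):
            raise ValueError("mapping must be injective on contents")

    def positions(self) -> list[tuple[int, int]]:
        """Region positions in row-major order."""
        return [(r, c) for r in range(self.rows) for c in range(self.cols)]


@dataclass(frozen=True)
class AugmentedCanvas:
    """Several per-sensor canvases tiled row-major into one image."""

    tiles: tuple[tuple[str, CanvasSpec], ...]
    tiles_x: int
    tiles_y: int

    @property
    def tile_spec(self) -> CanvasSpec:
        return self.tiles[0][1]

    @property
    def width(self) -> int:
        return self.tiles_x * self.tile_spec.width

    @property
    def height(self) -> int:
        return self.tiles_y * self.tile_spec.height


def baseline_layout(axes: Sequence[str] = ("sx", "sy", "sz")) -> RegionAssignment:
    """The default 6x6 assignment (four 3x3 quadrants, axes x spans inside)."""
    axes = tuple(axes)
    if len(axes) != 3:
        raise ValueError(
            f"a quadrant holds a 3x3 axes-by-spans grid; got {len(axes)} axes "
            "(put extra sensors on augmented-canvas tiles)"
        )
    mapping: dict[tuple[int, int], Content] = {}
    for q, kind in enumerate(_QUADRANT_KINDS):
        r0, c0 = (q // 2) * 3, (q % 2) * 3
        for i, axis in enumerate(axes):
            for j, span in enumerate(SPANS):
                mapping[(r0 + i, c0 + j)] = (kind, axis, span)
    order = {mapping[(r, c)]: r * 6 + c for r in range(6) for c in range(6)}
    return RegionAssignment(
        name="baseline", rows=6, cols=6, mapping=mapping, baseline_order=order
    )


def _half_swap_rows(r: int, c: int) -> tuple[int, int]:
    return ((r + 3) % 6, c)


def _half_swap_cols(r: int, c: int) -> tuple[int, int]:
    return (r, (c + 3) % 6)


def _tl_br(r: int, c: int) -> tuple[int, int]:
    if (r < 3) == (c < 3):  # TL or BR quadrant
        return ((r + 3) % 6, (c + 3) % 6)
    return (r, c)


def _tr_bl(r: int, c: int) -> tuple[int, int]:
    if (r < 3) != (c < 3):  # TR or BL quadrant
        return ((r + 3) % 6, (c + 3) % 6)
    return (r, c)


_POSITION_PERMS: dict[str, Callable[[int, int], tuple[int, int]]] = {
    "bottom_top_switched": _half_swap_rows,
    "left_right_switched": _half_swap_cols,
    "tl_br_switched": _tl_br,
    "tr_bl_switched": _tr_bl,
}


def variant_layout(
    name: str, axes: Sequence[str] = ("sx", "sy", "sz")
) -> RegionAssignment:
    """One of the robustness layout variants of the 6x6 baseline.

    ``bottom_top_switched`` / ``left_right_switched`` swap the canvas halves,
    ``tl_br_switched`` / ``tr_bl_switched`` swap two opposite quadrants, and
    ``flattened_quadrants`` refills the grid row-major with the quadrant
    contents concatenated in top-left, top-right, bottom-left, bottom-right
    order, dissolving the quadrant structure.
    """
    base = baseline_layout(axes)
    if name == "baseline":
        return base
    if name == "flattened_quadrants":
        contents: list[Content] = []
        for q in range(4):
            r0, c0 = (q // 2) * 3, (q % 2) * 3
            contents.extend(
                base.mapping[(r0 + i, c0 + j)] for i in range(3) for j in range(3)
            )
        mapping = {
            (idx // 6, idx % 6): content for idx, content in enumerate(contents)
        }
    elif name in _POSITION_PERMS:
        perm = _POSITION_PERMS[name]
        mapping = {
            (r, c): base.mapping[perm(r, c)] for r in range(6) for c in range(6)
        }
    else:
        raise ValueError(f"unknown layout variant {name!r}; known: {VARIANT_NAMES}")
    return RegionAssignment(
        name=name, rows=6, cols=6, mapping=mapping,
        baseline_order=base.baseline_order,
    )


def augmented_layout(
    sensors: Sequence[str], spec: CanvasSpec, tiles_x: int | None = None
) -> AugmentedCanvas:
    """Tile per-sensor canvases row-major into a ``tiles_x``-wide grid.

    ``tiles_y = ceil(n_sensors / tiles_x)``; unused slots stay all-unmarked.
    """
    if not sensors:
        raise ValueError("need at least one sensor")
    if tiles_x is None:
        tiles_x = len(sensors)
    if tiles_x < 1:
        raise ValueError("tiles_x must be >= 1")
    tiles_y = math.ceil(len(sensors) / tiles_x)
    return AugmentedCanvas(
        tiles=tuple((s, spec) for s in sensors),
        tiles_x=tiles_x,
        tiles_y=tiles_y,
    )
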