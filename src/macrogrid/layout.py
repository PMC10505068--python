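"""Macroarray geometry: the dot/cell lattice and disc-shaped localities.

A macroarray is a square grid of printed protein spots ("dots"), grouped
into square "cells" with a dark fiducial marker dot at the center of each
cell.  On the scanned image every dot occupies a fixed square tile of
pixels, so the whole region of interest is ``dots_per_side * px_per_dot``
pixels on a side.  The default constants describe the HexSelect 240x240
format: 57 600 dots in 2 304 cells of 5x5 dots, 9x9 pixels per dot,
scanned at 10 px/mm into a 2250x2250 16-bit image.

Local statistics (background repair, median/MAD normalization) are taken
over a "locality": the set of dots within a Euclidean radius, in dot
units, of the dot of interest.  A radius of 3 contains 29 lattice points,
a radius of 4 contains 49.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from functools import lru_cache

import numpy as np

__all__ = [
    "ArrayLayout",
    "LayoutError",
    "LocalityDisc",
    "make_layout",
    "locality_offsets",
    "locality_members",
    "dot_to_cell",
    "cell_to_dot",
    "shifted_stack",
]


class LayoutError(ValueError):
    """An override set violates a geometric invariant of the layout."""


@dataclass(frozen=True)
class ArrayLayout:
    """Immutable geometric constants of one macroarray format.

    Parameters
    ----------
    dots_per_side : int
        Number of dots along one side of the (square) array.
    cell_side_dots : int
        Dots along one side of a cell; must be odd so the marker dot is
        the central dot, and must divide ``dots_per_side``.
    px_per_dot : int
        Side length in pixels of the square tile covering one dot.
    image_side_px : int
        Side length of the full scanned image.  Defaults to the region of
        interest plus a symmetric margin matching the reference scanner
        framing (2250 px for the default layout).
    bit_depth_max : int
        Maximum representable intensity (65 535 for 16-bit scans).
    resolution_px_per_mm : int
        Scan resolution, pixels per millimetre.
    """

    dots_per_side: int = 240
    cell_side_dots: int = 5
    px_per_dot: int = 9
    image_side_px: int = 0  # 0 -> derived as roi_side_px + 2 * default margin
    bit_depth_max: int = 65535
    resolution_px_per_mm: int = 10

    _DEFAULT_MARGIN_PX = 45

    def __post_init__(self):
        if self.cell_side_dots % 2 != 1:
            raise LayoutError("cell_side_dots must be odd (the marker is the central dot)")
        if self.cell_side_dots <= 0 or self.px_per_dot <= 0 or self.dots_per_side <= 0:
            raise LayoutError("layout counts must be positive")
        if self.dots_per_side % self.cell_side_dots != 0:
            raise LayoutError(
                f"dots_per_side ({self.dots_per_side}) must be divisible by "
                f"cell_side_dots ({self.cell_side_dots})"
            )
        if self.px_per_dot % 2 != 1:
            raise LayoutError("px_per_dot must be odd (dot tiles are centred on a pixel)")
        if self.image_side_px == 0:
            object.__setattr__(
                self, "image_side_px", self.roi_side_px + 2 * self._DEFAULT_MARGIN_PX
            )
        if self.image_side_px < self.roi_side_px:
            raise LayoutError(
                f"image_side_px ({self.image_side_px}) smaller than the region of "
                f"interest ({self.roi_side_px})"
            )

    # ---- derived constants -------------------------------------------------
    @property
    def cells_per_side(self) -> int:
        return self.dots_per_side // self.cell_side_dots

    @property
    def roi_side_px(self) -> int:
        return self.dots_per_side * self.px_per_dot

    @property
    def cell_side_px(self) -> int:
        return self.cell_side_dots * self.px_per_dot

    @property
    def cell_halfwidth_px(self) -> int:
        # 2 * halfwidth + 1 == cell_side_px, guaranteed by the odd-side invariants
        return (self.cell_side_px - 1) // 2

    @property
    def total_dots(self) -> int:
        return self.dots_per_side**2

    @property
    def total_cells(self) -> int:
        return self.cells_per_side**2

    @property
    def margin_px(self) -> int:
        return (self.image_side_px - self.roi_side_px) // 2

    @property
    def marker_within(self) -> int:
        """Within-cell row/col index of the marker dot."""
        return self.cell_side_dots // 2

    # ---- geometry helpers --------------------------------------------------
    def ideal_marker_centers(self) -> np.ndarray:
        """Undistorted marker-center pixel coordinates, shape (cells, cells, 2).

        Last axis is (x, y) = (column, row) in full-image pixel coordinates.
        """
        n = self.cells_per_side
        c = np.arange(n) * self.cell_side_px + self.cell_halfwidth_px + self.margin_px
        xx, yy = np.meshgrid(c, c)  # xx varies along columns
        return np.stack([xx, yy], axis=-1).astype(float)

    def ideal_dot_centers(self) -> np.ndarray:
        """Undistorted dot-center pixel coordinates, shape (dots, dots, 2), (x, y)."""
        d = np.arange(self.dots_per_side) * self.px_per_dot + self.px_per_dot // 2 + self.margin_px
        xx, yy = np.meshgrid(d, d)
        return np.stack([xx, yy], axis=-1).astype(float)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def make_layout(**overrides) -> ArrayLayout:
    """Build an :class:`ArrayLayout`, defaulting to the HexSelect 240x240 format.

    Raises
    ------
    LayoutError
        If the override set is geometrically inconsistent (the message
        names the violated invariant).
    """
    known = {f.name for f in fields(ArrayLayout)}
    bad = set(overrides) - known
    if bad:
        raise LayoutError(f"unknown layout field(s): {sorted(bad)}")
    return ArrayLayout(**overrides)


@dataclass(frozen=True)
class LocalityDisc:
    """Integer lattice offsets within a Euclidean radius of the origin.

    ``offsets`` is a tuple of (dcol, drow) pairs in canonical row-major
    order (drow ascending, then dcol).  The origin is always included, so
    a dot is a member of its own locality.
    """

    radius: int
    offsets: tuple = field(repr=False)

    def __len__(self) -> int:
        return len(self.offsets)


@lru_cache(maxsize=None)
def locality_offsets(radius: int) -> LocalityDisc:
    """All integer lattice offsets (dcol, drow) with dcol^2 + drow^2 <= radius^2.

    The boundary is included.  |disc(3)| = 29 and |disc(4)| = 49.
    """
    r = int(radius)
    if r < 0:
        raise ValueError("locality radius must be a non-negative integer")
    offs = [
        (dc, dr)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if dc * dc + dr * dr <= r * r
    ]
    return LocalityDisc(radius=r, offsets=tuple(offs))


def locality_members(center, radius: int, layout: ArrayLayout) -> list:
    """Disc offsets translated to ``center`` and clipped to the array bounds.

    Parameters
    ----------
    center : (col, row) pair of 0-based dot indices.

    Returns
    -------
    list of (col, row) tuples, row-major order.
    """
    col, row = center
    n = layout.dots_per_side
    if not (0 <= col < n and 0 <= row < n):
        raise ValueError(f"center {center!r} outside a {n}x{n} array")
    disc = locality_offsets(radius)
    return [
        (col + dc, row + dr)
        for dc, dr in disc.offsets
        if 0 <= col + dc < n and 0 <= row + dr < n
    ]


def dot_to_cell(dot, layout: ArrayLayout):
    """Map a (col, row) dot index to ((cell_col, cell_row), (within_col, within_row))."""
    col, row = dot
    s = layout.cell_side_dots
    return (col // s, row // s), (col % s, row % s)


def cell_to_dot(cell, within, layout: ArrayLayout):
    """Inverse of :func:`dot_to_cell`."""
    s = layout.cell_side_dots
    return (cell[0] * s + within[0], cell[1] * s + within[1])


def shifted_stack(grid: np.ndarray, radius: int) -> np.ndarray:
    """Stack of ``grid`` translated by every offset of the radius disc.

    Returns an array of shape (K, H, W) where layer k holds, at position
    (row, col), the grid value at the k-th locality member of that
    position, or NaN where the member falls outside the array.  This is
    the vectorised form of :func:`locality_members` used for local
    medians/MADs: border localities are clipped (NaN layers), never
    padded or reflected.
    """
    disc = locality_offsets(radius)
    h, w = grid.shape
    out = np.full((len(disc), h, w), np.nan, dtype=float)
    for k, (dc, dr) in enumerate(disc.offsets):
        # value at member (col+dc, row+dr) lands in layer k at (row, col)
        src_r = slice(max(dr, 0), h + min(dr, 0))
        src_c = slice(max(dc, 0), w + min(dc, 0))
        dst_r = slice(max(-dr, 0), h + min(-dr, 0))
        dst_c = slice(max(-dc, 0), w + min(-dc, 0))
        out[k][dst_r, dst_c] = grid[src_r, src_c]
    return out
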