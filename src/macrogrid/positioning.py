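"""Two-stage dot positioning and array reconstruction.

Large printed membranes are warped non-linearly, so a plain interpolated
grid misses dot centers by several pixels at the far side of the array.
Positioning therefore runs in two stages:

1. *Four-point interpolation*: the operator supplies the pixel
   coordinates of the four corner marker dots; a bilinear interpolation
   over that quadrilateral gives an approximate center for every cell's
   marker dot.
2. *Adaptive refinement*: around each approximate center, the dark
   high-contrast marker is segmented by intensity thresholding (Otsu's
   split, taking the low-intensity class) and the refined center is the
   darkness-weighted centroid of the marker blob, rounded to an integer
   pixel.  Windows without a plausible dark blob fall back to the
   interpolated position and are flagged.

The refined marker centers anchor the reconstruction: each cell is the
square of ``+/- cell_halfwidth_px`` pixels around its marker, and each
dot tile is a fixed ``px_per_dot`` square block inside the cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .image_io import ArrayImage
from .layout import ArrayLayout

__all__ = [
    "CornerInput",
    "GeometryError",
    "PositioningError",
    "MarkerGrid",
    "CellTile",
    "QCSample",
    "interpolate_grid",
    "refine_marker",
    "build_marker_grid",
    "extract_cell",
    "extract_dot_tiles",
    "qc_sample",
]

log = logging.getLogger(__name__)


class GeometryError(ValueError):
    """Corner input or tile geometry is invalid."""


class PositioningError(RuntimeError):
    """The refined grid is implausible (non-monotonic or too many fallbacks)."""


@dataclass(frozen=True)
class CornerInput:
    """Operator-supplied pixel coordinates of the four corner marker dots.

    Order: top-left, top-right, bottom-left, bottom-right of the image
    as displayed.  These are the only manual inputs of the pipeline.
    """

    top_left: tuple
    top_right: tuple
    bottom_left: tuple
    bottom_right: tuple

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.top_left, self.top_right, self.bottom_left, self.bottom_right], dtype=float
        )

    @classmethod
    def from_flat(cls, values) -> "CornerInput":
        v = [float(x) for x in values]
        if len(v) != 8:
            raise GeometryError("corner input needs exactly 8 numbers: x1,y1,...,x4,y4")
        return cls((v[0], v[1]), (v[2], v[3]), (v[4], v[5]), (v[6], v[7]))


def _quad_area(c: CornerInput) -> float:
    # shoelace over the polygon TL -> TR -> BR -> BL
    p = c.as_array()[[0, 1, 3, 2]]
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def interpolate_grid(corners: CornerInput, layout: ArrayLayout) -> np.ndarray:
    """Bilinear interpolation of marker centers over the corner quadrilateral.

    Returns float coordinates of shape (cells_per_side, cells_per_side, 2),
    last axis (x, y); the four corners are reproduced exactly.
    """
    n = layout.cells_per_side
    expected_span = (n - 1) * layout.cell_side_px
    if _quad_area(corners) < 0.01 * expected_span**2:
        raise GeometryError("corner quadrilateral is degenerate (near-zero area)")
    tl, tr, bl, br = corners.as_array()
    f = np.linspace(0.0, 1.0, n)
    u = f[None, :, None]  # column fraction
    v = f[:, None, None]  # row fraction
    grid = (1 - u) * (1 - v) * tl + u * (1 - v) * tr + (1 - u) * v * bl + u * v * br
    return grid


def refine_marker(
    img: ArrayImage,
    approx,
    window: int | None = None,
    layout: ArrayLayout | None = None,
    min_area: int = 4,
    max_area_frac: float = 0.25,
):
    """Refine one marker center by low-intensity thresholding.

    Within a square window of halfwidth ``window`` around the approximate
    center, Otsu's threshold splits the histogram and the below-threshold
    (dark) class is taken as the marker blob.  The marker is always below
    the window median (it is the darkest printed object), so the split is
    seeded on the lower half of the histogram; while the dark class still
    covers more than ``max_area_frac`` of the window (the split peeled
    off a bright object instead of isolating the marker), Otsu is
    re-applied within the dark class.  Among the resulting dark connected
    components the one nearest the window center is taken, and the
    refined center is its darkness-weighted centroid, rounded to the
    nearest integer pixel.

    Returns
    -------
    (center, refined) : ((x, y) int tuple, bool)
        ``refined`` is False when no plausible blob was found and the
        rounded approximate position is returned instead.
    """
    if window is None:
        window = (layout or ArrayLayout()).cell_halfwidth_px
    h, w = img.pixels.shape
    cx, cy = int(round(approx[0])), int(round(approx[1]))
    if not (0 <= cx < w and 0 <= cy < h):
        raise GeometryError(f"approximate marker position {approx!r} outside the image")
    x0, x1 = max(cx - window, 0), min(cx + window + 1, w)
    y0, y1 = max(cy - window, 0), min(cy + window + 1, h)
    win = img.pixels[y0:y1, x0:x1].astype(float)

    fallback = ((cx, cy), False)
    if win.max() == win.min():
        return fallback

    sel = win[win <= np.median(win)]  # the marker lives in the lower half
    thr = None
    for _ in range(6):
        if sel.max() == sel.min():
            break
        t = threshold_otsu(sel.ravel())
        mask = win < t
        if mask.sum() <= max_area_frac * win.size:
            thr = t
            break
        sel = win[mask]
    if thr is None:
        return fallback
    mask = win < thr
    area = int(mask.sum())
    if area < min_area or area > max_area_frac * win.size:
        return fallback

    # keep only the dark component nearest the window center
    labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        yc, xc = (win.shape[0] - 1) / 2, (win.shape[1] - 1) / 2
        centroids = ndimage.center_of_mass(mask, labels, range(1, n_comp + 1))
        best = int(np.argmin([(r - yc) ** 2 + (c - xc) ** 2 for r, c in centroids])) + 1
        mask = labels == best
        if mask.sum() < min_area:
            return fallback

    weights = (thr - win) * mask  # darker pixels weigh more
    total = weights.sum()
    ys, xs = np.mgrid[y0:y1, x0:x1]
    rx = float((weights * xs).sum() / total)
    ry = float((weights * ys).sum() / total)
    return (int(round(rx)), int(round(ry))), True


@dataclass
class MarkerGrid:
    """Refined marker-center pixel coordinates, one per cell.

    ``coords`` has shape (cells_per_side, cells_per_side, 2) with integer
    (x, y); ``refined`` flags which centers came from blob refinement as
    opposed to the interpolated fallback.
    """

    coords: np.ndarray
    refined: np.ndarray

    @property
    def fallback_count(self) -> int:
        return int((~self.refined).sum())


def build_marker_grid(
    img: ArrayImage,
    corners: CornerInput,
    layout: ArrayLayout,
    window: int | None = None,
    max_fallback_frac: float = 0.05,
) -> MarkerGrid:
    """Run both positioning stages and validate the resulting grid.

    Raises
    ------
    PositioningError
        If refined centers are not strictly increasing along rows and
        columns (e.g. the operator swapped corner order), or if more
        than ``max_fallback_frac`` of cells could not be refined.
    """
    approx = interpolate_grid(corners, layout)
    n = layout.cells_per_side
    coords = np.zeros((n, n, 2), dtype=int)
    refined = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            center, ok = refine_marker(img, approx[i, j], window=window, layout=layout)
            coords[i, j] = center
            refined[i, j] = ok

    if not (np.all(np.diff(coords[:, :, 0], axis=1) > 0) and np.all(np.diff(coords[:, :, 1], axis=0) > 0)):
        raise PositioningError(
            "marker grid is not monotonic; check the corner coordinates and their order "
            "(top-left, top-right, bottom-left, bottom-right)"
        )
    grid = MarkerGrid(coords=coords, refined=refined)
    if grid.fallback_count > max_fallback_frac * n * n:
        raise PositioningError(
            f"{grid.fallback_count} of {n * n} marker dots could not be refined; "
            "the scan or corner input is likely faulty"
        )
    if grid.fallback_count:
        log.warning("marker refinement fell back to interpolation for %d cell(s)", grid.fallback_count)
    return grid


@dataclass
class CellTile:
    """Pixel sub-grid of one reconstructed cell, centred on its marker."""

    cell: tuple  # (cell_col, cell_row)
    pixels: np.ndarray


def extract_cell(img: ArrayImage, markers: MarkerGrid, cell, layout: ArrayLayout) -> CellTile:
    """Cut the ``+/- cell_halfwidth_px`` square around the cell's marker center.

    Within the tile, dot (i, j) of the cell occupies the ``px_per_dot``
    square block with top-left corner at (px_per_dot*i, px_per_dot*j).
    """
    ccol, crow = cell
    x, y = markers.coords[crow, ccol]
    hw = layout.cell_halfwidth_px
    h, w = img.pixels.shape
    if x - hw < 0 or y - hw < 0 or x + hw + 1 > w or y + hw + 1 > h:
        raise GeometryError(f"cell {cell} tile exceeds the image bounds (marker at {(x, y)})")
    return CellTile(cell=cell, pixels=img.pixels[y - hw : y + hw + 1, x - hw : x + hw + 1].astype(float))


def extract_dot_tiles(img: ArrayImage, markers: MarkerGrid, layout: ArrayLayout) -> np.ndarray:
    """All dot tiles as an array of shape (dots, dots, px_per_dot, px_per_dot).

    Indexed [dot_row, dot_col]; the marker tile of each cell is the
    central block.
    """
    n, s, p = layout.cells_per_side, layout.cell_side_dots, layout.px_per_dot
    d = layout.dots_per_side
    tiles = np.empty((d, d, p, p), dtype=float)
    for crow in range(n):
        for ccol in range(n):
            cell = extract_cell(img, markers, (ccol, crow), layout).pixels
            blocks = cell.reshape(s, p, s, p).transpose(0, 2, 1, 3)
            tiles[crow * s : (crow + 1) * s, ccol * s : (ccol + 1) * s] = blocks
    return tiles


@dataclass
class QCSample:
    """Evenly spaced sample of reconstructed cells for visual QC."""

    cell_indices: np.ndarray  # (k,) indices along each axis
    tiles: np.ndarray  # (k, k, side, side)
    marker_darkest: np.ndarray  # (k, k) bool

    def montage(self) -> np.ndarray:
        k = len(self.cell_indices)
        side = self.tiles.shape[-1]
        out = np.zeros((k * side, k * side))
        for i in range(k):
            for j in range(k):
                out[i * side : (i + 1) * side, j * side : (j + 1) * side] = self.tiles[i, j]
        return out


def qc_sample(img: ArrayImage, markers: MarkerGrid, layout: ArrayLayout, k: int = 6) -> QCSample:
    """Extract a k x k grid of evenly spaced cells and check each marker.

    The per-tile check asserts that the central dot block (the marker)
    has the lowest mean intensity of the cell's dot blocks — the visual
    criterion a reviewer applies to a reconstruction montage.
    """
    n = layout.cells_per_side
    if k > n:
        raise ValueError(f"cannot sample {k} cells per side from {n}")
    if k == 1:
        idx = np.array([(n - 1) // 2])
    else:
        idx = np.unique(np.round(np.linspace(0, n - 1, k)).astype(int))
    s, p = layout.cell_side_dots, layout.px_per_dot
    tiles = np.empty((len(idx), len(idx), layout.cell_side_px, layout.cell_side_px))
    darkest = np.zeros((len(idx), len(idx)), dtype=bool)
    m = layout.marker_within
    for a, crow in enumerate(idx):
        for b, ccol in enumerate(idx):
            tile = extract_cell(img, markers, (ccol, crow), layout).pixels
            tiles[a, b] = tile
            means = tile.reshape(s, p, s, p).mean(axis=(1, 3))
            darkest[a, b] = means.argmin() == m * s + m
    return QCSample(cell_indices=idx, tiles=tiles, marker_darkest=darkest)
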