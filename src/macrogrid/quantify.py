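"""Background offset estimation, subtraction and dot intensity summation.

The additive background varies smoothly across the membrane but is
treated as homogeneous within a single dot tile, where the offset is the
intensity of the pixel expressing no luminance — the tile's minimum
pixel.  Dots whose signal fills the whole tile leave no background
pixel, so their raw minimum is abnormally high; those offsets are
detected as robust outliers against the offsets of their locality
(radius-4 disc by default) and replaced by the local median offset.
Detection and replacement both read the *raw* offsets (two-pass), so a
replacement never cascades into its neighbours' statistics.

After subtraction (clamped at zero) the 81 pixels of each dot are summed
without any shape mask, yielding the dots_per_side^2 intensity table.
Only the additive offset is removed here; the multiplicative gain field
has no absolute reference on these membranes and is dealt with by the
locality-relative normalization downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layout import ArrayLayout, shifted_stack

__all__ = ["OffsetTable", "dot_offsets", "repair_offsets", "subtract_and_sum"]


@dataclass
class OffsetTable:
    """Per-dot background offsets after outlier repair."""

    offset: np.ndarray  # (dots, dots) float, repaired values
    raw: np.ndarray  # (dots, dots) float, tile minima
    flagged: np.ndarray  # (dots, dots) bool, True where replaced
    radius: int
    k: float


def dot_offsets(tiles: np.ndarray) -> np.ndarray:
    """Raw per-dot offset: the minimum pixel of each tile, shape (dots, dots)."""
    return np.asarray(tiles, dtype=float).min(axis=(-2, -1))


def repair_offsets(
    raw: np.ndarray, layout: ArrayLayout, radius: int = 4, k: float = 3.0
) -> OffsetTable:
    """Replace outlier offsets by their local median.

    A dot's offset is an outlier when it deviates from the median offset
    of its locality by more than ``k`` local MADs, with the MAD scaled by
    the normal-consistency factor 1.4826 so that k = 3 corresponds to the
    standard three-sigma robust cut.  Marker and blank dots participate
    here — their background is as informative as any — and border
    localities are clipped, not padded.  When the local MAD is zero, any
    nonzero deviation is flagged.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (layout.dots_per_side,) * 2:
        raise ValueError(f"offset grid shape {raw.shape} does not match the layout")
    stack = shifted_stack(raw, radius)
    local_med = np.nanmedian(stack, axis=0)
    local_mad = np.nanmedian(np.abs(stack - local_med), axis=0)
    dev = np.abs(raw - local_med)
    sigma = 1.4826 * local_mad
    flagged = np.where(sigma > 0, dev > k * sigma, dev > 0)
    repaired = np.where(flagged, local_med, raw)
    return OffsetTable(offset=repaired, raw=raw, flagged=flagged, radius=radius, k=k)


def subtract_and_sum(tiles: np.ndarray, offsets: OffsetTable | np.ndarray, layout: ArrayLayout):
    """Clamped per-pixel subtraction, then per-dot summation.

    Returns
    -------
    sums : (dots, dots) array
        Sum over each full tile of max(pixel - offset, 0).
    corrected : (dots, dots, p, p) array
        The background-subtracted tiles (for sink scoring and display).
    """
    off = offsets.offset if isinstance(offsets, OffsetTable) else np.asarray(offsets, dtype=float)
    d = layout.dots_per_side
    tiles = np.asarray(tiles, dtype=float)
    if tiles.shape[:2] != (d, d) or off.shape != (d, d):
        raise ValueError("dot tiles / offsets do not match the layout dimensions")
    corrected = np.clip(tiles - off[:, :, None, None], 0.0, None)
    return corrected.sum(axis=(-2, -1)), corrected
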