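"""Removal of null results: marker dots and blank (signal-free) dots.

Marker dots are removed purely by position — there is exactly one at
the center of every cell.  Blank dots carry no printed clone and must
be excluded from the local statistics, otherwise they drag the local
median down and inflate every neighbour's score.

Blank detection uses the divergence of the intensity gradient field:
a dot bearing signal is a smooth bright blob, so the gradient field
converges into it ("sink") and the divergence of the gradient — the
Laplacian — is strongly negative over the blob core.  We report the
*sink score*

    score(tile) = - sum over the tile core of  laplace( G_sigma * tile )

where G_sigma is a light Gaussian smoothing (sd 1 px by default), the
field is continued by edge replication outside the tile, and the core
is the tile minus a 2-px rim (the central 5x5 pixels of a 9x9 dot).
Summing over the core rather than the whole tile keeps the blob's
positive divergence annulus from cancelling its negative core, so the
score is a stable center-minus-surround response: bright centred blobs
score strongly positive, flat tiles score ~0, and dark blobs (markers)
score negative with mirrored magnitude.  Dots whose sink score falls
below a threshold ``tau`` are classed blank.

The score is a fixed linear functional of the tile, so it is evaluated
as an inner product with a precomputed weight matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from math import ceil

import numpy as np
from scipy.ndimage import gaussian_filter, laplace

from .layout import ArrayLayout

__all__ = [
    "NullMask",
    "NullClassificationError",
    "VALID",
    "MARKER",
    "BLANK",
    "CLASS_NAMES",
    "sink_score",
    "sink_scores",
    "classify_nulls",
]

log = logging.getLogger(__name__)

VALID, MARKER, BLANK = 0, 1, 2
CLASS_NAMES = {VALID: "valid", MARKER: "marker", BLANK: "blank"}


class NullClassificationError(RuntimeError):
    """The automatic blank threshold is degenerate for this array."""


_CORE_RIM = 2  # pixels trimmed from each tile edge when summing the divergence


@lru_cache(maxsize=8)
def _sink_weights(shape: tuple, smooth_sd: float) -> np.ndarray:
    """Weight matrix W with score(tile) = sum_ij W_ij * tile_ij.

    Built by pushing unit impulses through smooth -> Laplacian ->
    core-sum; edge replication makes the functional vanish on constant
    tiles (row sums of W are zero).
    """
    h, w = shape
    rim = min(_CORE_RIM, (min(h, w) - 1) // 2)
    weights = np.empty((h, w))
    canvas = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            canvas[:] = 0.0
            canvas[i, j] = 1.0
            lap = laplace(gaussian_filter(canvas, smooth_sd, mode="nearest"), mode="nearest")
            weights[i, j] = -lap[rim : h - rim, rim : w - rim].sum()
    return weights


def sink_score(tile: np.ndarray, smooth_sd: float = 1.0) -> float:
    """Sink score of one dot tile (positive for bright blobs)."""
    tile = np.asarray(tile, dtype=float)
    W = _sink_weights(tile.shape, smooth_sd)
    return float((tile * W).sum())


def sink_scores(tiles: np.ndarray, smooth_sd: float = 1.0) -> np.ndarray:
    """Vectorised :func:`sink_score` over an array of tiles (..., h, w)."""
    tiles = np.asarray(tiles, dtype=float)
    W = _sink_weights(tiles.shape[-2:], smooth_sd)
    return np.tensordot(tiles, W, axes=([-2, -1], [0, 1]))


def _resolve_tau(tau, scores: np.ndarray, marker_mask: np.ndarray) -> float:
    """Turn a threshold spec into an absolute sink-score cutoff.

    ``tau`` may be a number (absolute cutoff), the string ``"auto"``,
    or ``"mad:<k>"`` (median minus k MAD of the non-marker scores).

    The ``auto`` rule exploits the fact that blank dots carry only
    noise, so their sink scores are symmetric about zero, while every
    expressed dot scores well above zero.  The blank scale is estimated
    robustly from the sub-zero scores (sigma = 1.4826 * median|negative
    scores|) and the cutoff placed at 6 of those sigmas.  An array
    without blanks has (almost) no negative scores, so the cutoff
    collapses to zero and nothing is classed blank.  All automatic
    rules scale with the image gain, so classification is invariant
    under affine intensity changes.
    """
    if isinstance(tau, (int, float)) and not isinstance(tau, bool):
        return float(tau)
    pool = scores[~marker_mask]
    med = float(np.median(pool))
    if isinstance(tau, str) and tau == "auto":
        neg = pool[pool < 0]
        # a blank population leaves a substantial negative tail (half of the
        # blanks); a handful of negative scores are isolated artifacts and
        # cannot support a scale estimate -> treat as a blank-free array
        if neg.size < max(1.0, 0.002 * pool.size):
            # noise-free limit: blanks score exactly 0, expressed dots > 0
            if (pool == 0).any() and (pool > 0).any():
                return 0.5 * float(pool[pool > 0].min())
            return float("-inf")  # blank-free array: class nothing blank
        sigma = 1.4826 * float(np.median(-neg))
        if sigma == 0:
            raise NullClassificationError(
                "automatic blank threshold degenerate (zero spread below 0); "
                "pass an absolute tau"
            )
        return 6.0 * sigma
    if isinstance(tau, str) and tau.startswith("mad:"):
        k = float(tau.split(":", 1)[1])
        mad = float(np.median(np.abs(pool - med)))
        if mad == 0:
            raise NullClassificationError(
                "automatic blank threshold degenerate (sink-score MAD is 0); "
                "pass an absolute tau"
            )
        return med - k * mad
    raise ValueError(f"unrecognised blank threshold spec: {tau!r}")


@dataclass
class NullMask:
    """Per-dot class (valid / marker / blank) and sink score."""

    classes: np.ndarray  # (dots, dots) int8
    sink: np.ndarray  # (dots, dots) float
    tau: float

    @property
    def marker_mask(self) -> np.ndarray:
        return self.classes == MARKER

    @property
    def blank_mask(self) -> np.ndarray:
        return self.classes == BLANK

    @property
    def valid_mask(self) -> np.ndarray:
        return self.classes == VALID

    def class_names(self) -> np.ndarray:
        out = np.empty(self.classes.shape, dtype=object)
        for code, name in CLASS_NAMES.items():
            out[self.classes == code] = name
        return out


def classify_nulls(
    tiles: np.ndarray,
    layout: ArrayLayout,
    tau="auto",
    smooth_sd: float = 1.0,
) -> NullMask:
    """Classify every dot as marker, blank or valid.

    Parameters
    ----------
    tiles : (dots, dots, p, p) array
        Background-subtracted dot tiles (subtracting first keeps the
        smooth background's own curvature out of the sink scores).
    tau : float | "auto" | "mad:<k>"
        Blank threshold spec; dots with sink score strictly below the
        resolved cutoff are classed blank.
    """
    d = layout.dots_per_side
    if tiles.shape[:2] != (d, d):
        raise ValueError(f"expected {(d, d)} dot tiles, got {tiles.shape[:2]}")
    scores = sink_scores(tiles, smooth_sd=smooth_sd)

    classes = np.zeros((d, d), dtype=np.int8)
    m = layout.marker_within
    s = layout.cell_side_dots
    classes[m::s, m::s] = MARKER  # one marker per cell, by known position

    cut = _resolve_tau(tau, scores, classes == MARKER)
    blank = (classes != MARKER) & (scores < cut)
    classes[blank] = BLANK
    log.info(
        "null classification: %d markers, %d blanks, %d valid (tau=%.4g)",
        int((classes == MARKER).sum()), int(blank.sum()), int((classes == VALID).sum()), cut,
    )
    return NullMask(classes=classes, sink=scores, tau=cut)
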