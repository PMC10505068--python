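"""Synthetic macroarray scans with known ground truth.

Every pipeline stage is tested by parameter recovery on images rendered
by this module, so no scanner data is needed.  The renderer emulates the
features that make real membranes hard:

* dark printed marker dots on a brighter heterogeneous background;
* smooth spatially varying additive offset and multiplicative gain
  fields (low-order spline surfaces);
* a mild non-linear geometric warp (low-order polynomial displacement,
  a few pixels at most) of the print grid;
* Gaussian read noise and optional shot noise;
* clone spots printed in duplicate pairs, with per-clone expression
  levels shared by both replicates;
* blank (signal-free) dot pairs in region-structured densities, as seen
  when source plates of the clone library have empty wells.

Dots are rendered as radially truncated Gaussian blobs confined to their
own 9x9 tile.  The effective width grows slowly with amplitude
("blooming"), so faint spots leave untouched background pixels in the
tile corners while extremely strong signals fill the entire dot space —
exactly the situation that forces the background-offset outlier repair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline

from .image_io import ArrayImage
from .layout import ArrayLayout, make_layout
from .positioning import CornerInput
from .scoring import PairMap, default_pair_map

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "SimulationError",
    "simulate_array",
    "demo_spec",
    "write_manifest",
    "read_manifest",
]

CLASS_MARKER = "marker"
CLASS_BLANK = "blank"
CLASS_BASAL = "basal"
CLASS_SIGNAL = "signal"


class SimulationError(ValueError):
    """The simulation spec is internally inconsistent."""


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic scan (all intensities on the 16-bit scale).

    Amplitudes are blob peak heights before the gain field is applied.
    ``basal_amplitude_range`` is the bacterial-background expression of
    ordinary clone spots, drawn uniformly *per spot*: spot-to-spot
    printing and growth variability dominates the background level, so
    the two replicates of an unrecognized clone are uncorrelated — the
    regime in which duplicate-pair validation is informative.
    ``signal_amplitude_range`` is the extra amplitude of seropositive
    clones, drawn per *clone* (both replicates light up together, up to
    ``spot_variability``).  ``blank_region_rates`` gives the per-pair
    blank probability in equal vertical bands of the array (at most two
    blank pairs per cell); region boundaries are sharp, as in real
    clone libraries.
    """

    layout: ArrayLayout = field(default_factory=make_layout)
    seed: int = 0
    warp_amplitude: float = 3.0
    noise_sd: float = 50.0
    shot_noise: bool = False
    offset_base: float = 3000.0
    offset_variation: float = 600.0
    gain_variation: float = 0.2
    gain_regions: tuple = ()  # (col0, col1, row0, row1, factor) in dot units
    marker_depth: float = 2500.0
    basal_amplitude_range: tuple = (300.0, 4000.0)
    signal_amplitude_range: tuple = (8000.0, 20000.0)
    spot_variability: float = 0.1  # per-spot amplitude factor range for signal spots
    n_signal_pairs: int = 48
    signal_clones: tuple = ()  # ((cell_row, cell_col, pair_k, amplitude), ...)
    blank_region_rates: tuple = (0.02, 0.08, 0.15)
    psf_sd: float = 1.8
    psf_bloom: float = 0.1  # relative width growth per 1000 amplitude units above the knee
    psf_bloom_knee: float = 6000.0  # amplitude where blooming starts


def demo_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """The default full-size demonstration array (48 seropositive pairs)."""
    return replace(SimulationSpec(seed=seed), **overrides)


@dataclass
class GroundTruth:
    """Everything the renderer knows, for joining against pipeline output."""

    spec: SimulationSpec
    marker_centers: np.ndarray  # (cells, cells, 2) float (x, y), warped
    dot_centers: np.ndarray  # (dots, dots, 2) float (x, y), warped
    classes: np.ndarray  # (dots, dots) object: marker/blank/basal/signal
    clone_ids: np.ndarray  # (dots, dots) object, "" where unmapped
    amplitudes: np.ndarray  # (dots, dots) float blob peak (negative for markers)
    offset_field: np.ndarray  # (H, W) float32
    gain_field: np.ndarray  # (H, W) float32
    dot_signal_sums: np.ndarray  # (dots, dots) float, noiseless background-free tile sums
    pairmap: PairMap

    @property
    def layout(self) -> ArrayLayout:
        return self.spec.layout

    def corners(self) -> CornerInput:
        n = self.layout.cells_per_side
        mc = self.marker_centers
        return CornerInput(
            top_left=tuple(mc[0, 0]),
            top_right=tuple(mc[0, n - 1]),
            bottom_left=tuple(mc[n - 1, 0]),
            bottom_right=tuple(mc[n - 1, n - 1]),
        )

    def signal_clone_ids(self) -> set:
        return set(self.clone_ids[self.classes == CLASS_SIGNAL].tolist())


def _smooth_field(shape, rng, knots: int = 5) -> np.ndarray:
    """Smooth random surface on [-1, 1], via a bicubic spline over coarse knots."""
    h, w = shape
    coarse = rng.standard_normal((knots, knots))
    spl = RectBivariateSpline(np.linspace(0, h - 1, knots), np.linspace(0, w - 1, knots), coarse)
    f = spl(np.arange(h), np.arange(w))
    peak = np.abs(f).max()
    return (f / peak if peak > 0 else f).astype(np.float32)


def _warp_displacement(points: np.ndarray, layout: ArrayLayout, rng, amplitude: float) -> np.ndarray:
    """Smooth polynomial displacement field evaluated at (x, y) points.

    The displacement is a quadratic polynomial in normalized image
    coordinates, scaled so its maximum Euclidean norm over the image
    equals ``amplitude`` pixels.
    """
    if amplitude == 0:
        return np.zeros_like(points)
    c = (layout.image_side_px - 1) / 2.0
    uv = (points - c) / c  # normalized to [-1, 1]
    coeffs = rng.standard_normal((2, 5))

    def basis(u, v):
        return np.stack([u, v, u * v, u * u, v * v], axis=-1)

    # normalise the field's maximum over the image footprint
    g = np.linspace(-1, 1, 21)
    gu, gv = np.meshgrid(g, g)
    bg = basis(gu, gv)
    dg = np.stack([bg @ coeffs[0], bg @ coeffs[1]], axis=-1)
    scale = amplitude / np.linalg.norm(dg, axis=-1).max()

    b = basis(uv[..., 0], uv[..., 1])
    return np.stack([b @ coeffs[0], b @ coeffs[1]], axis=-1) * scale


def _assign_classes(spec: SimulationSpec, pairmap: PairMap, rng):
    """Blank / signal assignment at the clone-pair level."""
    layout = spec.layout
    d = layout.dots_per_side
    classes = np.full((d, d), CLASS_BASAL, dtype=object)
    clone_ids = np.full((d, d), "", dtype=object)
    amplitudes = np.zeros((d, d))

    m = layout.marker_within
    s = layout.cell_side_dots
    classes[m::s, m::s] = CLASS_MARKER
    amplitudes[m::s, m::s] = -spec.marker_depth

    t = pairmap.table
    clone_dots = {
        clone: [(int(y) - 1, int(x) - 1) for x, y in zip(grp["x"], grp["y"])]
        for clone, grp in t.groupby("clone_id")
    }
    for clone, dots in clone_dots.items():
        for r, c in dots:
            clone_ids[r, c] = clone

    # clone -> cell of its first dot (pairs never straddle cells in the default map)
    clone_cell = {clone: (dots[0][0] // s, dots[0][1] // s) for clone, dots in clone_dots.items()}

    # blanks: region-banded probability, at most two blank pairs per cell
    n_bands = len(spec.blank_region_rates)
    cells = layout.cells_per_side
    blank_clones = set()
    per_cell = {}
    for clone in sorted(clone_dots):
        ci, cj = clone_cell[clone]
        band = min(cj * n_bands // cells, n_bands - 1) if n_bands else 0
        rate = spec.blank_region_rates[band] if n_bands else 0.0
        if rate > 0 and per_cell.get((ci, cj), 0) < 2 and rng.random() < rate:
            blank_clones.add(clone)
            per_cell[(ci, cj)] = per_cell.get((ci, cj), 0) + 1
    for clone in blank_clones:
        for r, c in clone_dots[clone]:
            classes[r, c] = CLASS_BLANK
            amplitudes[r, c] = 0.0

    # basal expression, independent per spot
    lo, hi = spec.basal_amplitude_range
    for clone in sorted(clone_dots):
        if clone in blank_clones:
            continue
        for r, c in clone_dots[clone]:
            amplitudes[r, c] = rng.uniform(lo, hi)

    # seropositive clones
    if spec.signal_clones:
        chosen = []
        for ci, cj, k, amp in spec.signal_clones:
            clone = f"c{ci:03d}_{cj:03d}_p{k:02d}"
            if clone not in clone_dots:
                raise SimulationError(f"signal clone {clone} not present in the pair map")
            if clone in blank_clones:
                raise SimulationError(f"signal clone {clone} collides with a blank pair")
            chosen.append((clone, float(amp)))
    else:
        pool = sorted(set(clone_dots) - blank_clones)
        if spec.n_signal_pairs > len(pool):
            raise SimulationError("more signal pairs requested than available clones")
        idx = rng.choice(len(pool), size=spec.n_signal_pairs, replace=False)
        slo, shi = spec.signal_amplitude_range
        chosen = [(pool[i], rng.uniform(slo, shi)) for i in sorted(idx)]
    v = spec.spot_variability
    for clone, amp in chosen:
        for r, c in clone_dots[clone]:
            classes[r, c] = CLASS_SIGNAL
            amplitudes[r, c] += amp * rng.uniform(1.0 - v, 1.0 + v)

    return classes, clone_ids, amplitudes


def _blob_profile(amp: np.ndarray, r2: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    """Truncated-Gaussian blob values for |amp| peaks at squared radii r2.

    Above the bloom knee the width grows with amplitude and the radial
    truncation with it, so very strong spots fill the whole tile while
    ordinary ones leave untouched background pixels in the tile corners.
    ``amp`` broadcasts against ``r2``.
    """
    mag = np.abs(amp)
    sd = spec.psf_sd * (1.0 + spec.psf_bloom * np.maximum(mag - spec.psf_bloom_knee, 0.0) / 1000.0)
    trunc = np.minimum(2.5 * sd, 6.5)
    vals = amp * np.exp(-r2 / (2.0 * sd**2))
    return np.where(r2 <= trunc**2, vals, 0.0)


def simulate_array(spec: SimulationSpec) -> tuple:
    """Render one synthetic scan; deterministic for a fixed seed.

    Returns ``(ArrayImage, GroundTruth)``.
    """
    layout = spec.layout
    rng = np.random.default_rng(spec.seed)
    side = layout.image_side_px
    p = layout.px_per_dot
    hw = p // 2

    pairmap = default_pair_map(layout)
    classes, clone_ids, amplitudes = _assign_classes(spec, pairmap, rng)

    ideal_dots = layout.ideal_dot_centers()
    ideal_markers = layout.ideal_marker_centers()
    dot_centers = ideal_dots + _warp_displacement(ideal_dots, layout, np.random.default_rng(spec.seed + 1), spec.warp_amplitude)
    marker_centers = ideal_markers + _warp_displacement(ideal_markers, layout, np.random.default_rng(spec.seed + 1), spec.warp_amplitude)

    # render blobs into their own (rounded) tiles
    canvas = np.zeros((side, side))
    cx = dot_centers[..., 0].ravel()
    cy = dot_centers[..., 1].ravel()
    amp = amplitudes.ravel()
    ax = np.rint(cx).astype(int)
    ay = np.rint(cy).astype(int)
    offs = np.arange(-hw, hw + 1)
    oxx, oyy = np.meshgrid(offs, offs)
    px = ax[:, None] + oxx.ravel()[None, :]  # (N, p*p)
    py = ay[:, None] + oyy.ravel()[None, :]
    r2 = (px - cx[:, None]) ** 2 + (py - cy[:, None]) ** 2
    vals = _blob_profile(amp[:, None], r2, spec)
    inside = (px >= 0) & (px < side) & (py >= 0) & (py < side)
    np.add.at(canvas, (py[inside], px[inside]), vals[inside])

    offset_field = (spec.offset_base + spec.offset_variation * _smooth_field((side, side), rng)).astype(np.float32)
    gain_field = (1.0 + spec.gain_variation * _smooth_field((side, side), rng)).astype(np.float32)
    for col0, col1, row0, row1, factor in spec.gain_regions:
        x0 = layout.margin_px + col0 * p
        x1 = layout.margin_px + col1 * p
        y0 = layout.margin_px + row0 * p
        y1 = layout.margin_px + row1 * p
        gain_field[y0:y1, x0:x1] *= factor

    noiseless = np.clip(offset_field + gain_field * canvas, 0.0, float(layout.bit_depth_max))

    # per-dot true background-free content (what a perfect subtraction recovers)
    residual = noiseless - offset_field
    flat = np.zeros(px.shape)
    flat[inside] = residual[py[inside], px[inside]]
    dot_signal_sums = flat.sum(axis=1).reshape(amplitudes.shape)

    image = noiseless.astype(float)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    if spec.shot_noise:
        image = image + rng.standard_normal(image.shape) * np.sqrt(np.clip(noiseless, 0, None))
    pixels = np.clip(np.rint(image), 0, layout.bit_depth_max).astype(np.uint16)

    truth = GroundTruth(
        spec=spec,
        marker_centers=marker_centers,
        dot_centers=dot_centers,
        classes=classes,
        clone_ids=clone_ids,
        amplitudes=amplitudes,
        offset_field=offset_field,
        gain_field=gain_field,
        dot_signal_sums=dot_signal_sums,
        pairmap=pairmap,
    )
    return ArrayImage(pixels=pixels, source=f"<synthetic seed={spec.seed}>"), truth


def write_manifest(truth: GroundTruth, path) -> None:
    """Write the per-dot ground truth as a TSV (x, y 1-based, as in reports)."""
    d = truth.layout.dots_per_side
    cols, rows = np.meshgrid(np.arange(1, d + 1), np.arange(1, d + 1))
    frame = pd.DataFrame(
        {
            "x": cols.ravel(),
            "y": rows.ravel(),
            "class": truth.classes.ravel(),
            "clone_id": truth.clone_ids.ravel(),
            "amplitude": truth.amplitudes.ravel(),
        }
    )
    frame.to_csv(Path(path), sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    """Read a ground-truth manifest written by :func:`write_manifest`."""
    frame = pd.read_csv(Path(path), sep="\t", keep_default_na=False, na_values=[])
    frame["amplitude"] = frame["amplitude"].astype(float)
    return frame
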