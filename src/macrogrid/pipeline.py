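"""End-to-end orchestration of the macroarray analysis and its reports.

``run_pipeline`` drives the full chain — load, position, reconstruct,
background-correct, null-removal, MAD scoring, pair validation — and
writes a result bundle of plain TSV tables plus diagnostic images.  The
analysis path contains no randomness, so identical input and config
produce byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import image_io, nulls, positioning, quantify, scoring
from .layout import ArrayLayout, make_layout

__all__ = ["RunConfig", "RunResult", "ConfigError", "run_pipeline", "stack_results", "load_scores_table"]

log = logging.getLogger("macrogrid.run")


class ConfigError(ValueError):
    """The run configuration is incomplete or inconsistent."""


@dataclass
class RunConfig:
    """Fully resolved parameters of one pipeline run."""

    image: str
    corners: positioning.CornerInput
    out_dir: str
    mirror: bool = False
    layout: ArrayLayout = field(default_factory=make_layout)
    blank_tau: object = "auto"
    radius: int = 4
    mad_threshold: float = 3.0
    min_locality_samples: int = 9
    offset_k: float = 3.0
    absolute_scores: bool = False
    pairmap: str | None = None  # None -> built-in point-symmetric default
    strict_saturation: bool = False
    saturation_limit: int = 65535
    qc_cells: int = 6

    def validate(self) -> None:
        if not self.image:
            raise ConfigError("no input image given")
        if self.corners is None:
            raise ConfigError("corner coordinates are required (the four corner marker dots)")
        if self.radius < 0:
            raise ConfigError("locality radius must be non-negative")

    def to_dict(self) -> dict:
        c = self.corners.as_array().ravel().tolist() if self.corners is not None else None
        return {
            "image": self.image,
            "corners": c,
            "out_dir": self.out_dir,
            "mirror": self.mirror,
            "layout": self.layout.to_dict(),
            "blank_tau": self.blank_tau,
            "radius": self.radius,
            "mad_threshold": self.mad_threshold,
            "min_locality_samples": self.min_locality_samples,
            "offset_k": self.offset_k,
            "absolute_scores": self.absolute_scores,
            "pairmap": self.pairmap,
            "strict_saturation": self.strict_saturation,
            "saturation_limit": self.saturation_limit,
            "qc_cells": self.qc_cells,
        }


@dataclass
class RunResult:
    """In-memory results of one run plus the paths of the written bundle."""

    config: RunConfig
    markers: positioning.MarkerGrid
    offsets: quantify.OffsetTable
    null_mask: nulls.NullMask
    scores: scoring.MADScoreTable
    positives: np.ndarray
    clone_calls: pd.DataFrame
    paths: dict
    summary: dict


def _dot_tile_origins(markers: positioning.MarkerGrid, layout: ArrayLayout) -> np.ndarray:
    """Top-left image pixel of every dot tile, shape (dots, dots, 2) as (x, y)."""
    s, p, hw = layout.cell_side_dots, layout.px_per_dot, layout.cell_halfwidth_px
    d = layout.dots_per_side
    out = np.zeros((d, d, 2), dtype=int)
    for r in range(d):
        for c in range(d):
            mx, my = markers.coords[r // s, c // s]
            out[r, c] = (mx - hw + p * (c % s), my - hw + p * (r % s))
    return out


def _write_overlay(path, img, markers, layout, positives):
    """Reconstructed array as grayscale with called dots tinted red."""
    import imageio.v3 as iio

    m = layout.margin_px
    side = layout.roi_side_px
    # display ROI from the ideal frame; called-dot tiles located via markers
    lo, hi = np.percentile(img.pixels, [1, 99.9])
    norm = np.clip((img.pixels.astype(float) - lo) / max(hi - lo, 1), 0, 1)
    rgb = np.repeat((norm * 255).astype(np.uint8)[:, :, None], 3, axis=2)
    origins = _dot_tile_origins(markers, layout)
    p = layout.px_per_dot
    for r, c in zip(*np.nonzero(positives)):
        x, y = origins[r, c]
        rgb[y : y + p, x : x + p, 0] = 255
        rgb[y : y + p, x : x + p, 1:] //= 3
    iio.imwrite(str(path), rgb[m : m + side, m : m + side])


def _write_blank_map(path, null_mask):
    """Class map image: blanks white, markers grey, valid dots black."""
    import imageio.v3 as iio

    img = np.zeros(null_mask.classes.shape, dtype=np.uint8)
    img[null_mask.marker_mask] = 128
    img[null_mask.blank_mask] = 255
    iio.imwrite(str(path), np.kron(img, np.ones((4, 4), dtype=np.uint8)))


def _write_montage(path, qc):
    import imageio.v3 as iio

    m = qc.montage()
    lo, hi = m.min(), m.max()
    iio.imwrite(str(path), ((m - lo) / max(hi - lo, 1) * 255).astype(np.uint8))


def _write_histogram_png(path, hist: pd.DataFrame):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    if len(hist):
        ax.bar(hist["bin_left"], hist["count"], width=hist["bin_right"] - hist["bin_left"], align="edge")
        ax.set_yscale("log")
    ax.set_xlabel("number of MADs from median")
    ax.set_ylabel("dot count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Run the full analysis and write the result bundle to ``cfg.out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("macrogrid")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        with open(out / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

        layout = cfg.layout
        img = image_io.load_image(cfg.image, mirror=cfg.mirror)
        sat = image_io.check_saturation(img, cfg.saturation_limit, strict=cfg.strict_saturation)
        if not sat.passed:
            log.warning("%d saturated pixel(s) at limit %d", sat.count, sat.limit)

        markers = positioning.build_marker_grid(img, cfg.corners, layout)
        qc = positioning.qc_sample(img, markers, layout, k=min(cfg.qc_cells, layout.cells_per_side))
        tiles = positioning.extract_dot_tiles(img, markers, layout)

        raw_off = quantify.dot_offsets(tiles)
        offsets = quantify.repair_offsets(raw_off, layout, radius=cfg.radius, k=cfg.offset_k)
        sums, corrected = quantify.subtract_and_sum(tiles, offsets, layout)

        null_mask = nulls.classify_nulls(corrected, layout, tau=cfg.blank_tau)
        scores = scoring.mad_scores(
            sums, null_mask, layout,
            radius=cfg.radius,
            min_samples=cfg.min_locality_samples,
            absolute=cfg.absolute_scores,
        )
        positives = scoring.call_positives(scores, cfg.mad_threshold)
        hist = scoring.score_histogram(scores)
        pm = scoring.load_pair_map(cfg.pairmap) if cfg.pairmap else scoring.default_pair_map(layout)
        calls = scoring.validate_pairs(scores, pm, threshold=cfg.mad_threshold)

        # ---- result bundle (all coordinates 1-based in the files) ----------
        paths = {}

        frame = scores.to_frame()
        paths["scores"] = out / "scores.tsv"
        frame.to_csv(paths["scores"], sep="\t", index=False)

        paths["clone_calls"] = out / "clone_calls.tsv"
        calls.to_csv(paths["clone_calls"], sep="\t", index=False)

        d = layout.dots_per_side
        colsg, rowsg = np.meshgrid(np.arange(1, d + 1), np.arange(1, d + 1))
        nm = pd.DataFrame(
            {
                "x": colsg.ravel(),
                "y": rowsg.ravel(),
                "class": null_mask.class_names().ravel(),
                "sink_score": null_mask.sink.ravel(),
            }
        )
        paths["null_mask"] = out / "null_mask.tsv"
        nm.to_csv(paths["null_mask"], sep="\t", index=False)

        offs = pd.DataFrame(
            {
                "x": colsg.ravel(),
                "y": rowsg.ravel(),
                "offset": offsets.offset.ravel(),
                "raw_offset": offsets.raw.ravel(),
                "flagged": offsets.flagged.ravel().astype(int),
            }
        )
        paths["offsets"] = out / "offsets.tsv"
        offs.to_csv(paths["offsets"], sep="\t", index=False)

        paths["histogram"] = out / "histogram.tsv"
        hist.to_csv(paths["histogram"], sep="\t", index=False)

        paths["qc_montage"] = out / "qc_montage.png"
        _write_montage(paths["qc_montage"], qc)
        paths["blank_map"] = out / "blank_map.png"
        _write_blank_map(paths["blank_map"], null_mask)
        paths["overlay"] = out / "overlay.png"
        _write_overlay(paths["overlay"], img, markers, layout, positives)
        paths["histogram_png"] = out / "histogram.png"
        _write_histogram_png(paths["histogram_png"], hist)

        summary = {
            "saturated_pixels": sat.count,
            "marker_fallbacks": markers.fallback_count,
            "qc_marker_darkest": int(qc.marker_darkest.sum()),
            "qc_cells": int(qc.marker_darkest.size),
            "offset_outliers": int(offsets.flagged.sum()),
            "blanks": int(null_mask.blank_mask.sum()),
            "degenerate_dots": int((scores.flag == scoring.FLAG_DEGENERATE).sum()),
            "sparse_dots": int((scores.flag == scoring.FLAG_SPARSE).sum()),
            "positive_dots": int(positives.sum()),
            "positive_pairs": int((calls["status"] == "positive").sum()) if len(calls) else 0,
        }
        log.info("run summary: %s", summary)
        paths = {k: str(v) for k, v in paths.items()}
        return RunResult(
            config=cfg,
            markers=markers,
            offsets=offsets,
            null_mask=null_mask,
            scores=scores,
            positives=positives,
            clone_calls=calls,
            paths=paths,
            summary=summary,
        )
    finally:
        root.removeHandler(handler)
        handler.close()


def load_scores_table(bundle_dir) -> pd.DataFrame:
    """Read the per-dot scores table from a result bundle directory."""
    return pd.read_csv(Path(bundle_dir) / "scores.tsv", sep="\t")


def stack_results(tables: dict) -> pd.DataFrame:
    """Stack per-dot score tables from several samples into long format.

    Parameters
    ----------
    tables : mapping sample_id -> scores DataFrame (as written by
        :func:`run_pipeline` / read by :func:`load_scores_table`).

    All tables must share the same dot grid; one row per (sample, dot),
    no imputation.
    """
    if not tables:
        raise ValueError("nothing to stack")
    frames = []
    ref_keys = None
    for sample, frame in tables.items():
        keys = frame[["x", "y"]].to_numpy()
        if ref_keys is None:
            ref_keys = keys
        elif keys.shape != ref_keys.shape or not np.array_equal(keys, ref_keys):
            raise ValueError(f"sample {sample!r} uses a different array layout; cannot stack")
        f = frame[["x", "y", "sum", "score", "flag"]].copy()
        f.insert(0, "sample", sample)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
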