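"""Shared fixtures: small synthetic arrays exercising the full pipeline."""

import numpy as np
import pytest

from macrogrid import make_layout
from macrogrid.synthetic import SimulationSpec, simulate_array


@pytest.fixture(scope="session")
def small_layout():
    """A 6x6-cell array (30 dots per side) for fast geometry tests."""
    return make_layout(dots_per_side=30)


@pytest.fixture(scope="session")
def mid_layout():
    """A 12x12-cell array (60 dots per side) for pipeline-level tests."""
    return make_layout(dots_per_side=60)


@pytest.fixture(scope="session")
def clean_sim(mid_layout):
    """Noise-free, warp-free scan with flat fields: the exact-recovery surface."""
    spec = SimulationSpec(
        layout=mid_layout,
        seed=11,
        warp_amplitude=0.0,
        noise_sd=0.0,
        offset_variation=0.0,
        gain_variation=0.0,
        n_signal_pairs=12,
    )
    img, truth = simulate_array(spec)
    return img, truth


@pytest.fixture(scope="session")
def noisy_sim(mid_layout):
    """Realistic conditions at reduced size: warp 3 px, noise sd 50."""
    spec = SimulationSpec(layout=mid_layout, seed=23, n_signal_pairs=12)
    img, truth = simulate_array(spec)
    return img, truth


def run_analysis(img, truth, **kw):
    """Convenience: the full analysis chain on an in-memory image."""
    from macrogrid import nulls, positioning, quantify, scoring

    layout = truth.layout
    markers = positioning.build_marker_grid(img, truth.corners(), layout)
    tiles = positioning.extract_dot_tiles(img, markers, layout)
    offsets = quantify.repair_offsets(quantify.dot_offsets(tiles), layout)
    sums, corrected = quantify.subtract_and_sum(tiles, offsets, layout)
    null_mask = nulls.classify_nulls(corrected, layout, tau=kw.get("tau", "auto"))
    scores = scoring.mad_scores(sums, null_mask, layout)
    return dict(
        markers=markers, tiles=tiles, offsets=offsets, sums=sums,
        corrected=corrected, null_mask=null_mask, scores=scores,
    )
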