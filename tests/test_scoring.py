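"""Locality-MAD scores, positive calling and duplicate-pair validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macrogrid import make_layout
from macrogrid.layout import locality_members
from macrogrid.nulls import BLANK, MARKER, NullMask
from macrogrid.scoring import (
    FLAG_DEGENERATE,
    FLAG_OK,
    PairMap,
    PairMapError,
    call_positives,
    default_pair_map,
    load_pair_map,
    mad_scores,
    score_histogram,
    validate_pairs,
)


def brute_force_mad(sample):
    """Sort-based oracle: median of absolute deviations from the median."""
    s = sorted(sample)
    n = len(s)
    med = (s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2]))
    dev = sorted(abs(x - med) for x in s)
    return (dev[n // 2] if n % 2 else 0.5 * (dev[n // 2 - 1] + dev[n // 2]))


def all_valid_mask(layout):
    classes = np.zeros((layout.dots_per_side,) * 2, dtype=np.int8)
    return NullMask(classes=classes, sink=np.zeros_like(classes, dtype=float), tau=0.0)


def test_module_scores_match_brute_force_oracle(small_layout):
    """Scores recomputed per dot from sorted locality samples (independent
    oracle) equal the vectorised module output, clipped localities and
    null exclusions included."""
    rng = np.random.default_rng(123)
    checked = 0
    for rep in range(4):
        sums = rng.gamma(3.0, 500.0, size=(30, 30))
        classes = np.zeros((30, 30), dtype=np.int8)
        classes[2::5, 2::5] = MARKER
        classes[rng.random((30, 30)) < 0.08] = BLANK
        classes[2::5, 2::5] = MARKER
        nulls = NullMask(classes=classes, sink=np.zeros((30, 30)), tau=0.0)
        table = mad_scores(sums, nulls, small_layout, radius=4)
        for _ in range(250):
            col, row = rng.integers(0, 30, size=2)
            members = locality_members((col, row), 4, small_layout)
            sample = [sums[r, c] for c, r in members if classes[r, c] == 0]
            if classes[row, col] != 0:
                assert np.isnan(table.score[row, col])
                continue
            med = np.median(sample)
            mad = brute_force_mad(sample)
            if len(sample) < 9 or mad == 0:
                assert np.isnan(table.score[row, col])
            else:
                expect = (sums[row, col] - med) / mad
                assert table.score[row, col] == pytest.approx(expect, rel=1e-12)
                checked += 1
    assert checked >= 500


class TestMadScores:
    def test_constructed_locality_one_to_fortynine(self):
        """A locality holding the sums 1..49 with the dot of interest at 37
        scores (37 - 25) / 12 = 1.0."""
        layout = make_layout(dots_per_side=20)
        sums = np.zeros((20, 20))
        center = (10, 10)  # (col, row)
        members = locality_members(center, 4, layout)
        assert len(members) == 49
        values = [v for v in range(1, 50) if v != 37]
        it = iter(values)
        for col, row in members:
            if (col, row) == center:
                sums[row, col] = 37.0
            else:
                sums[row, col] = float(next(it))
        table = mad_scores(sums, all_valid_mask(layout), layout, radius=4)
        assert table.score[10, 10] == pytest.approx(1.0)

    def test_all_equal_sums_are_degenerate(self, small_layout):
        sums = np.full((30, 30), 5.0)
        table = mad_scores(sums, all_valid_mask(small_layout), small_layout)
        assert np.all(table.flag == FLAG_DEGENERATE)
        assert np.all(np.isnan(table.score))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(a=st.floats(0.01, 1e3), b=st.floats(-1e6, 1e6))
    def test_affine_invariance_of_scores(self, a, b):
        layout = make_layout(dots_per_side=30)
        rng = np.random.default_rng(8)
        sums = rng.gamma(4.0, 1000.0, size=(30, 30))
        nulls = all_valid_mask(layout)
        base = mad_scores(sums, nulls, layout)
        shifted = mad_scores(a * sums + b, nulls, layout)
        assert np.nanmax(np.abs(base.score - shifted.score)) < 1e-9

    def test_marker_and_blank_excluded_from_scores_and_samples(self, small_layout):
        rng = np.random.default_rng(9)
        sums = rng.normal(1000, 50, size=(30, 30))
        classes = np.zeros((30, 30), dtype=np.int8)
        classes[2::5, 2::5] = MARKER
        classes[0, 0] = BLANK
        sums[0, 0] = 1e9  # would wreck its locality if it were sampled
        nulls = NullMask(classes=classes, sink=np.zeros((30, 30)), tau=0.0)
        table = mad_scores(sums, nulls, small_layout)
        assert table.flag[2, 2] == "marker"
        assert table.flag[0, 0] == "blank"
        assert np.isnan(table.score[0, 0])
        assert np.nanmax(np.abs(table.score)) < 10  # the planted 1e9 never leaked

    def test_row_count_covers_every_dot(self, small_layout):
        sums = np.random.default_rng(0).normal(100, 10, (30, 30))
        table = mad_scores(sums, all_valid_mask(small_layout), small_layout)
        frame = table.to_frame()
        assert len(frame) == small_layout.total_dots
        assert frame["x"].between(1, 30).all() and frame["y"].between(1, 30).all()
        assert not frame.duplicated(subset=["x", "y"]).any()

    def test_sparse_locality_flagged(self, small_layout):
        rng = np.random.default_rng(2)
        sums = rng.normal(1000, 50, size=(30, 30))
        classes = np.zeros((30, 30), dtype=np.int8)
        classes[:6, :6] = BLANK  # isolate the corner dot's locality
        classes[0, 0] = 0
        nulls = NullMask(classes=classes, sink=np.zeros((30, 30)), tau=0.0)
        table = mad_scores(sums, nulls, small_layout, min_samples=9)
        assert table.flag[0, 0] == "sparse"
        assert np.isnan(table.score[0, 0])


class TestCallPositives:
    def test_infinite_threshold_empty(self, small_layout):
        sums = np.random.default_rng(3).normal(1000, 100, (30, 30))
        table = mad_scores(sums, all_valid_mask(small_layout), small_layout)
        assert call_positives(table, np.inf).sum() == 0

    def test_strict_inequality_at_the_threshold(self, small_layout):
        table = mad_scores(
            np.random.default_rng(4).normal(1000, 100, (30, 30)),
            all_valid_mask(small_layout),
            small_layout,
        )
        table.score[:] = np.nan
        table.flag[:] = FLAG_OK
        table.score[0, 0], table.score[0, 1], table.score[0, 2] = 2.9, 3.0, 3.1
        mask = call_positives(table, 3.0)
        assert mask.sum() == 1 and mask[0, 2]

    def test_histogram_counts_valid_dots(self, small_layout):
        sums = np.random.default_rng(5).normal(1000, 100, (30, 30))
        table = mad_scores(sums, all_valid_mask(small_layout), small_layout)
        hist = score_histogram(table)
        assert hist["count"].sum() == int(table.valid_mask.sum())


class TestPairMap:
    def test_default_map_pairs_every_non_marker_dot(self, small_layout):
        pm = default_pair_map(small_layout)
        per_cell = (small_layout.cell_side_dots**2 - 1) // 2
        assert per_cell == 12
        assert len(pm) == small_layout.total_cells * per_cell
        counts = pm.table.groupby("clone_id").size()
        assert (counts == 2).all()

    def test_point_symmetry_about_the_marker(self, small_layout):
        pm = default_pair_map(small_layout)
        s = small_layout.cell_side_dots
        for clone, grp in list(pm.table.groupby("clone_id"))[:30]:
            (x1, y1), (x2, y2) = grp[["x", "y"]].to_numpy()
            # replicate coordinates mirror through the cell center
            assert (x1 - 1) % s + (x2 - 1) % s == s - 1
            assert (y1 - 1) % s + (y2 - 1) % s == s - 1

    def test_unpaired_clone_rejected(self):
        bad = pd.DataFrame({"x": [1], "y": [1], "clone_id": ["c"], "replicate": [1]})
        with pytest.raises(PairMapError, match="exactly 2"):
            PairMap(table=bad)

    def test_duplicate_position_rejected(self):
        bad = pd.DataFrame(
            {"x": [1, 1], "y": [1, 1], "clone_id": ["c", "c"], "replicate": [1, 2]}
        )
        with pytest.raises(PairMapError, match="twice"):
            PairMap(table=bad)

    def test_tsv_roundtrip(self, tmp_path, small_layout):
        pm = default_pair_map(small_layout)
        path = tmp_path / "pairs.tsv"
        pm.table.to_csv(path, sep="\t", index=False)
        again = load_pair_map(path)
        pd.testing.assert_frame_equal(
            again.table.sort_values(["clone_id", "replicate"]).reset_index(drop=True),
            pm.table.sort_values(["clone_id", "replicate"]).reset_index(drop=True),
        )


class TestValidatePairs:
    def make_scores(self, small_layout, assignments):
        sums = np.random.default_rng(6).normal(1000, 100, (30, 30))
        table = mad_scores(sums, all_valid_mask(small_layout), small_layout)
        table.score[:] = 0.0
        table.flag[:] = FLAG_OK
        for (row, col), val in assignments.items():
            table.score[row, col] = val
        return table

    def test_pair_logic(self, small_layout):
        pm = default_pair_map(small_layout)
        # clone c000_000_p00 maps dots (1,1) and (5,5) 1-based -> (0,0), (4,4)
        both = self.make_scores(small_layout, {(0, 0): 5.0, (4, 4): 6.0})
        calls = validate_pairs(both, pm)
        row = calls.set_index("clone_id").loc["c000_000_p00"]
        assert row["status"] == "positive"
        assert row["min_score"] == 5.0

        single = self.make_scores(small_layout, {(0, 0): 5.0, (4, 4): 1.0})
        calls = validate_pairs(single, pm)
        assert calls.set_index("clone_id").loc["c000_000_p00", "status"] == "negative"

    def test_unevaluable_replicate_never_positive(self, small_layout):
        pm = default_pair_map(small_layout)
        table = self.make_scores(small_layout, {(0, 0): 50.0, (4, 4): 50.0})
        table.flag[4, 4] = FLAG_DEGENERATE
        table.score[4, 4] = np.nan
        calls = validate_pairs(table, pm)
        assert calls.set_index("clone_id").loc["c000_000_p00", "status"] == "unevaluable"

    def test_pair_calls_never_exceed_half_dot_calls(self, noisy_sim):
        from conftest import run_analysis

        img, truth = noisy_sim
        res = run_analysis(img, truth)
        calls = validate_pairs(res["scores"], truth.pairmap)
        n_dot = int(call_positives(res["scores"]).sum())
        n_pair = int((calls["status"] == "positive").sum())
        assert n_pair <= n_dot // 2

    def test_out_of_layout_pairmap_rejected(self, small_layout):
        table = self.make_scores(small_layout, {})
        bad = PairMap(
            table=pd.DataFrame(
                {"x": [1, 99], "y": [1, 99], "clone_id": ["c", "c"], "replicate": [1, 2]}
            )
        )
        with pytest.raises(PairMapError, match="outside"):
            validate_pairs(table, bad)
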