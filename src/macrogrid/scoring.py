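"""Locality-MAD normalization, positive calling and duplicate-pair validation.

There is no absolute reference spot on these membranes, so expression is
quantified relative to each dot's locality: for dot *d* with locality
sample S (the background-subtracted sums of the valid dots within the
radius-4 disc around *d*, itself included),

    score(d) = (sum(d) - median(S)) / MAD(S)

where MAD is the raw median of absolute deviations from the sample
median (no normal-consistency factor — "number of MADs from median" is
the reporting unit itself).  Because median and MAD are taken locally,
any locality-wise affine distortion of the sums (local background gain
and offset) cancels exactly, which is what makes scores comparable
across arrays, samples and timepoints.

A dot is called positive when its score strictly exceeds the threshold
(3 by default).  Clones are printed as duplicate dot pairs; a clone is
validated positive only when *both* replicates exceed the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import ArrayLayout, shifted_stack
from .nulls import BLANK, MARKER, NullMask

__all__ = [
    "MADScoreTable",
    "PairMap",
    "PairMapError",
    "FLAG_OK",
    "FLAG_MARKER",
    "FLAG_BLANK",
    "FLAG_DEGENERATE",
    "FLAG_SPARSE",
    "mad_scores",
    "call_positives",
    "score_histogram",
    "default_pair_map",
    "load_pair_map",
    "validate_pairs",
]

log = logging.getLogger(__name__)

FLAG_OK = "ok"
FLAG_MARKER = "marker"
FLAG_BLANK = "blank"
FLAG_DEGENERATE = "degenerate"  # local MAD is 0: score undefined
FLAG_SPARSE = "sparse"  # too few valid dots in the locality


@dataclass
class MADScoreTable:
    """Per-dot normalized scores with exclusion flags.

    ``score`` is NaN wherever ``flag`` is not ``"ok"``; ``n`` is the
    number of valid dots in each locality sample.  ``to_frame`` emits
    the linearized (x, y, sum, score, flag) table covering every dot
    position exactly once (coordinates 1-based, as in the report files).
    """

    score: np.ndarray
    sums: np.ndarray
    n: np.ndarray
    flag: np.ndarray  # object array of flag strings
    radius: int
    threshold: float | None = None

    @property
    def valid_mask(self) -> np.ndarray:
        return self.flag == FLAG_OK

    def to_frame(self) -> pd.DataFrame:
        d = self.score.shape[0]
        cols, rows = np.meshgrid(np.arange(1, d + 1), np.arange(1, d + 1))
        return pd.DataFrame(
            {
                "x": cols.ravel(),
                "y": rows.ravel(),
                "sum": self.sums.ravel(),
                "score": self.score.ravel(),
                "flag": self.flag.ravel(),
            }
        )


def mad_scores(
    sums: np.ndarray,
    nulls: NullMask,
    layout: ArrayLayout,
    radius: int = 4,
    min_samples: int = 9,
    absolute: bool = False,
) -> MADScoreTable:
    """Score every valid dot against its locality median and MAD.

    Marker and blank dots are excluded both from scoring and from every
    locality sample.  Localities are clipped at the array border.  Dots
    whose sample has zero MAD (``degenerate``) or fewer than
    ``min_samples`` valid members (``sparse``) carry no score and can
    never be called positive.

    With ``absolute`` the reported value is |deviation| / MAD instead of
    the signed deviation.
    """
    d = layout.dots_per_side
    sums = np.asarray(sums, dtype=float)
    if sums.shape != (d, d) or nulls.classes.shape != (d, d):
        raise ValueError("sums / null mask do not match the layout")

    valid = nulls.valid_mask
    grid = np.where(valid, sums, np.nan)
    stack = shifted_stack(grid, radius)
    n = np.sum(~np.isnan(stack), axis=0)
    med = np.nanmedian(stack, axis=0)
    mad = np.nanmedian(np.abs(stack - med), axis=0)

    flag = np.full((d, d), FLAG_OK, dtype=object)
    flag[nulls.classes == MARKER] = FLAG_MARKER
    flag[nulls.classes == BLANK] = FLAG_BLANK
    sparse = valid & (n < min_samples)
    flag[sparse] = FLAG_SPARSE
    degen = valid & ~sparse & (mad == 0)
    flag[degen] = FLAG_DEGENERATE

    ok = flag == FLAG_OK
    score = np.full((d, d), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (sums - med) / mad
    score[ok] = np.abs(raw[ok]) if absolute else raw[ok]
    log.info(
        "MAD scoring: %d scored, %d degenerate, %d sparse (radius %d)",
        int(ok.sum()), int(degen.sum()), int(sparse.sum()), radius,
    )
    return MADScoreTable(score=score, sums=sums, n=n, flag=flag, radius=radius)


def call_positives(scores: MADScoreTable, threshold: float = 3.0) -> np.ndarray:
    """Boolean mask of dots whose score strictly exceeds the threshold."""
    with np.errstate(invalid="ignore"):
        return scores.valid_mask & (scores.score > threshold)


def score_histogram(scores: MADScoreTable, bin_width: float = 0.5) -> pd.DataFrame:
    """Dot count vs number of MADs from median, for the score histogram."""
    vals = scores.score[scores.valid_mask]
    if vals.size == 0:
        return pd.DataFrame({"bin_left": [], "bin_right": [], "count": []})
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


# ---------------------------------------------------------------------------
# duplicate-pair validation
# ---------------------------------------------------------------------------


class PairMapError(ValueError):
    """The clone pair map is inconsistent with the layout."""


@dataclass
class PairMap:
    """Mapping from dot positions to duplicate clone spots.

    ``table`` has columns x, y (1-based dot coordinates), clone_id,
    replicate (1 or 2).  Every clone id must map exactly two dots.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"x", "y", "clone_id", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise PairMapError(f"pair map missing column(s): {sorted(missing)}")
        counts = self.table.groupby("clone_id").size()
        bad = counts[counts != 2]
        if len(bad):
            raise PairMapError(
                f"{len(bad)} clone id(s) do not map exactly 2 dots "
                f"(e.g. {bad.index[0]!r} maps {int(bad.iloc[0])})"
            )
        dup = self.table.duplicated(subset=["x", "y"])
        if dup.any():
            raise PairMapError("pair map assigns the same dot position twice")

    def __len__(self) -> int:
        return self.table["clone_id"].nunique()


def default_pair_map(layout: ArrayLayout) -> PairMap:
    """Point-symmetric default pairing of the non-marker dots of every cell.

    Within each cell, dot (i, j) is paired with its mirror through the
    central marker, (s-1-i, s-1-j), giving (s^2 - 1) / 2 clone pairs per
    cell (12 for 5x5 cells).  The published clone configuration of the
    commercial library is proprietary to the array vendor, so this
    symmetric map is a documented stand-in; real runs should pass the
    vendor's map as a TSV.
    """
    s = layout.cell_side_dots
    m = layout.marker_within
    rows = []
    for ci in range(layout.cells_per_side):  # cell row
        for cj in range(layout.cells_per_side):  # cell col
            k = 0
            for wi in range(s):  # within row
                for wj in range(s):  # within col
                    if (wi, wj) == (m, m):
                        continue
                    mirror = (s - 1 - wi, s - 1 - wj)
                    if (wi, wj) > mirror:
                        continue
                    clone = f"c{ci:03d}_{cj:03d}_p{k:02d}"
                    for rep, (a, b) in enumerate([(wi, wj), mirror], start=1):
                        rows.append(
                            {
                                "x": cj * s + b + 1,
                                "y": ci * s + a + 1,
                                "clone_id": clone,
                                "replicate": rep,
                            }
                        )
                    k += 1
    return PairMap(table=pd.DataFrame(rows))


def load_pair_map(path) -> PairMap:
    """Read a pair map TSV with columns x, y, clone_id, replicate."""
    return PairMap(table=pd.read_csv(Path(path), sep="\t"))


def validate_pairs(
    scores: MADScoreTable, pairmap: PairMap, threshold: float = 3.0
) -> pd.DataFrame:
    """Clone-level calls requiring both duplicate spots above threshold.

    Returns one row per clone with both replicate scores, the pair
    minimum, and status ``positive`` (both > threshold), ``negative``
    (both evaluable, at least one <= threshold) or ``unevaluable`` (a
    replicate is a marker/blank/degenerate/sparse dot — such clones are
    never positive).  Single-replicate exceedances surface in QC via the
    per-dot table.
    """
    d = scores.score.shape[0]
    t = pairmap.table
    if (t["x"] < 1).any() or (t["x"] > d).any() or (t["y"] < 1).any() or (t["y"] > d).any():
        raise PairMapError("pair map coordinates outside the layout")
    rows = []
    for clone, grp in t.sort_values("replicate").groupby("clone_id"):
        xs = grp["x"].to_numpy() - 1
        ys = grp["y"].to_numpy() - 1
        sc = scores.score[ys, xs]
        flags = scores.flag[ys, xs]
        evaluable = [f == FLAG_OK for f in flags]
        if all(evaluable):
            status = "positive" if bool(np.all(sc > threshold)) else "negative"
        else:
            status = "unevaluable"
        rows.append(
            {
                "clone_id": clone,
                "x1": int(xs[0] + 1), "y1": int(ys[0] + 1),
                "x2": int(xs[1] + 1), "y2": int(ys[1] + 1),
                "score1": sc[0], "score2": sc[1],
                "min_score": float(np.min(sc)) if all(evaluable) else np.nan,
                "status": status,
            }
        )
    calls = pd.DataFrame(rows)
    n_pos = int((calls["status"] == "positive").sum()) if len(calls) else 0
    log.info("pair validation: %d / %d clones positive at threshold %g", n_pos, len(calls), threshold)
    return calls
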