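# Methods

This note documents the model behind each pipeline stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Array model

A macroarray is a square lattice of `dots_per_side²` printed spots
(default 240² = 57 600), partitioned into cells of `cell_side_dots²`
dots (default 5² = 25) whose central dot is a dark printed fiducial
marker. On a 10 px/mm 16-bit scan each dot occupies a 9×9-px tile, so
the region of interest is 2160×2160 px inside a nominally 2250×2250-px
frame. All geometry is derived from these constants; smaller layouts
exercise identical code paths and are used throughout the test-suite.

A *locality* is the set of dots within a Euclidean radius (in dot
units) of a dot of interest, boundary included, the dot itself
included, clipped (never padded) at the array border. Radius 3 covers
29 lattice positions, radius 4 covers 49. Radius 4 is the default for
both background repair and score normalization: it trades locality of
the gain field against sample size, and a 3-dot disc barely leaves the
dot's own cell (4 positions at best), making it vulnerable to
cell-level artifacts.

## Positioning

Membrane distortion is smooth but non-linear, and errors accumulate
over 22 cm, so a single global interpolation cannot place 57 600 dots.
The pipeline uses the four corner marker coordinates (the only manual
input) for a bilinear interpolation of all marker positions, then
refines each marker inside a ±22-px window:

* Otsu's threshold is applied to the window histogram, seeded on the
  lower half (the marker is the darkest printed object), and re-applied
  within the dark class while that class covers more than 25% of the
  window — this peels away background/bright classes until the marker
  blob is isolated.
* Among dark connected components the one nearest the window center is
  kept; implausible blobs (< 4 px or > 25% of the window) trigger a
  fallback to the interpolated position, which is flagged and counted.
  More than 5% fallbacks aborts the run.
* The refined center is the darkness-weighted centroid rounded to an
  integer pixel. Summation uses fixed 9×9 blocks, so sub-pixel
  anchoring would add nothing; on warp-free noise-free renders the
  recovered grid is exact, and under the demo conditions (3-px warp,
  sd-50 noise) the maximum error is well under 1 px.

Bilinear (not projective) interpolation is deliberate: the residual is
absorbed by refinement, and a projective fit would suggest a rigidity
the membrane does not have. Rotation beyond what refinement absorbs is
out of scope — large membranes are physically easy to orient.

## Background offset and summation

Offsets are treated as homogeneous within one dot tile. The offset
estimate is the tile's **minimum pixel** — the pixel expressing no
luminance. Dots whose signal fills the entire tile leave no background
pixel; their minima are detected as robust outliers against the
locality: |offset − local median| > k·1.4826·MAD with k = 3 (the
standard three-sigma robust cut; 1.4826 makes the MAD a consistent
sigma estimate). Detection and replacement both use the *raw* offsets
(two passes), so a replacement never contaminates a neighbour's
statistics. When the local MAD is zero, any deviation is flagged.
Marker and blank dots participate in offset statistics — their
background is as informative as anyone's.

Subtraction clamps at zero (intensities are counts) and all 81 pixels
are summed without a shape mask. The multiplicative gain field is
*not* estimated here: the membranes carry no reference spot, so only
relative gain is defined, and it cancels in the locality-normalized
score.

Note one honest limitation of the minimum-pixel estimator: under pixel
noise of sd σ it is biased low by roughly the expected minimum of 81
noise draws (~2.3σ) and carries the variance of an extreme order
statistic, which the 81-pixel summation amplifies. The outlier repair
bounds the tails of this error; the remainder is common-mode across
dots and removed by the locality median.

## Null removal

Markers are removed purely by position (exactly one per cell). Blank
dots — printed positions with no expressing clone — are removed via
the divergence of the intensity gradient: a signal-bearing dot is a
smooth bright blob into which the gradient field converges, so the
Laplacian over the blob core is strongly negative. The *sink score* is

    score(tile) = − Σ_core laplace(G₁ * tile)

with Gaussian smoothing of sd 1 px, edge-replicate continuation, and
the core being the tile minus a 2-px rim. The rim exclusion matters:
summed over the *whole* tile the discrete Laplacian telescopes to ~0
for any tile (divergence theorem), so the full-tile sum is not a
usable statistic; the core sum is a stable center-minus-surround
response, linear in the tile, zero on constants and sign-symmetric
(bright blob positive, dark blob negative with equal magnitude). It is
evaluated as an inner product with a precomputed 9×9 weight matrix.
Blank detection runs on background-subtracted tiles so the smooth
background's own curvature does not leak into the scores.

The blank threshold `tau` resolves from:

* a number — absolute cutoff (dots below it are blank);
* `"auto"` (default) — blank sink scores are noise around zero and
  therefore symmetric about zero, while every expressed dot scores
  well above zero. The blank scale is estimated from the sub-zero
  scores, σ̂ = 1.4826·median|negatives|, and the cutoff placed at 6σ̂.
  If negatives are rarer than 0.2% of dots they are isolated artifacts
  rather than a blank population, and nothing is classed blank (in the
  exactly noise-free limit, where blanks score exactly 0, the cutoff
  is the midpoint gap to the smallest positive score). The rule
  scales with the image gain, so classification is invariant under
  affine intensity changes. Arrays with genuinely very few blanks
  (< ~0.4%) will have them missed by `auto`; pass an absolute `tau`.
* `"mad:k"` — median − k·MAD of the non-marker scores, for parity
  experiments; note that for unimodal score distributions small k
  misclassifies the lower tail of expressed dots by construction.

Blank pairing (blanks occur as duplicate pairs, at most two pairs per
cell) is an array property, not an algorithm step, so it is not
enforced during classification.

## Scoring and pair validation

For each valid dot, the locality sample is the background-subtracted
sums of the valid dots in its radius-4 disc. The reported value is
(sum − median)/MAD with the **raw** MAD — no 1.4826 factor — because
"number of MADs from median" is itself the reporting unit and the
customary threshold (3) is calibrated in it. The score is signed:
overexpression is a positive deviation; negative deviants are not
outliers of interest (an `absolute` option exists for parity checks).
Dots whose sample has zero MAD (`degenerate`) or fewer than 9 valid
members (`sparse`) are flagged and excluded from calling, as are
markers and blanks; every dot still appears exactly once in the output
table. Positives are strict exceedances (score > 3, not ≥), and a
clone is positive only when both replicates are evaluable and both
exceed the threshold; a clone with an unevaluable replicate is
reported `unevaluable`, never positive.

Local median/MAD normalization makes the score exactly invariant under
locality-wise affine transforms of the sums — the formal content of
"local offset and gain are eliminated" — which is what licenses
stacking scores across samples and timepoints.

## Synthetic scans

The generator renders everything the pipeline must survive:

* smooth additive offset and multiplicative gain surfaces (bicubic
  spline over a 5×5 coefficient grid; defaults 3000 ± 600 and
  1.0 ± 0.2 on the 16-bit scale), plus optional sharp-edged gain
  regions for invariance experiments;
* a quadratic-polynomial displacement field scaled to a chosen maximum
  (default 3 px) — smooth, non-linear, heterogeneous;
* Gaussian read noise (default sd 50) and optional shot noise;
* dark markers (depth 2500) at every cell center;
* blank pairs with region-banded probabilities (0.02/0.08/0.15 across
  three vertical bands, ≤ 2 pairs per cell) mimicking empty wells in
  library source plates — straight density boundaries included;
* dots as radially truncated Gaussian blobs (sd 1.8 px) confined to
  their own 9×9 tile. Above an amplitude knee (6000) the width blooms
  with amplitude, so ordinary spots leave exact background pixels in
  their tile corners while extreme signals fill the whole tile — the
  case that forces the offset-outlier repair.

Expression amplitudes follow a two-regime model. Basal (bacterial
background) amplitudes are uniform(300, 4000) **independently per
spot**: spot-to-spot printing and growth variability dominates the
background level, so the two replicates of an unrecognized clone are
uncorrelated. Seropositive amplitudes are uniform(8000, 20 000) **per
clone**, shared by both replicates up to a ±10% spot factor: a true
serum response lights up both spots together. This split is the regime
in which duplicate-pair validation is informative — single-spot
excursions (noise, background-estimation error, expression outliers)
are uncorrelated between replicates and are vetoed by the pair rule,
while genuine responses reproduce. If basal levels were instead fully
pair-correlated, a strongly expressing but unrecognized clone would be
statistically indistinguishable from a weak serum response and no
pairwise rule could separate them.

What the generator does **not** emulate: chemiluminescence physics and
scanner MTF, rotation/misorientation, saturation artifacts beyond
simple clipping, spot-shape irregularities, and the vendor's actual
clone-pair geometry (the shipped point-symmetric pair map is a
documented stand-in; real analyses should supply the vendor map).
Passing recovery tests therefore demonstrates the statistical machinery
under realistic geometry, background and noise — not robustness to
every physical artifact of a wet-lab membrane.

The default demo (`demo_spec`): full-size array, 48 seropositive
pairs, 3-px warp, sd-50 noise. Test-suite simulations use 30–120-dot
layouts to keep runtimes in seconds; the end-to-end acceptance check
runs the full 240-dot demo once.

## Numerical conventions

* Internal indices are 0-based (col = x, row = y); all report files use
  1-based x/y.
* Refined marker coordinates are integer pixels; tiles are views on the
  original grid, so sums are order-independent and reruns are
  byte-identical (no randomness anywhere in the analysis path).
* Localities at borders are clipped; local statistics use NaN-aware
  medians over a stacked-shift representation, so a vectorised result
  equals the per-dot enumeration exactly.
* 8-bit input is promoted by ×257 (full scale to full scale) and the
  original depth recorded; lossy TIFF compression is rejected.
* Saturation (pixels ≥ 65 535 by default) is a warning; `--strict-saturation`
  turns it into an abort before any analysis.
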