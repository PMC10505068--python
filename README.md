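# macrogrid

Automated semiquantitative analysis of spotted **protein macroarrays** —
large PVDF membranes printed with an annotated library of *E. coli*
clones expressing recombinant human proteins, probed with serum to
reveal an individual's antibody repertoire. Each membrane scan holds
57 600 printed spots ("dots", 9×9 px each) grouped into 2 304 cells of
5×5 dots with a dark fiducial marker dot at each cell center; clones
are printed as duplicate spot pairs.

General microarray software does not handle this format (array size,
resolution, lack of reference spots), and the membranes carry strong,
spatially varying background offset and gain. `macrogrid` turns one
16-bit grayscale TIFF scan into a per-dot table of locality-normalized
scores and pair-validated clone calls:

1. **Two-stage positioning** — the operator supplies only the four
   corner marker coordinates; a bilinear ("four-point") interpolation
   approximates every cell's marker, then each marker is refined by
   low-intensity thresholding of its window (the membrane warp is
   non-linear, so interpolation alone is not enough).
2. **Reconstruction** — each cell is the ±22 px square around its
   refined marker; dots are fixed 9×9 blocks inside it.
3. **Background subtraction** — per dot, the offset is the minimum
   pixel of its tile; offsets that are robust outliers against their
   locality (signal filled the whole tile) are replaced by the local
   median offset; subtraction is clamped at zero and all 81 pixels are
   summed (no shape mask needed).
4. **Null removal** — marker dots are excluded by position; blank
   (signal-free) dots are detected from the divergence of the intensity
   gradient field ("sinks") and excluded from all statistics.
5. **Scoring** — for dot *d* with locality sample *S* (valid dots
   within a 4-dot-radius disc, 49 lattice positions),

   ```
   score(d) = (sum(d) − median(S)) / MAD(S)
   ```

   with the raw (unscaled) median absolute deviation. The result is
   the *number of MADs from median*; because median and MAD are local,
   the local background offset and gain cancel, making scores
   comparable across arrays, samples and timepoints.
6. **Pair validation** — a clone is called positive only when **both**
   duplicate spots score above the threshold (default > 3).

A synthetic-scan generator with full ground truth (warp, background
fields, blank structure, clone amplitudes) makes the entire pipeline
testable without scanner data.

## Worked example

Simulate a reduced 60×60-dot array with 10 seropositive clone pairs,
then analyse it (`truth.yaml` records the corner coordinates an
operator would read off the displayed scan):

```sh
$ macrogrid simulate --out sim --seed 7 --layout-dots 60 --n-signal-pairs 10
$ macrogrid run --image sim/image.tif \
    --corners 66.97,68.18,561.54,67.61,66.80,562.12,560.01,562.45 \
    --out run --layout-dots 60 --pairmap sim/pairmap.tsv
blanks: 252
degenerate_dots: 0
marker_fallbacks: 0
offset_outliers: 169
positive_dots: 38
positive_pairs: 10
qc_cells: 36
qc_marker_darkest: 36
saturated_pixels: 0
sparse_dots: 0
```

All 36 QC cells show the marker as the darkest block (positioning is
sound), 252 dots were excluded as blanks, 38 single dots exceeded
3 MADs but only 10 clones survived pair validation — exactly the 10
simulated ones. The per-dot table (1-based x/y, one row per dot):

```
$ head -4 run/scores.tsv
x   y   sum      score                 flag
1   1   36838.0  -0.4540167773146004   ok
2   1   74507.0  1.4086012035813886    ok
3   1   26229.0  -0.9755706956922994   ok
```

and the clone-level calls:

```
    clone_id  x1  y1  x2  y2    score1    score2
c000_008_p05  41   2  45   4 21.672829 14.160183
c001_007_p01  37   6  39  10 24.401617 15.577786
c002_010_p07  53  12  53  14 11.120689 29.208491
...
```

The bundle also contains a QC montage of evenly sampled cells, a
blank-dot map, a score histogram, and an overlay image with called
dots in red. `macrogrid stack run1 run2 … --out table.tsv` joins
score tables from several samples into one long table on (x, y) for
longitudinal comparisons.

For real scans, pass the vendor's clone pair map as a TSV with columns
`x, y, clone_id, replicate`; the built-in default pairs dots
point-symmetrically through each cell's marker (12 pairs per cell).

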