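# Methods

This note documents the models, parameter choices and numerical
conventions behind `dermseg`, and what the synthetic experiments do and
do not demonstrate.

## Problem and pipeline

A dermoscopic image contains a pigmented lesion that is darker than the
surrounding skin, corrupted by hair strokes, specular (glare)
highlights, illumination gradients and sensor noise.  The pipeline
produces a binary lesion mask in two stages:

1. **Seed stage** — gray conversion → median filter → Gaussian
   smoothing → maximum-entropy threshold → binary morphology →
   largest component.  Output: a single-component seed mask.
2. **Refinement stage** — the seed boundary initializes a greedy
   active contour that locks onto the image gradient; the converged
   contour is rasterized and cleaned (small open/close, hole fill,
   largest component).

Both stages are deterministic: identical input and configuration give
bit-identical masks.

## Seed stage

**Gray conversion** uses BT.601 luma (0.299 R + 0.587 G + 0.114 B), the
conventional default when no colorimetric calibration is available.

**Median filter** (default 9×9, on the raw gray image).  Entropy-based
thresholds are extremely sensitive to sparsely populated histogram
tails: a class containing 0.1% of the pixels spread over 30 gray
levels has entropy ln 30 ≈ 3.4, which can exceed the entropy of a
proper lesion/skin split and pull the argmax to a degenerate tail
split.  Dark hairs and saturated highlights create exactly such tails,
so they must be removed *before* the histogram is formed.  The window
is sized to the artifacts: a w×w median erases dark strokes up to
about w/2 px wide and bright discs up to about w/2 px radius, while
leaving the lesion (tens of pixels across) intact.  The alternative
placement — a 3×3 majority vote applied to the thresholded binary mask
(`median_target="mask"`) — is retained in the configuration; it cleans
salt-and-pepper mask noise but cannot protect the threshold itself,
and on the phantom suite it leaves the seed stage unusable whenever
hairs are present.

**Gaussian smoothing** uses the explicitly normalized kernel
`exp(-(n1²+n2²)/2σ²)/Σ`, σ = 2 by default, support 2·ceil(3σ)+1 (>99%
of the mass).  The isotropic kernel factorizes exactly, so the
convolution is performed as two 1-D passes.  Borders are reflect-padded
(edge sample repeated) so image dimensions never change.

**Histogram support clipping** (default 1st/99th percentile).  Even
after the median, artifact residue (e.g. hair crossings, which are
wider than single strokes) can leave a sparse tail.  Clipping the
image to its inner-quantile range collapses each tail onto a single
occupied level with ≥1% mass, whose class entropy is 0 — removing the
degenerate-split incentive without altering the threshold criterion.
Set `clip_percentile: 0` to disable.

**Maximum-entropy threshold.**  T maximizes H_B(t)+H_W(t) over all t
where both classes are occupied; natural logarithms (the argmax is
base-invariant); 0·ln 0 := 0; empty-class entropy := 0 with such t
excluded; ties break to the smallest t.  Class sums run over occupied
levels only, so splits at unoccupied levels produce bit-identical
entropies and the tie-break is exact rather than at the mercy of
floating-point summation order.  Lesions are darker than skin, so the
default polarity takes pixels ≤ T as foreground.

**Morphology.**  Area opening removes 8-connected components below 100
px (hair fragments, specular dots at ~226×276 image scale); disk
opening (radius 9) shears off thin protrusions; disk closing (radius
25) bridges fragmented lesion parts; the largest 8-connected component
is kept (ties broken by raster order of the first pixel).  Opening
precedes closing by default; both radii and the order are
configurable.  Erosion and dilation treat everything outside the frame
as background; closing is evaluated on a zero-padded canvas and
cropped, so it remains extensive (result ⊇ input) up to the frame.
Hole filling floods the background from the border with
4-connectivity, the topologically consistent dual of the 8-connected
foreground.

## Refinement stage

**Energy.**  A closed contour of N points carries
E = Σ ½(α|v_i−v_{i−1}|² + β|v_{i−1}−2v_i+v_{i+1}|²) + E_img(v_i) with
E_img = −|∇(G_σ∗I)|², central differences on the smoothed gray image,
normalized so min = −1, max = 0.  Normalization makes α and β
scale-free against image contrast.  The classic external-constraint
term is identically zero here: nothing in the automatic pipeline
supplies user constraints.

**Greedy evolution.**  Points are visited in index order; each point
examines the integer offsets of its (2k+1)² window, current position
included, and moves only on strict improvement.  A candidate is scored
by the change it induces in the total energy — both adjacent elastic
terms, the three bending terms containing the point, and the image
term — so every accepted move strictly lowers E: the energy history is
non-increasing, and evolution cannot cycle.  A sweep that moves no
point terminates evolution; otherwise it stops at `max_iterations`
(logged, last contour returned).

**Weights.**  Defaults α = 0.02, β = 0.01.  Because the image well has
unit depth, the weights must be small: a 1-px move at typical 3–5 px
point spacing changes the elastic term by ≈ 2αs and the bending term
by ≈ 3β·O(1), and these must not exceed the ~0.1–0.3 per-pixel slope
of the edge well, or the contour detaches from (or never reaches) the
boundary.  Measured on the phantom suite, α = 0.1 collapses contours
straight through the lesion edge, while α = 0.02 improves the seed
mask on 20/20 phantoms.

**Capture range and multiscale evolution.**  With integer moves and
total-energy scoring, the contour cannot drift across regions where
the field is flat (any move costs internal energy and gains nothing).
`evolve_multiscale` runs the greedy snake against fields of decreasing
σ (default 16→8→4→2): heavy smoothing spreads an edge's gradient well
over ~3σ pixels so a distant contour feels it; the final fine scale
localizes the boundary.  Within each scale the energy history is
non-increasing.  The pipeline itself initializes on the seed boundary,
already within a few pixels of the lesion edge, and uses a single
σ = 2 field.

**Initialization and rasterization.**  The seed boundary is traced as
the longest 0.5-level iso-contour of the mask, resampled to N = 100
points uniformly by arc length, and given a fixed orientation
(positive shoelace sum in row/col coordinates).  The converged contour
is filled with an even-odd polygon rasterization plus its Bresenham
perimeter (self-intersections are logged and filled even-odd), then a
radius-3 disk opening/closing smooths rasterization jaggies, holes are
filled, and the largest component is kept, guaranteeing a
single-component, hole-free result.

## Evaluation

Jaccard P = |A∩R|/|A∪R| and Dice DSC = 2|A∩R|/(|A|+|R|), linked by
DSC = 2P/(1+P) ≥ P; both symmetric.  Two empty masks score 1.0 with a
warning (a correctly empty prediction on a lesion-free control is a
perfect answer; the ratio is formally 0/0).  Batch evaluation emits
one row per image pair plus mean P and DSC; shape mismatches mark the
row failed without aborting the batch.

## Phantom generator

Each phantom is a 226×276 RGB image: skin base color (196, 168, 148),
an elliptical lesion (semi-axes 20–60 px) darker by a configurable
contrast (default 70 luma units), with its radius modulated by
harmonics of order 2–5 at relative amplitude 0.08 so the boundary is
irregular but simple.  Artifacts, applied in order after the lesion:
a zero-mean linear illumination ramp (peak amplitude 10), dark hair
polylines 2–4 px wide at intensity ≈ 45, saturated specular discs of
radius 1–3 px, and additive Gaussian noise (σ default 5, clipped to
[0, 255]).  The ground-truth mask is the rasterized lesion region
before any artifact.  A single integer seed fixes everything;
suite member *k* uses seed + *k*, so suites extend without
reshuffling.

What the phantoms do **not** emulate: skin texture, pigment networks,
multi-focal or border-touching lesions, lens vignetting, color
calibration differences, and lesions lighter than skin.  Passing the
phantom experiments therefore demonstrates the pipeline's robustness
to the modeled artifact classes — not clinical-grade accuracy on real
dermoscopy, which requires expert-annotated images.

## Experiment sizes

The standard experiments use 20 phantoms with moderate artifacts
(hairs 0–20, contrast 50–100, noise σ 0–8), 10 synthetic disks with
radii in [20, 50] initialized at 1.5× the radius, 200 random
histograms against an exhaustive threshold scan, 100 random 16×16
masks against brute-force morphology oracles, and 1000 random mask
pairs for the metric identities.  On one CPU the full suite runs in
well under a minute.

## Known limitations

- The greedy snake moves points on the pixel grid; sub-pixel boundary
  accuracy comes only from the final rasterization, not the contour.
- Meaningful bending regularization (large β) is incompatible with
  single-point integer moves; β is kept small and boundary smoothness
  is delegated to the morphological refinement.
- The entropy threshold assumes a darker-lesion polarity; inverse
  polarity must be set explicitly.
- Percentile clipping assumes artifacts occupy less than ~1% of the
  image per tail; images dominated by glare would need a larger
  clip fraction.
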