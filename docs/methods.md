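# Methods

## Problem and model

`ellipick` localizes the two long-axis endpoints of an elongated fruit
(e.g. dragon fruit) from a per-pixel foreground segmentation of a
detector crop, and labels them *head* (blossom end) vs *root* (branch end,
where the picking cut is made). The fruit outline is modeled as an ellipse
in implicit conic form

    A x² + B xy + C y² + D x + E y + F = 0,    B² − 4AC < 0,

with coefficient vector `s = (A, …, F)` defined up to scale. The algebraic
distance of a point `(x, y)` to the conic is `D = H·s` with
`H = (x², xy, y², x, y, 1)`; the fit minimizes `Σ Dᵢ²` over the traced
boundary points of each candidate region.

### Normalization constraint

`Σ Dᵢ²` alone is degenerate (`s = 0` minimizes it) and a unit-norm
constraint can return hyperbolas on noisy data. We adopt the
ellipse-specific quadratic constraint `4AC − B² = 1` (direct least-squares
ellipse fitting), which guarantees an elliptical minimizer whenever one
exists. The solver is the partitioned 3×3 reduction of the constrained
generalized eigenproblem (Halíř–Flusser form), chosen for numerical
stability over the raw 6×6 eigensolve. Input points are centered to zero
mean and scaled to unit RMS radius before the scatter matrix is built
(raw pixel coordinates in the thousands make the scatter matrix severely
ill-conditioned); coefficients are mapped back by polynomial substitution.
The test suite cross-checks this solver against an independent dense 6×6
generalized-eigenproblem oracle.

### Parametric form and endpoints

`conic_to_params` converts to center `(cx, cy)`, semi-axes `a ≥ b > 0`,
and major-axis rotation `theta ∈ [0, π)` via the eigendecomposition of the
quadratic part; degenerate conics (point/imaginary ellipses) are rejected.
The long-axis endpoints are `center ± a·(cos θ, sin θ)`, ordered by
`(y, then x)` so outputs are deterministic. Coordinates are continuous,
0-based, `x` = column, `y` = row, pixel centers at integers — one stated
convention for every module.

## Mask processing and candidate selection

The segmentation is binarized, zero-padded with a background margin of
`max(h, w) // 2` (an ellipse fitted to a mask touching the crop edge can
otherwise exceed the canvas and corrupt rasterization/IoU), opened with a
disc of radius 1 and closed with radius 2 (small discs remove speckle
without eroding the fruit; the radii are package defaults, since no
canonical kernel exists for this step), then split into 8-connected
components (8-connectivity keeps thin diagonal boundary runs intact).
Each component's outer boundary is traced as an ordered, duplicate-free
closed loop (marching-squares contours at the 0.5 iso-level, sub-pixel),
which stabilizes the fit compared with unordered gradient-edge pixels.

One ellipse is fitted per component; each candidate is rasterized
(pixel-center interior test) and scored by IoU against the full cleaned
foreground. The max-IoU candidate wins; exact ties go to the larger
component. Speckle distractors form separate components whose tiny
ellipses overlap almost none of the fruit, so selection is robust to them
without size thresholds. Components with fewer than 6 boundary points
cannot constrain a conic and are skipped (logged).

All geometry is computed on the padded working canvas; a `frame_offset`
on every mask maps results back to the original image frame, so reported
endpoints are camera-frame coordinates.

## Endpoint labeling

Two rectangular patches of size `K1 × K2 = round(α·w) × round(α·h)` (with
`w, h` the cropped fruit image size, `α = 0.4` by default, floor 8 px) are
cut from the original image, centered on the endpoints and clipped at the
image border. `α = 0.4` covers the fruit tip plus adjacent branch/flower
context without spanning the whole fruit. A pluggable classifier maps each
patch to `(class ∈ {head, root}, confidence ∈ [0, 1])`; patches are passed
raw (resizing/preprocessing is the classifier's concern). If both patches
receive the same class, the higher-confidence patch keeps it and the other
is flipped; the flipped endpoint's reported confidence is one minus its
overridden prediction (the contract does not define a confidence for an
unpredicted class, and this choice keeps the value in [0, 1] with the
natural complement reading). Exact ties keep the first patch's prediction
(logged). Two reference classifiers ship with the package: a
brightness-cue reader matched to the synthetic generator, and a
constant-class stub for exercising the conflict rule.

## Metrics

* Detection: P, R per confusion counts; AP by greedy confidence-ordered
  matching (a prediction claims the highest-IoU unmatched truth of its
  class at IoU ≥ 0.5) and exact integration of the precision envelope over
  recall (all-points interpolation — the exact-integral reading of
  "area under the PR curve"); mAP is the unweighted class mean.
* Segmentation: pixel confusion per class (background = 0, fruit = 1),
  IoU = TP/(TP+FP+FN), MIoU the mean over both classes.
* Endpoints: DE is the mean of the two per-endpoint Euclidean distances —
  the alternative reading √(Σ of four squared differences / 2) is noted
  but not used, as mean-of-norms preserves pixel units and matches the
  per-endpoint grouping; AE is the absolute axis-angle difference reduced
  modulo 180° to [0°, 90°] (axes are direction-free); CA counts individual
  endpoint label decisions, T/(T+F).
* Undefined metrics (empty denominators) are reported as `None` with a
  warning, never silently coerced to 0.

## Synthetic scenes

The generator emulates one detector crop of a side-view fruit on a
224×224 canvas (the working resolution of the segmentation stage):
semi-major axis 40–70 px, elongation a/b in 1.6–2.6, center jitter ±10 px,
uniform rotation. Optional degradations: smooth radial boundary noise
(low-order Fourier perturbation of the radius, harmonics 2–4, RMS
displacement = σ px — fruit-like undulation rather than pixel salt),
1–3 px speck distractors placed outside the fruit, and a circular
occlusion "bite" of a configurable area fraction at a random boundary
point. A bright disc is planted just beyond the head endpoint, emulating
the flower that often remains attached at the blossom end; the
brightness-cue classifier reads exactly this cue, which closes the
head/root loop without a trained network.

What passing tests show — and do not show: the synthetic scenes have
piecewise-constant colors, a perfectly elliptical (or smoothly perturbed)
outline, and a noiseless cue. Success here demonstrates the geometry,
selection rule, frame bookkeeping, and metric definitions are correct; it
says nothing about segmentation quality on real orchard imagery or about
any trained classifier's accuracy, which enter through the predictor
contracts.

## Numerical choices and degenerate inputs

* Fit failure (< 6 points, collinear/coincident points, non-elliptical
  solution) raises a typed error; the selection stage skips such
  candidates and fails only when no component yields an ellipse.
* Circles report `theta = 0` (rotation is arbitrary).
* Angle comparisons in tests are modulo π.
* Empty masks raise a stage-tagged error rather than propagating NaNs.
* IoU of two empty masks is defined as 0.

## Problem sizes

Dataset-scale checks use 200 random ellipses / point clouds for the fit,
100 clean scenes for end-to-end recovery, 50 seeds per boundary-noise
level σ ∈ {0, 1, 2, 4} px, 100 random detection sets for the AP oracle,
and 20 trials for the equivariance checks — sizes at which the measured
quantities are stable across seeds while the whole suite stays fast.

## Known limitations

* One fruit per crop: multi-fruit masks are resolved by the max-IoU rule
  to the single best ellipse, not split.
* The boundary tracer follows the outer contour only; interior holes are
  handled by the closing step, not by hole-filling.
* Heavy occlusion (large bites) biases the fitted ellipse toward the
  remaining arc; no robust/RANSAC variant is provided.
* The Labelme converter is best-effort (rectangle and point shapes only).
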