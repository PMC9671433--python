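# Methods

This note documents the models, numerical choices and limitations of
`vesselflow`. It describes what the code computes and what the synthetic
validation does and does not establish; all quantitative statements here
are reproduced by the test suite or `scripts/acceptance.py`.

## Problem setting

High-speed transillumination video of a microvessel (reference regime:
640×640 px at 2000 frames/s, 0.34 µm/px, arterioles of 20–30 µm) shows a
dark vessel band on lighter tissue. Two obstacles dominate: episodic
whole-frame motion from muscle contraction and respiration, and poor
intensity contrast exactly at the vessel wall. The pipeline addresses the
first by *selecting* still frames rather than registering moving ones, and
the second by segmenting on temporal variance rather than intensity.

## Stage A — rest interval

The Pearson correlation r_k between consecutive frames (k, k+1), computed
over a user-placed interrogation window on stationary tissue, is near 1
when the tissue is still and dips sharply during a contraction. The rest
interval is the contiguous span of L frames (default L = 50) maximizing
the mean of its L−1 pair correlations.

Choices:

* **Consecutive pairing**, not correlation against a fixed reference: a
  transient contraction then produces a localized dip rather than a level
  shift, and slow drift does not degrade the score.
* **Mean** (not minimum) as the window score: the quantity of interest is
  aggregate stillness; the mean is smooth and matches the plateau-plus-dip
  shape of real traces.
* Ties go to the earliest start. Window sums use cumulative sums; a
  1e-10 tolerance on the maximum absorbs their float drift so the
  earliest-tie rule is exact.
* Pairs where a window is uniform (zero variance) have undefined
  correlation; they are flagged NaN and make every containing window
  ineligible rather than being silently dropped.
* The window must sample tissue, not lumen — flowing cells decorrelate
  frames even at perfect rest. Placement is a user input;
  `suggest_window` proposes the lowest-temporal-variance block but never
  overrides an explicit choice.

## Stage B — temporal-variance segmentation

Per pixel, the unbiased sample variance (divisor N−1) of the gray level
over the N rest-interval frames. Flowing cells make the lumen the
high-variance class; static tissue is near the sensor noise floor.

* **Polarity**: lumen = high variance. The alternative reading (lumen =
  low) would contradict the mechanism that makes the method work — the
  fluctuation is generated by blood flow.
* **Auto threshold**: Otsu's method computed on the log10-variance
  histogram and mapped back to the linear scale. Temporal variances span
  orders of magnitude (noise ≈ σ_noise², flow-driven values two to three
  decades higher); on the linear histogram Otsu's equal-spread assumption
  fails and the threshold lands inside the lumen class. A manual threshold
  overrides.
* **Pre-threshold smoothing** (default 1 px Gaussian, the optical PSF
  scale; `smooth_sigma` in the pipeline config): the variance signal
  crosses the threshold inside the outermost lumen pixel, and when the
  wall is aligned with the pixel grid that boundary pixel is lost
  coherently along the whole segment — a one-sided half-pixel bias that
  only ever shrinks the vessel. Light smoothing regularizes the crossing;
  oblique walls are unaffected because grid sampling already dithers them.
* **Cleanup**: morphological closing (disc radius 2 px), removal of
  components below 100 px² (8-connectivity), hole filling. Defaults are
  small against a 59–88 px vessel and configurable; the operation is
  idempotent.

## Stage C — diameter

Orientation is the global maximum of a straight-line Hough transform
(1° × 1 px resolution) over the mask's edge pixels, reported in degrees
counter-clockwise from the image horizontal in [0, 180), ties to the
smaller angle. The mask is rotated to horizontal with nearest-neighbour
interpolation (stays binary; canvas expanded so nothing clips; area drift
≤ 2 %). Diameter = white-pixel area / number of analyzed columns ×
pixel size. A per-column thickness trace is available for
wall-irregularity inspection. Percent change = (basal − stimulated) /
basal × 100; dilation gives negative values, never clipped.

## Stage D — micro-PIV

Mesh: n_rows × n_cols (default 15 × 5) windows of 20×20 px. Wall rows are
the per-column mean first/last lumen row; row centers are evenly spaced,
symmetric about the centerline, outermost windows touching the walls.
Overlap follows from lumen height H: 1 − (H − ws)/((n_rows−1)·ws), clamped
to [0, 0.95]. A lumen narrower than one window raises a mesh error (the
constricted-vessel condition).

Matching: normalized 2-D cross-correlation γ evaluated at every integer
shift keeping the template inside the search area (±15 px default).
Implementation uses vectorized sliding windows with explicit per-window
centering — algebraically the textbook two-pass formula, verified against
a naive double-loop oracle to 1e-9. Ties on γ resolve to the smallest
displacement magnitude, then row-major order. Windows whose peak γ falls
below 0.3 are marked invalid: a particle-free window correlates only with
noise and its argmax is uniform-random — the standard PIV signal-quality
floor. Zero-variance templates are invalid with a distinct reason code.

Speed = |displacement| × pixel size × frame rate / frame gap (gap 1 by
default at 2000 fps).

**Integer vs subpixel.** At the reference frame rate a 1400 µm/s
centerline flow moves 2.06 px per frame, so integer matching quantizes
speeds to 680 µm/s steps. On clean synthetic texture the per-pair argmax
never dithers across the step boundary, so time-averaging does not recover
sub-quantum resolution and the fitted bluntness index inherits a bias of
up to a few tenths. The optional 3-point Gaussian peak interpolation
(`subpixel`) resolves ~0.1 px and is used by the acceptance script; the
library default stays integer, which is the method as printed.

Outliers: Tukey's fences at 1.5·IQR beyond the quartiles (inclusive
linear-interpolation quartiles), pooled over all valid vectors of the
field. IQR = 0 removes nothing; fewer than 4 values skips filtering with a
warning.

## Profile fit

Per column, valid speeds are time-averaged per row; columns are then
averaged unweighted. Radial position of a row is the signed distance of
its window center from the lumen centerline. The model
V(r) = Vmax (1 − (|r|/R)^k) is fitted by least squares with R fixed from
the measured diameter (R is a measured geometric quantity; co-fitting it
lets the fit trade wall position against bluntness). Vmax is linear given
k and is profiled out analytically, so the search is one-dimensional in k
∈ [0.5, 10] (L-BFGS-B multistart from k = 1, 2, 4, then a bounded polish
to 1e-6 relative). Rows at |r| ≥ R (possible after wall jitter) are
clamped to 0.999 R with a warning. A fit whose Vmax does not exceed the
RMS residual is rejected as flat — the no-flow degenerate case.

Derived quantities: mean velocity Vmax·k/(k+2) (exact disc integral of the
model), flow = mean velocity × πR². k = 2 gives the parabolic mean Vmax/2;
k → ∞ approaches plug flow.

## Synthetic scenes

`render_scene` draws a darker vessel band (gray 130 vs background 170 with
static low-amplitude value-noise texture and a thin darker wall line) at a
given orientation, seeds RBC-sized cells (radius 3.4 µm = 10 px) uniformly
in the lumen, and advects them along the axis by V(r)/frame rate with
periodic wrap-around (particle count conserved). Cells render as
anti-aliased discs with a parabolic shading dome — the interior carries a
gradient so any correlation window on a cell has texture — and overlapping
cells combine by maximum opacity (opaque absorbers: a stack is no darker
than one). Default areal density 0.08 /µm² approximates the projected
coverage of a ~25 µm blood column at tube hematocrit ~25 %: in
transillumination nearly every lumen pixel lies over some cell, making the
lumen a continuous moving texture. Jitter episodes translate whole frames
by random nonzero integer offsets (periodic boundary); contraction
schedules interpolate diameter linearly between knots, rescaling cell
radial positions with the lumen. Sensor noise is i.i.d. Gaussian (default
σ = 2 gray levels = 5 % of vessel contrast) added before 8-bit
quantization. All randomness derives from one seeded generator; renders
are bit-reproducible.

Default flow: Vmax 1400 µm/s, k = 2 — mid-range of the experimental
regime (20–30 µm arterioles, ~700–1800 µm/s). Where scenes sweep the
diameter, Vmax scales proportionally (constant wall shear rate, the
approximate physiological scaling along the arteriolar tree); holding Vmax
fixed would make near-wall cells of a 35 µm vessel move less than their
own diameter within the 50-frame window, an artifact of the scene, not of
the method.

**What a green synthetic test does not establish.** The generator omits
light scattering and defocus, the biconcave RBC shape and its deformation,
plasma/cell two-phase rheology, radial migration and the cell-free layer,
out-of-plane motion, vessel curvature and bifurcations, and non-rigid
tissue deformation (jitter is a rigid translation). Recovery of diameter
and k on these scenes validates the algorithmic chain, not performance on
degraded in-vivo optics.

## Degenerate inputs and failure modes

* No-flow video: the variance image is flat; auto-thresholding raises, and
  with a manual threshold the PIV stage reports zero velocities and the
  fit rejects the flat profile.
* Constriction below one window height (≈ 6.8 µm): PIV raises a mesh
  error; diameter-only analysis (`stop_after="diameter"`, used by the
  timecourse command) still reports the constricted diameter down to the
  strongest reduction exercised (80 %).
* A mask with no line structure (e.g. all-true) has no orientation; the
  pipeline falls back to 0° with a warning.
* AVI decoding requires an imageio video plugin; without one, a clear
  format error suggests multi-page TIFF or a frame directory.

## Known limitations

* The 50-frame rest interval bounds how slow a near-wall cell can be and
  still generate variance: the flow-visible lumen is intrinsically a
  fraction of a pixel inside the geometric wall. The 1 px pre-smoothing
  compensates on average; per-instance wall placement is still ±1 px.
* Integer PIV quantizes speeds (680 µm/s at the reference calibration,
  gap 1); use `subpixel` or a larger `piv_gap` for slow flows.
* Asymmetric profiles are reported (per-side residuals) but the fitted
  model is axisymmetric.
* Orientation is a single global estimate; curved vessels need a smaller
  ROI where the segment is straight.
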