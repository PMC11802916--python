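# Methods

This note records the models, conventions, parameter choices and numerical
decisions behind `hemoflow`, and what the synthetic-data validation does and
does not establish about real microscope data.

## Conventions

Images follow the row/column convention with the origin at the top-left
pixel; `x` runs along columns, `y` along rows, both converted to µm by the
pixel size. Because image rows grow downward, all *exported angles* (edge
directions, rose plots) are measured counter-clockwise from +x after
flipping the y axis, i.e. in the mathematical convention a viewer of the
displayed image expects. Cosine similarities are unaffected by this choice
as long as both vectors share a frame. Velocities are µm/min
(pixel displacement × pixel size / frame interval × 60), matching the scale
of lamellar actin flows (a few µm/min); divergence is therefore 1/min.

## PIV (`flow`)

Windowed cross-correlation between consecutive frames. Parameters are
stated in calibrated units and converted to integer pixels per movie:
window side = round(√window_area / pixel size) px, overlap and search side
likewise. Defaults: 1.2 µm² windows, 0.8 µm overlap, 2 µm² search area,
correlation gate 0.5.

Decisions the correlation definition leaves open, and how they are fixed
here:

- **Correlation score** is the zero-normalized cross-correlation (window
  means subtracted, divided by window norms), so the 0.5 gate is invariant
  to intensity offset and gain.
- **Subpixel refinement** is a 3-point parabolic fit per axis around the
  integer peak — standard PIV practice; the offset is clipped to ±0.5 px.
  On noiseless translations of 0.5–2 px/frame the median absolute error is
  ≈ 0.03 px (the tests assert ≤ 0.2 px).
- **Search truncation at frame borders**: candidate displacements whose
  target window would leave the frame are not evaluated; a node with no
  admissible candidate, a flat (zero-variance) window, a peak correlation
  ≤ the gate, or a center outside the mask is invalid.
- Flat candidate windows get correlation −1 rather than NaN, so they can
  never win the peak search.

**Interpolation** is a validity-weighted Gaussian convolution: each
component is convolved with separable kernels (space: size 5 µm, σ 1 µm,
in grid-node units; time: size 5 frames, σ 2 frames) applied to
value × validity and normalized by the convolved validity. Consequences:
invalid nodes inside a kernel support of valid neighbors become valid;
sequence ends are handled by renormalization, never by padding or
fabricated frames; the output is a convex combination of valid inputs, so
the maximum speed can never grow. A kernel whose physical size is below one
grid step degenerates to no smoothing.

**Mean flow speed** averages |**v**| over every valid node-frame sample
with equal weight — frames are not reweighted by their valid-node count;
this choice is deliberate and documented because other weightings are
defensible. **Streamlines** integrate the *time-averaged* field (validity-
weighted) with fixed-step RK4 and bilinear sampling, terminating at the
grid boundary, invalid (NaN) samples, stagnation (< 1e-12 µm/min), or a
step cap. **Deformation maps** advect a regular vertex grid by forward
Euler (velocity sampled bilinearly per frame × frame interval); vertices
whose trajectory leaves the valid field freeze at their exit position and
are flagged invalid in the output. Two-channel flow comparison (e.g. actin
vs. Moesin) is exposed on both raw and interpolated fields, since either is
a reasonable input to the cosine-similarity summary.

## Divergence and regions (`fieldstats`)

∂u/∂x + ∂v/∂y with central differences on interior nodes and first-order
one-sided differences at grid borders (the scheme `np.gradient` implements),
using the grid spacing in µm, hence units 1/min. Central differences are
exact on linear fields, which the tests exploit: the linear sink
**v** = −a**r** has divergence −2a to rounding error. A node is invalid
wherever any node its stencil touches is invalid.

The cortical region is the set of pixels outside the body mask whose
Euclidean distance (pixel-lattice EDT × pixel size) to it is ≤ 5 µm by
default; the lamellar region is cell minus body minus ring. Regional means
weight every valid node-frame sample equally. Because "averaging the
negative divergence" is ambiguous, two estimators are provided: the default
clips the field to min(div, 0) and averages all region nodes; the
alternative averages only strictly negative nodes. The default is named in
the summary function so outputs can state which estimator produced them.

## Cortex mapping (`cortexmap`)

The ratio image is (num − bg)/(den − bg) per pixel, gated where the
background-subtracted denominator exceeds a floor (default 1e-3 intensity
units) — gated pixels are invalid, never infinite. Backgrounds default to
zero; for real images an out-of-cell estimate should be supplied per
channel.

**Circumscribing ellipse.** "Minimal ellipse centered at the body centroid
containing the cell" is solved by searching orientation φ and axis ratio
q = b/a: for fixed (φ, q) the smallest admissible semi-major axis has the
closed form a(φ, q) = max over mask pixels of √(x′² + y′²/q²) in the
rotated frame, so the area πa²q is minimized over a coarse (72 × 37) grid
and refined by Nelder–Mead, with containment enforced exactly on the mask's
convex-hull pixel centers (plus a 1e-9 inflation). Ties break toward
smaller eccentricity, so a disk returns a circle.

**Line scans** are a deterministic stand-in for an interactive line tool:
bilinear sampling at 0.5-px steps, thickness realized as 10 parallel lines
at 1-px offsets averaged per step. Interpolation is validity-normalized
(weights only valid pixels, requiring ≥ half the bilinear weight), so
values never bleed across the mask or gated-ratio boundary. Lamellar
profiles start at equally arc-length-spaced points on the ellipse edge
(every 100 px by default) and run toward the body centroid; each scan's
axis starts at 0 where it first enters the cell. The lamellar
*distribution* re-anchors each scan at its first body-mask crossing
(lamella positive, body negative); only the distance axis is re-anchored —
intensities are not rescaled.

**Cortical enrichment** runs scans outward from the body centroid in 72
directions, aligns them at the body-circumscribing ellipse edge (x = 0),
bins at 0.5-px resolution, and requires ≥ 10% of scans to carry data at
both probes. The body-center probe sits at x = −3 in axis units that the
original description leaves unstated; here the default is −3 µm and the
unit is a parameter (`offset_units` = "um" or "px") rather than a guess at
intent. On the synthetic cell (5 µm body, 2× ring of width 2 µm) the
statistic recovers 1.98 against a ground truth of 2.0; a constant image
gives exactly 1.

## FRAP (`frap`)

The correction multiplies the background-subtracted bleach trace by
control(pre)/control(n), where control(pre) is the mean of the first five
control frames. This cancels any decay *shared multiplicatively* by both
ROIs: if both carry e^(−βt), the corrected trace is the undecayed recovery
times a constant (the mean pre-bleach decay factor), and the constant drops
out in the subsequent normalization — the tests assert proportionality to
1e-9. Note the control trace itself is not background-subtracted (the
correction formula is applied as stated), so exact cancellation presumes a
control ROI whose background contribution is negligible.

Normalization maps the first post-bleach frame to 0 and the pre-bleach mean
to 1 and is invariant under affine transforms of the corrected trace.

The recovery model is a one-phase association F(t) = P·(1 − e^(−kt)) over
0–14 s, fitted by unweighted least squares (`scipy.optimize.curve_fit`),
initialized at P₀ = max in window and k₀ = 1/(first time F exceeds P₀/2),
with k bounded in (1e-4, 1e3) 1/s. The half-life is reported from the
fitted rate, ln 2 / k, not read off the curve. Degenerate traces (no
recovery signal) raise a convergence error carrying the initial values and
residuals instead of returning a spurious estimate. The one-phase model is
the standard single-component FRAP default; it is a configurable choice,
and no mobile-fraction or pure-diffusion model is attempted.

On the synthetic generator (5 pre + 45 post frames at 0.5 s, plateau
fraction 0.6, bleach floor 0.2, additive noise σ = 0.02 on unit-scale
signals) the median recovered half-life over 50 seeds is within 5% of
ln 2/k for k ∈ {0.1, 0.35, 1.0} 1/s. The *per-seed* spread is wider — for
k = 0.1/s the Fisher information of this window/noise combination bounds
the median absolute error near 8% — so single-trace half-lives at slow
rates should be treated as noisy; medians across cells are the robust
readout.

## Morphodynamics (`morphodynamics`)

**Persistence** windows slide by one frame; each window ends at the nearest
frame whose offset is ≥ 60 s, because frame intervals (10–20 s) need not
divide 60 s. Zero-path windows are skipped. The ratio is clamped at 1.0 to
absorb float round-off (net displacement cannot exceed path length).

**Direction of motion** for polarity and edge analysis is the one-step
forward displacement of the nucleus, unsmoothed — the simplest reading of
"direction of nuclear motion". Polarity counts pixels strictly in front of
/ behind the perpendicular line through the nuclear centroid; pixels
exactly on the line are excluded from both halves, so symmetric masks give
exactly 1.

**CIL acceleration** uses the central second difference over the ±60 s
sampling offsets, (p(+60) − 2p(0) + p(−60))/60², with track positions
linearly interpolated at the exact sample times. The partner is placed at
+x, so repulsion — accelerating away from the partner — is negative. The
metric is invariant to global rotation and translation to rounding error.

**Edge dynamics.** Boundary correspondence uses the signed EDT of mask t
sampled along the traced (subpixel) boundary of mask t+1. EDT distances are
measured between pixel centers, so a half-pixel is subtracted to refer
distances to the mask *interface* (the 0.5-level the contour tracer uses);
without this every extension is biased a half pixel outward. The largest
extension is the longest circular run of strictly positive boundary speeds,
reported as the **maximum** speed within that run: the protrusion's lateral
walls contribute near-zero values that would bias a run mean low, and the
maximum recovers the programmed radial growth of the sector generator
within 10% (asserted). The mean over all positive boundary points is
reported separately as the all-extension speed. The extension direction
points from the nucleus to the centroid of the largest connected component
of mask t+1 minus mask t.

**Shape.** Volume is voxel count × voxel volume. Surface area comes from
marching cubes at level 0.5 after a Gaussian smooth of σ = 0.8 voxel: the
raw voxel (or lightly smoothed) iso-surface overestimates area — σ = 0.5
still leaves a 4.5% area excess on a 20-voxel-radius sphere (sphericity
0.958) — while σ = 0.8 reduces the error to ~0.4% (sphericity 0.996)
without eroding features larger than a few voxels. Sphericity is
π^{1/3}(6V)^{2/3}/A.

## Synthetic data (`synthetic`)

What each generator emulates, and its defaults:

- **Speckle movies** — lamellar actin speckle advected by uniform, solid-
  rotation or linear radial-sink flow. Gaussian blobs (σ = 1 px) at
  Poisson-random positions (density 0.05), advected by a semi-Lagrangian
  backward warp with bilinear resampling and a reflective boundary (chosen
  to avoid spurious edge sinks in divergence tests); i.i.d. Gaussian noise
  is added to emitted frames, not to the advected latent, so noise does not
  accumulate into texture. Parameterizations whose displacement exceeds a
  stated search radius are rejected.
- **Two-channel cells** — a uniform reference channel inside a disk cell
  and a numerator equal to reference × a radial ratio profile, by default a
  Gaussian cortical ring (amplitude 2 at the body edge, σ = ring width/2)
  with an optional linear lamellar gradient. Defaults (5 µm body, 12 µm
  cell, 2 µm ring, 0.1 µm/px) match hemocyte scale at high-resolution
  imaging.
- **FRAP traces** — 5 pre-bleach + 45 post-bleach frames every 0.5 s; the
  bleach ROI recovers as floor + A(1 − e^(−kt)) and both bleach and control
  ROIs decay as e^(−β·t_acq) from the first *acquired* frame (acquisition
  light bleaches from the first exposure, including pre-bleach frames —
  which is why the control-ROI correction cancels the decay up to a
  constant).
- **Tracks** — straight motion, a fixed-step persistent random walk whose
  heading diffuses with rotational diffusion D_r (θ increments
  √(2 D_r Δt)·N(0,1)), and head-on collision pairs with configurable
  post-collision reversal; the collision annotation is emitted by the
  generator, mirroring manual marking of collisions on real movies, not
  detected. Default speed 3 µm/min and Δt = 10 s are typical hemocyte
  values.
- **Mask sequences** — a disk growing radially inside angular sectors at a
  programmed µm/frame, for edge-dynamics ground truth.
- **Ellipsoid masks** — voxelized ellipsoids with closed-form volume and
  Thomsen-approximate surface area (exact for spheres).

All generators are bit-reproducible under a fixed seed.

**What passing these tests shows — and does not.** The generators validate
the *measurement code*: units, geometry, estimator definitions, and
recovery of known parameters. They deliberately omit point-spread blur,
shot noise, uneven illumination, segmentation error, focus drift and
z-motion. Accuracy on real movies therefore also depends on acquisition
quality and mask quality, which these tests say nothing about; the additive-
Gaussian noise results bound performance only in the idealized regime.

## Problem sizes

Test and example workloads are sized for interactive runs: 64×64 px
speckle movies (16×16 for the exhaustive-search cross-check), ~240 px
synthetic cells, 50-seed FRAP ensembles, 100-seed track ensembles, and
40-voxel-diameter 3D masks. All quantitative tolerances above were chosen
with these sizes; larger inputs only improve the statistics.
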