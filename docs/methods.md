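# Methods

## Overview

`gimotion` quantifies gastrointestinal motility in free-breathing 2D+t
cine MRI of the abdomen. One acquisition ("motility scan", MS) covers a
set of coronal planes, each imaged as a short cine series (40 frames at
0.656 s in the protocol the defaults follow); scans are repeated at 0,
30 and 60 min after a liquid meal (MS1–MS3). The analysis runs in four
stages:

1. **Stabilization** — whole-field respiratory translation between
   successive frames is estimated and removed.
2. **Contouring** — sparse manual outlines of the gastric fundus
   (20 points) or duodenal wall (30 points) are resampled into 100-point
   equidistant closed contours.
3. **Indices** — per-structure motility indices and the gastric
   residual-volume index are computed from the contour series.
4. **Study statistics** — paired t-tests contrast two conditions across
   subjects.

All geometry is computed in physical millimetres (mm = pixel index ×
spacing), so anisotropic pixel spacing is handled uniformly. Contours
are simple closed polygons normalized to counterclockwise orientation
(positive shoelace area), which fixes the sign conventions below.

## Respiratory stabilization

Between frames n and n+1 the translation `b_n` minimizes the mean sum of
squared intensity differences over a region of interest χ:

    E(n, n+1; b) = (1/|χ|) Σ_{x∈χ} [I_n(x) − I_{n+1}(x + b)]²

The model is a pure integer-pixel translation: respiration moves the
whole field, predominantly cranio-caudally, and no rotation, scaling or
non-rigid deformation is estimated. The minimizer is found by exhaustive
search over the (2r+1)² integer candidates in [−r, r]² (default r = 10
px), which at cine-MRI scale costs a few seconds per stack and is
exactly testable against a brute-force oracle. Among equal-energy minima
the smallest-magnitude shift wins, then the lexicographically smallest
(row, col) — a deterministic rule that favours the null under
degeneracy (a constant ROI in both frames returns (0, 0) with a
degeneracy flag). Pairwise shifts are chained into cumulative shifts so
every frame is translated back onto frame 0; there is no global
re-registration to a template. Pixels vacated by the translation are
filled with the frame's border-median intensity and flagged in a
validity mask (the filling policy only affects display; all indices are
computed from contours, not intensities).

Whether sub-pixel shifts or a different energy would improve the
original workflow cannot be settled here; integer SSD search is the
declared implementation, and the noise-robustness test (5% additive
Gaussian noise, ≥95% of estimates within 1 px) bounds its practical
error.

## Wall contouring

A chord-length-parameterized periodic C2 cubic spline interpolates the
seed points; its arc length is evaluated on a 20×-dense polyline and the
curve is sampled at n = 100 equal arc intervals. Orientation is
normalized to counterclockwise and the contour starts at the spline
point nearest the first seed. Resampling is idempotent to well below
0.1% Hausdorff distance, and a 20-seed circle is reproduced with radius
error under 0.005%.

Interpolating cubics overshoot at sharp corners: for a square outlined
by corner and edge-midpoint seeds the resampled perimeter is ~1.75% above
truth. This is the best achievable among standard interpolating families
(local Catmull-Rom variants and higher-order B-spline interpolation are
all worse on that case) and is irrelevant for smooth anatomy; it is
documented as the worst-case bound in the test suite.

Point correspondence across frames: each frame is resampled
independently, then the start index of frame t is rotated to minimize
the sum of squared distances to frame t−1's points over all cyclic
shifts. This is the minimal rule that treats P(k) as the same material
wall point across frames; it is exact for rigid motion and a good
approximation for the slow wall deformations of interest. Whether the
original workflow outlined every frame or propagated one outline is not
determinable; this implementation requires per-frame seeds (the phantom
supplies them).

The centroid is the **area** centroid of the polygon (first moment of
the enclosed region), not the vertex mean — "centre of gravity of the
area" — and the enclosed area is the absolute shoelace area.

## Motility indices

With A(t) the enclosed area, G(t) the area centroid and P_t(k) the
corresponded wall points:

* **DM(A)** = 100 · SD(A) / mean(A), with the sample (n−1) SD — percent
  area variability, scale-free. The same normalization applies to fundus
  and duodenum.
* **DM(G)** = Σ_t ‖G(t+1) − G(t)‖ — 2D Euclidean path length of the
  centroid, in mm. The source of this index family plots only the Y
  component; the Y trace DG_Y(t) = G_y(t) − G_y(0) is exposed separately
  for figure parity, and the 2D path length is the declared definition
  of the summary (the original norm is not stated).
* **V_N, V_T** — for each frame pair (n−1, n) and point k, the
  displacement divided by Δt is projected onto the unit inward normal
  and unit counterclockwise tangent of the *later* frame's contour at k.
  Inward and counterclockwise motion are positive. Because the local
  frame is orthonormal the decomposition is exact:
  V_N² + V_T² = ‖ΔP/Δt‖² to rounding error.
* **DM(V_N), DM(V_T)** = mean of |V_N| resp. |V_T| over all pairs and
  points, in mm/s. Absolute values prevent simultaneous extension and
  contraction from cancelling. The mean (rather than the sum) keeps the
  index sample-size independent and on the printed mm/s scale; this
  aggregation choice is flagged because verbal descriptions of the index
  admit either reading.
* **Gastric residual volume index** — per scan, the sum over the
  designated planes (default P1–P4) of the frame-mean fundus area,
  expressed as a percentage of MS1 (exactly 100 at MS1). Because only
  the ratio is used, slice thickness and spacing never enter.

A caveat on DM(V_T): equal-arc resampling re-parameterizes each frame,
so purely radial wall motion still produces some apparent tangential
point sliding. DM(V_N) is robust (the normal displacement of a curve is
parameterization-independent to first order); measured DM(V_T) carries
an upward bias under radial deformation and should be read as an upper
bound.

Condition contrasts use the classical two-sided paired t-test on
per-subject differences, unadjusted for multiple comparisons (the output
table notes this). All-zero differences return p = 1 with a degeneracy
flag; constant non-zero differences return p = 0 with t = ±∞.

## Digital phantoms

The generators emulate the study's scenes so that every stage has an
analytic oracle:

* **Fundus** — a bright ellipse whose area follows
  `baseline · (1 − emptying) · (1 + a·sin(2πt/T))`. The oscillation
  (default a = 5%, T = 20 s) models the slow gastric pacemaker rhythm;
  emptying is constant within a scan and acts between scans
  (MS1 → MS2 → MS3 at 0 / ½ / 1 of the MS3 fraction), mirroring the two
  time scales of the protocol. Ground-truth area is analytic
  (π·a·b·scale).
* **Duodenum** — a tube of radius R = 10 mm along a C-shaped arc
  centerline (≈200°, arc radius 32 mm), with radius field
  `r(s,t) = R(1 − d·w(s)·exp(−(s − c(t))²/2σ²))`: a Gaussian contraction
  ring of depth fraction d (default 0.5) and width σ = 8 mm travelling
  at 8 mm/s, re-entering every 13 s. A smoothstep envelope w(s) vanishes
  at both tube ends so the end caps are static. Wall motion is purely
  radial in the centerline frame, so ground-truth V_T ≡ 0 and
  inward-positive V_N = −Δr/Δt; the ground-truth DM(V_N) is the
  arc-length-weighted boundary mean of |V_N|. The ring width is chosen
  resolvable by 30 seed points (seed spacing ≈ 9 mm along the ≈260 mm
  boundary), a prerequisite for any contour-based analysis.
* **Respiration** — a cranio-caudal sinusoid (default amplitude 4 px,
  period 4 s) rounded to integer pixels and applied to the geometry
  before rendering, so a noise-free phantom is exactly recoverable by
  integer registration. The injected shift per frame is recorded.
* **Rendering** — 4×-supersampled even-odd scanline occupancy averaged
  down to gray levels (soft, partial-volume-like edges), then additive
  Gaussian noise (default σ = 5% of the dynamic range), clipped at 0.
* **Seeds** — exact ground-truth boundary points (20 fundus / 30
  duodenum) in the frame-0-aligned geometry, matching a workflow in
  which outlining follows stabilization. `seeds_in_raw_frame` maps them
  onto the raw respiring frames for experiments without stabilization.

What the phantoms do **not** emulate: MR physics (no k-space, coil or
sequence modelling), intensity inhomogeneity, through-plane motion,
outline placement error (seeds are exact boundary points), non-integer
or non-translational respiration, and luminal content heterogeneity.
Passing tests therefore demonstrate correctness of the geometry,
registration and statistics under the stated motion models — not
robustness to segmentation error or to MR artefacts.

## Synthetic study model

Per subject, the reference-condition MS3 emptying fraction is drawn from
N(0.16, 0.131) and the second condition adds a within-subject effect
N(0.11, σ_eff); contraction depth is drawn analogously
(N(0.15, 0.10) plus effect N(0.35, σ_eff)). σ_eff = √(σ_b² − σ_a²) is
the value implied by the additive paired model when both marginal SDs
are as specified (floored at 20% of σ_b so it vanishes with it); for the
residual this gives σ_eff ≈ 6.5 percentage points and hence the
between-subject correlation a paired design exploits. The defaults put
the MS3 residual at 84% vs 73% with marginal SDs ≈ 13 and 15 percentage
points — the scale of the motivating study. Subject size variation
(±8% SD) scales the fundus ellipse; plane factors (1.0, 0.9, 0.75, 0.55)
differentiate the four meal-containing planes. All randomness flows from
one master seed through a `SeedSequence`; regeneration is
bit-reproducible.

Study-level power and size are evaluated on the generator's true
per-subject residuals (50 replicate draws): the pipeline's measured
residual tracks the prescribed value to well under 1% (the rendered
emptying check bounds the contour/raster error at 2%), so the operating
characteristics of the paired test are determined by the parameter
draws, and evaluating them there keeps 50 replicates affordable.

## Problem sizes and tolerances

Defaults follow the acquisition protocol: 40 frames at 0.656 s,
192 × 288 px at 1.7 mm, 4 fundus planes, n = 8 subjects, two conditions,
three scans. The test suite uses these defaults for the phantom-based
checks and smaller grids (96 × 144, 6–10 frames, 2 planes) for the
end-to-end orchestration tests. The acceptance script renders one full
default study (240 stacks) and 50 parameter-level replicate studies.
Key tolerances: registration equals the exhaustive oracle exactly;
circle resampling radius < 0.5%; velocity decomposition conserves speed
to 1e-9 relative; phantom DM(V_N) recovery within 10% (measured ≈ 1–3%);
rendered emptying within 2 percentage points.

## Known limitations

* Integer-pixel translation only; sub-pixel respiration leaves ≤ 0.5 px
  residual by construction.
* Per-frame manual seeds are required; no automatic wall segmentation.
* DM(V_T) is upward-biased under radial deformation (see above).
* The responder/subset analysis is explicit user input; the package
  never selects subsets from the observed effect direction, since that
  would embed a circular rule.
* Indices quantify the magnitude of wall motion, not its quality
  (mixing, antegrade vs retrograde transport).
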