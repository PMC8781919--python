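# Methods

This note documents the models, conventions and parameter choices behind
`cbreco`, in the order the pipeline applies them.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Geometry and conventions

The scan model is a circular cone-beam trajectory: point source, flat
detector, object rotating about a vertical axis.  Conventions (all code and
the synthetic generator share them; self-consistency is what the tests
assert, since the opposite handedness would merely mirror the volume):

* Right-handed volume frame, rotation axis = +z.  A projection at angle φ
  corresponds to the object rotated counter-clockwise by φ viewed from +z.
* In the rotated frame the source sits on +y at distance `scd` from the
  rotation centre; the detector plane is `y = scd − sdd`, columns along +x,
  rows along +z.
* Detector pixel centres at integer 0-based indices; the central ray hits
  column `(n_u−1)/2 + axis_offset_px`, row `(n_v−1)/2`.  A rotation-axis
  offset is therefore a pure horizontal shift of the detector origin — the
  same shift enters the cosine weights and the backprojection sampling.
* `d` = signed distance of a rotated voxel from the plane through the
  rotation centre parallel to the detector, positive toward the source;
  the FDK distance weight is `scd²/(scd−d)²`, exactly 1 at the centre
  plane.
* Voxels are isotropic with pitch `pixel_size·scd/sdd` — the detector
  pitch demagnified to the rotation-centre plane, i.e. the Nyquist-matched
  choice.  A full scan covers [0, 2π).

## Normalization and fluence correction

Raw counts are corrected as `I = (raw − dark)/(flat − dark) · C_fl`, with
the up-scaling constant `C_fl` either the mean open-beam level
`mean(flat − dark)` or, when a fluence monitor is available, the
per-projection reading minus the mean dark level.  Three modes then make
gray values comparable across projections:

* `none` — projections already fluence corrected upstream;
* `roi_fluence` — divide each projection by the mean of a user-chosen
  background ROI (removes per-projection source jitter exactly when the
  ROI stays object-free);
* `flat_mean` — divide by the mean open-beam level (when no free
  background exists).

Isolated detector pixels where `flat ≤ dark` are given the mean
denominator (and are the natural prey of the defect mask); a flat field
that is unusable everywhere is an error.  The normalized output is floored
at a tiny positive value, and the log transform `p = −ln(max(I, 1e−6))`
clamps transmission at 1e−6 (≈ 13.8 attenuation) — zero or negative
transmission is physically meaningless and otherwise produced infinities.

## Beam hardening

Polychromatic beams harden with depth, so attenuation grows sublinearly
with path length and homogeneous objects reconstruct darker in the centre
(cupping).  The correction is the empirical polynomial
`f(x) = a·x + b·x^c` applied to post-log attenuation values; `c` is the
sensitive parameter and is kept in [2, 3].  `calibrate_bhc` fits `(a, b)`
by linear least squares for each candidate `c` on a grid, given matching
samples of measured and target (linear) attenuation — usable with a
calibration wedge or a known beam model.  The synthetic two-energy beam
(`transmission = w₁e^{−k₁p} + w₂e^{−k₂p}`) provides exactly such a model;
its default in the cupping study (w = 0.7/0.3, k = 0.3/3.0) is chosen as a
strongly polychromatic spectrum that produces a clearly measurable cupping
gap at sub-unit path attenuations.

## Ring-artifact correction

Two mechanisms, applied to normalized (pre-log) projections, in the order
defect repair first, gain equalization second:

**Defect pixels (MF).**  Defects stay on fixed detector coordinates while
object structure moves from projection to projection, so the pixel-wise
stack mean suppresses structure but keeps defects.  The mean image is
median-blurred (default 5×5), the absolute difference z-scored, and pixels
above `n·σ` (default n = 3) flagged.  Masked pixels are replaced per
projection by the median of unmasked neighbours in a window that grows
until a valid neighbour exists.  Note the z-score is relative: on a
defect-free stack the top tail of the difference distribution (object
silhouette edges) can still be flagged and smoothed — harmless, but the
reason the repair is optional per run.

**Detector gain (DLR/SCM).**  For each horizontally adjacent pixel pair
the gain ratio is estimated as the median over projections of the value
ratio; per row, the cumulative product of ratios yields a gain profile,
which is high-pass detrended by dividing out a wide moving median and
normalized to mean 1.  Choices that matter:

* Ratios run along rows (columns relative to neighbours) because ring
  artifacts are fixed detector *columns* mis-scaled relative to their
  neighbours.
* The detrend uses a moving *median* (window `n_u/16`, odd, ≥ 5) rather
  than a moving average: isolated gain spikes must not be pulled into the
  trend they are measured against, while genuine smooth flat-field trends
  still are.  The window is kept narrow because the cumulative product
  also carries the median *static* structure profile of the object —
  anything that never moves (e.g. a perfectly centred feature) survives
  the per-pair median and must be tracked by the trend, which a narrow
  window does better near steep silhouettes.
* Pixel pairs with near-zero denominators are excluded; pairs with under
  10% usable projections fall back to ratio 1.
* The method assumes structure that moves across projections; a purely
  static (rotationally symmetric, centred) scene degrades the estimate
  near its silhouette.  The validation studies therefore use off-centre
  structures, which is also the realistic case.

The ring severity metric used in validation samples the reconstructed
slice along circles centred on the rotation axis and averages the
per-circle standard deviation over a radial band.  Genuine off-axis
structure also raises it, so the studies evaluate a band outside the
phantom that the injected rings are drawn into by construction.

## Weighting, filtering

Cosine weights `SDD/√(Xp²+Yp²+SDD²)` are applied before filtering.  The
ramp filter is realized as a discrete spatial-domain kernel — sampling the
band-limited ramp, not `|ω|` — which avoids the DC-offset error of
frequency-domain sampling; the Ram-Lak tap sum telescopes to zero as the
support grows (`Σ_odd n⁻² = π²/8`).  Convolution is evaluated through the
FFT with zero-padding to at least `N_f + N_p − 1` (next fast length), so
it is exactly linear (acyclic) convolution; the default kernel half-length
equals the row length, making the support cover the whole row.

The kernel's sampling interval is the detector pitch demagnified to the
rotation-centre plane (`pixel_size·scd/sdd`, = the voxel size).  Filtering
at the native detector pitch instead would only rescale all reconstructed
values by `scd/sdd`; the demagnified convention is chosen so voxel values
come out in absolute attenuation per mm.

## Backprojection, normalization constant, chunking

Voxel-driven: each voxel is projected to the detector per angle
(`Xp = x⊥·sdd/(scd−d)`, `Yp = z·sdd/(scd−d)`), sampled with full-precision
bilinear interpolation (coordinates outside the detector contribute zero),
and accumulated with weight `scd²/(scd−d)²`.  The accumulated sum is
multiplied by `π/n_proj · Δs`: the angular step of the FDK integral over a
full scan (each ray direction is measured twice over 2π, hence π rather
than 2π) times the Riemann factor of the discrete ramp convolution.  With
this constant a synthetic phantom's attenuation is recovered on an
absolute scale (measured by the fidelity study, not asserted a priori).

Axis tilt is applied as a per-slice horizontal sampling shift
`a + m·iz`, with `iz` the slice index on the canonical grid
(`n_z = n_v`); internally the shift is computed from the slice's z
coordinate in mm, so sub-volumes and single-slice reconstructions remain
consistent with full ones.

Chunking: the volume is partitioned into z-slabs and the projection stack
into batches, greedily maximal under a byte budget that must hold one slab
plus one batch (float32 elements); slabs are maximized first.  Because
each voxel's angle sum is split sequentially across batches and voxels are
independent, the chunked result is bitwise identical to the unchunked one
(accumulation in float64) — this invariance is the contract that makes
arbitrary-size reconstruction safe, and it is asserted rather than
assumed.

## Geometry calibration

**Axis offset (autofocus).**  A mis-centred axis doubles/blurs edges.  One
slice — near-central, where cone-beam artifacts vanish — is reconstructed
for each candidate offset on a coarse grid (the weighting is re-evaluated
per candidate since the offset shifts `Xp`); each reconstruction is scored
by: crop the central `L×L` window (`L = m·w/2`, margin factor m = 0.8
default), bilateral-denoise (spatial σ = 3 px, range σ = 10% of the
window's dynamic range — defaults chosen as conventional denoising
settings), Sobel gradient, sum of squares.  The argmax wins, ties broken
toward the smaller |offset|; a parabola through the best triplet refines
below the grid step, clamped to ±1 step.  A maximum on the search boundary
returns the boundary value with a warning (range too narrow).  The score
scales quadratically with a global intensity factor, so the estimate is
scale-free.  Featureless slices defeat any autofocus; the caller must pick
a slice with structure.

**Axis tilt.**  When the offset varies linearly with slice height, offsets
estimated at several heights are fitted with ordinary least squares
(design matrix `[1, z]`); the intercept/slope feed the per-slice
correction above.  The fit is checked against the closed-form
normal-equation solution in the tests.

## Synthetic generator: what it emulates, what it does not

Line integrals through ellipsoids have a closed form (quadratic
ray-intersection chord lengths), so forward projections are exact and
additive over the ellipsoid list (overlaps sum their attenuation deltas).
Artifact injectors: per-pixel gain *relative to the flat field* (detector
sensitivity drift between reference and scan — deliberately not included
in the flat, since drift captured by the flat would be removed by
normalization and leave nothing for DLR to correct), stuck pixels constant
across projections, per-projection fluence factors, the two-energy beam,
and axis offset/tilt injected by shifting the detector frame (tilt as a
per-row shift, which maps 1:1 to a per-slice shift at the centre plane
under the Nyquist-matched voxel size).

Not emulated: photon (Poisson) noise, detector blur/afterglow, scatter,
continuous full-spectrum beams, mechanical wobble beyond the linear tilt.
Passing tests therefore demonstrate algorithmic correctness and artifact
recovery under ideal counting statistics, not robustness to noise — on
real data the autofocus and DLR estimates carry statistical error that
these studies do not measure.

## Study problem sizes

The validation studies use a 2× magnification geometry (scd 100 mm,
sdd 200 mm, 0.4 mm pitch, 0.2 mm voxels): phantom fidelity 128² × 180
projections into 64³; chunk invariance 64² × 45 into 32³ (4 slabs × 3
batches); offset recovery 96² × 120 over a [−20, 20] px sweep; tilt
recovery 128² × 90 at five slice heights; ring and cupping studies
96² × 120 on single slices.  These sizes put FDK discretization error far
below the tolerances of interest while the full set runs in well under a
minute on one CPU.

## Known limitations

* Full-scan FDK only: no short-scan (Parker) weighting, no helical or
  offset-detector trajectories, no iterative solvers.
* Cone-beam artifacts at large cone angles are inherent to FDK and are not
  corrected; calibration slices should be near-central.
* The DLR estimate degrades for rotationally symmetric, centred objects
  (static structure) — see above.
* Detector slant/skew is not modelled; the tilt correction is the linear
  offset-vs-height term only.
* CPU implementation, vectorized per slab and batch; the chunking contract
  is the portable part of a streamed/accelerator realization.
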