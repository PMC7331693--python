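# Methods

`xvlung` quantifies regional lung function from time-resolved 3D lung images
in the manner of X-ray velocimetry (XV): tissue motion is estimated between
breath phases by windowed cross-correlation, converted into a per-region
fractional-expansion map at peak inspiration, and that map's distribution is
summarised into two disease scores. This note records the models, the
numerical choices, and what the built-in phantom does and does not emulate.

## The analysis chain

### Displacement estimation (velocimetry)

Consecutive breath-phase volumes are tiled into cubic interrogation windows
(default 64³ voxels, 50% overlap, hence one vector per 32³ region — the
standard XV geometry; desk-scale runs use proportionally smaller windows).
Each window pair is cross-correlated spectrally after mean subtraction, with
zero padding to twice the window so no circular wrap contaminates the peak,
and the correlation plane is normalised by the overlap voxel count so large
shifts are not biased towards zero. Estimation is two-pass: the integer peak
is located first, the second window is re-cropped at that integer offset, and
the residual peak is refined per axis by three-point Gaussian interpolation
(parabolic fallback when a neighbour is non-positive). This makes integer
shifts exact and keeps sub-voxel errors below ~0.01 voxel on well-seeded
speckle. Ties at the integer peak break toward zero displacement; vector
magnitudes are bounded by half the window.

Vector validation uses the conventional peak-ratio detectability: the ratio
of the tallest correlation peak to the tallest value outside its
neighbourhood, computed on the *unnormalised* plane (normalisation inflates
noise at small-overlap shifts and mimics a competing peak). The exclusion
neighbourhood (radius 3) must cover the correlation-peak width set by the
speckle grain. Vectors with ratio < 1.2 are replaced by the component-wise
median of trusted 3×3×3 neighbours, iterating inward for clusters. Vectors
are computed for *every* window; windows with < 50% lung-mask coverage are
flagged invalid for masked statistics but retained, because the global-volume
estimator interpolates the field just outside the lung boundary.

Displacements are accumulated across phases by summation on the fixed XV
grid. This Eulerian accumulation assumes per-frame displacements are small
relative to the window; no Lagrangian tracking is attempted, a known
limitation shared with the baseline formulation.

### Fractional expansion

The expansion of an XV region is (change in ROI volume)/(ROI volume), a
unitless quantity. With `u` the displacement accumulated from breath start to
peak inspiration, the map stores `det(I + ∇u) − 1` per XV voxel, with
gradients by central differences on the XV grid (`numpy.gradient`, one-sided
at edges). Before differentiation, in-mask vectors are extended outward by
nearest neighbour so border derivatives use lung values only — the discrete
analogue of one-sided differences at the mask edge. The determinant form is
exact for affine fields: a uniform dilation `u = αx` yields `(1+α)³ − 1`
everywhere. Peak inspiration is the phase of maximum global fractional
volume, ties to the earlier phase. A main-stem-bronchi (or any other)
exclusion region can be subtracted from the mask; all downstream statistics
ignore it.

Caveat: at XV voxels only partially covered by lung, the reported expansion
mixes lung and non-lung motion; there is no single "true" value for such a
voxel. Fidelity statements in the tests are therefore made at fully covered
voxels, and expansion variation on scales below the XV stride is aliased —
the phantom's expansion-noise kernel must span roughly two or more XV voxels
for the map to track the truth (r > 0.95 measured end-to-end under those
conditions).

### Histogram, double-Gaussian decomposition, HD and CD

In-mask expansion values are histogrammed with unit area (default 50 bins
across the value range); the interquartile range is computed from the raw
values with linear quantile interpolation, so it is independent of binning.
A two-component Gaussian curve `a₁G(μ₁,σ₁) + a₂G(μ₂,σ₂)` is fitted to the
density over bin centres by bounded least squares (`scipy.optimize.curve_fit`)
— a basis-function regression, not a distributional assumption. Multi-start
initialisation: (i) single-mode moments duplicated at ±1 SD, (ii) a
single-mode-plus-shoulder start, (iii) the two tallest local maxima of a
smoothed density; the best residual wins. Amplitudes are constrained
non-negative and spreads bounded below by half a bin width; parameters are
reported canonically with μ₁ ≤ μ₂, and R² = 1 − SS_res/SS_tot measures the
fit. The fit is exposed statsmodels-style (`DoubleGaussianModel.fit()`
returning a results object with parameters, large-sample standard errors
from the least-squares covariance, and `summary()`), because it is the one
genuine model-fitting step of the chain; the surrounding stages are image
operations and keep a pipeline shape.

Two scores summarise the histogram:

* **HD = IQR / IQR_L**, the animal's IQR over the arithmetic mean littermate
  IQR (a median option exists). Littermates average exactly 1 by
  construction; HD is invariant to rescaling all expansion values.
* **CD = (μ₂ − μ₁)/μ₂** from the canonical modes, in [0, 1) for positive
  modes and increasing as the low mode separates. When the minor component
  is negligible — amplitude ratio < 1% or component weight < 2% of the
  fitted area — the histogram is declared unimodal and CD is 0. The
  negligibility rule is this package's choice; no published rule exists for
  the collapsed-fit case.

Note that even genuinely unimodal histograms can support a two-bump
decomposition with ~20% mode separation; healthy-cohort CD values of
0.1–0.25 are therefore normal background, and CD is meaningful as a
*relative* score against the healthy population (the tests verify the rank
separation, not an absolute zero). Animals flagged for heart blur receive no
CD; their HD is reported but flagged.

### Global volume/time curve and expiratory time constant

The inspired air volume per phase, as a fraction of the mask-derived total
lung volume (voxel count × voxel volume), is computed from the accumulated
displacement field by one of two signed estimators:

* **regional** — Σ (expansion × XV-voxel volume) over the XV mask; exact
  when the lung tiles whole XV voxels, lossy at coarse grids where boundary
  flux smears across partially covered windows;
* **flux** (primary whenever the fine segmentation mask is available) — by
  the divergence theorem the same integral equals the outward displacement
  flux through the lung surface; the field is interpolated (cubic) onto the
  boundary faces of the fine mask dilated by 4 voxels — the displacement
  kinks exactly at the lung surface, a few voxels out it is smooth and the
  bordering tissue is incompressible so the net flux is unchanged — plus a
  small volumetric correction for the nonlinear `det−1 − div` difference.
  On ground-truth fields this recovers the configured tidal fraction within
  ~1%; through measured fields the boundary windows' texture-weighted
  averaging still biases the level by O(10%) at desk scale, so measured
  fractional tidal volumes are comparative rather than absolute.

The literal magnitude-sum index (Σ|u|, normalised the same way) is computed
alongside for comparison but is not dimensionally a volume.

The expiratory time constant τ is the time from peak inspiration until the
expired fraction first reaches 67% of tidal volume (the conventional ~1−1/√2
threshold; the printed 0.67 is the default and 1/√2-based values can be
passed), located by linear interpolation between bracketing phases. τ depends
only on volume fractions, hence is invariant to rescaling the volume axis. If
the threshold is never reached within the breath, τ is censored at the
expiration duration and flagged.

### Orientation, segmentation and QC

*Mirror-symmetry orientation.* The cranial/caudal maximum-intensity
projection is thresholded to bone: the intensity quantile (default 0.99)
selects bone seeds, the actual cut is the midpoint between seed and
background median intensities (a raw top-quantile cut through a noisy bone
plateau keeps an arbitrary speckle subset), and closing/opening consolidates
the blobs. The binary is centred on its centroid, smoothed once (so rotated
candidates are not compared against a crisper unrotated image), and each
candidate angle (−90°..90°, 0.5° steps) is scored by the best Pearson
correlation between the rotated image and its reflection over vertical axes
within a small offset range of the centre column, restricted to the
inscribed disc (rotation corners otherwise fake symmetry). The spine is the
larger on-axis bone blob; correction rotates the symmetry line vertical with
the spine at the bottom (an exact 180° flip when needed) and crops to the
padded bone bounding box. Recovery is within 1° over random rotations and
idempotent. The unreliability floor (score 0.75) sits between the null
distribution measured on structureless volumes (max ≈ 0.66 over seeds) and
the ≥ 0.9 scores of symmetric anatomy.

*Lung segmentation.* Air-filled lungs are darker than soft tissue: Otsu
separates exterior air from the body, holes are filled, a second Otsu inside
the body separates lung from tissue, 3D opening/closing removes speckle, and
components must occupy a contiguous z-range with slice-to-slice overlap
(continuity check). The two largest surviving components are kept. Dice
≥ 0.95 on noise-free phantoms, degrading gracefully under 5% additive noise.

*Heart blur.* Cardiac motion locally defeats the velocimetry, leaving
contiguous near-zero-displacement regions, typically lower-left. In-mask
vectors of the accumulated peak field with magnitude < 0.05 voxels are
marked; the sample is flagged when the largest contiguous marked region
exceeds 5% of the mask, and the region centroid is reported so the expected
locality can be checked. Both thresholds are declared defaults of this
package (no published rule exists) and are exposed in configuration.
Flagged animals keep HD (flagged) and lose CD.

## The synthetic breathing-lung phantom

No imaging data ships with the package; the phantom provides seeded inputs
with known truth. One animal comprises:

* a two-lobed ellipsoidal lung mask (per-seed jitter of a few percent,
  always two separated components) inside a soft-tissue body ellipsoid with
  darker exterior;
* a per-voxel fractional-expansion scene: spatially correlated Gaussian
  noise (white noise smoothed with a configurable kernel, default 6 fine
  voxels, re-centred so sub-population means are exact) around `mu_main`
  with a profile-dependent spread — `healthy` narrow (σ = 0.010),
  `heterogeneous` wide (σ = 0.022), `clustered` additionally painting
  contiguous low-mode blobs (`mu_low` = 0.04, σ = 0.008, 30% of the mask)
  grown from random seeds by dilation with the final shell trimmed to the
  target fraction. The paper-scale expansion magnitudes of real mice are not
  published; `mu_main` = 0.10 is a plausible regional tidal expansion for a
  ventilated mouse and is the package's declared default. An optional heart
  blur region (a mask-fraction-sized contiguous region in the lower-left
  lung) is forced to exactly zero expansion and zero displacement;
* a breath curve: fractional volume rising linearly from 0 to the tidal
  fraction over a 0.15 s inspiration (peak snapped to the nearest sampled
  phase), then decaying linearly or exponentially (default rate expires 95%
  over the 0.35 s expiration) across 15 phases of the 0.5 s cycle;
* displacement fields synthesised as the gradient of a potential whose
  spectral inverse-Laplacian solution is iterated (4 Newton-style
  corrections) until `det(I + ∇u) − 1` matches the scene inside the mask to
  ~1e−6 RMS; the volume-conserving counter-contraction of the periodic
  domain is placed at least 8 voxels away from the lung, so the shell just
  outside the lung is divergence-free like real bordering tissue. The scene
  is rescaled so its in-mask mean equals the configured tidal fraction (the
  global fractional volume *is* the mask mean of regional expansion, so the
  two must agree);
* speckled image frames: band-passed noise texture (default ~4-voxel grain,
  sized for 64³ windows; proportionally finer grain should be used with
  smaller windows) warped by a backward-map recursion constructed so the
  frame-to-frame apparent motion *equals* the stored per-frame truth exactly
  and the truth series sums to the peak field — the texture is interpolated
  once per frame from the reference, so no blur compounds;
* a bilaterally symmetric bone phantom (spine distinctly larger than
  sternum, mirrored rib pairs) rotated by a known in-plane angle, for the
  orientation algorithm.

All randomness flows from one seed through named child streams (mask jitter,
main-mode noise, blob seeds, low-mode noise, texture, per-phase image
noise), so identical configurations are bit-identical.

What the phantom does *not* emulate: X-ray physics (phase contrast,
projections, CT reconstruction — all out of scope), airway trees and lobar
fissures, cardiac-motion image blur as such (heart blur is emulated directly
as static texture / zero displacement), ventilation hysteresis, and
image noise structure of real detectors (only additive Gaussian noise is
available). Passing tests therefore demonstrate the correctness and
sensitivity of the *analysis chain* under known motion, not performance on
real laboratory images.

## Problem sizes and engines

Cohort-level statistics run the `truth` engine: phantom ground-truth fields
sampled on the XV grid are pushed through the expansion → histogram →
scoring → volume-curve chain, so cohort properties (HD/CD discrimination at
n = 5 per group on 96³ grids, the littermate mean-HD identity) are tested at
full cohort scale. The `measured` engine — lung segmentation on the first
frame, full windowed cross-correlation, then the same chain — is validated
separately on single 96³ animals (velocimetry RMS error, expansion-map
fidelity, segmentation Dice), because correlation over all windows of a
cohort is disproportionately expensive at desk scale. Desk-scale runs use
16³ windows (50% overlap) on 64³–96³ grids; the 64³/50% reference geometry
is exercised directly for its grid arithmetic.

## Known limitations

* Eulerian accumulation of per-frame vectors ignores material advection;
  fine for the ~0.1 fractional expansions simulated, increasingly biased for
  larger motions.
* Boundary XV voxels mix lung and body signal; their expansion values widen
  the histogram slightly. Real XV has the same property; scores remain
  comparative against littermates processed identically.
* The double-Gaussian fit cannot represent three or more distinct regions; a
  third mode is absorbed into the two fitted components by design.
* Measured-engine fractional tidal volumes carry an O(10%) level bias at
  desk-scale window-to-lung ratios (texture-weighted window averaging at the
  boundary); ground-truth-field recovery is ~1%.
* No significance testing between groups, no FOT comparison, and no ≥3
  component mixtures are provided.
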