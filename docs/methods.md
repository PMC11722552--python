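# Methods

`nervequant` quantifies neuronal fluorescence microscopy along five axes: (1)
soma/neurite segmentation by structure thickness, (2) organelle puncta detection
and shape descriptors, (3) node-of-Ranvier morphometrics, (4) fiber
directionality, and (5) ratiometric pHluorin2 pH at mitochondria–lysosome
membrane contact sites. Because the imaging data these procedures were designed
for (patient fibroblasts, mouse embryonic motor neurons, sciatic-nerve sections)
are not publicly deposited, every stage is validated against seeded synthetic
scenes with exact ground truth, generated by `nervequant.synth`.

## Soma/neurite segmentation

**Stage 1 — cell delimitation.** The field is contrast-stretched by saturating
the bottom 0.7 quantile of pixel values (linear map of the [q-quantile, max]
range onto [0, 1]; quantiles by linear interpolation of order statistics),
binarized with a global Otsu threshold, cleaned by a morphological area opening
that removes objects below 3.5 µm², and de-holed selectively: holes below
~15 µm² (artifacts of non-homogeneous staining) are refilled, larger holes are
genuine background and kept.

**Stage 2 — thickness map and soma extraction.** Structure thickness is
estimated per pixel by ray tracing: contour normals come from a 3×3 Sobel
operator applied to a Gaussian-smoothed (σ = 2 px) copy of the mask; from each
pixel a ray is stepped at 0.5 px (bilinear mask lookup) in both senses of the
normal until the mask value first drops below 0.5, with a sub-pixel linear
correction at the crossing. The default records the distance to the *nearest*
crossing (half-chord), which on convex shapes agrees with the exact Euclidean
distance transform; a `full`-chord mode is available in the configuration.
Pixels whose normal is undefined (deep interior, where the smoothed mask is
locally flat) fall back to the exact EDT and are flagged. The soma seed is the
thresholded map (default 100 px, i.e. 7 µm at the 0.07 µm pixel size of the
motor-neuron acquisitions), dilated by a disk of radius 5 and area-filtered at
3.5 µm². The seed is then re-expanded into the original foreground: every seed
pixel provably lies at least the threshold distance from the cell contour, so
dilating the seed by that same distance and intersecting with the cell mask
recovers the cell body without invading thin processes; closing and hole
filling finish the mask. This re-expansion is our realization of the
inward-interpolation step of the original recipe — it is monotone in the
threshold (the EDT is 1-Lipschitz), a property the test suite checks.
Neurites are the set difference cell \ soma, so pixel counts are conserved
exactly.

**Operating condition.** The 0.7-quantile anchor assumes cells occupy well
under ~30% of the frame; if they cover more, the anchor lands inside the cell
intensity range and erodes the mask. Real acquisitions (1024² at 0.07 µm/px)
satisfy this easily; the synthetic fields use 640² frames for the same reason.

**Unit conflicts.** Published pixel/micron threshold pairs are mutually
inconsistent at the stated pixel sizes (e.g. 200 px vs 3.5 µm² at 0.07 µm/px).
For the soma stage the micron values are authoritative (they transfer across
magnifications); for the puncta (10 px) and node (100 px) artifact filters the
printed pixel values are used, because the micron alternatives (0.7 µm², 5 µm²)
exceed the size of genuine objects at the stated pixel sizes and would delete
them. Both unit variants are exposed in the configuration, and the run manifest
reports every threshold in both units — in particular the 100 px = 7 µm soma
thickness threshold.

## Puncta detection and shape descriptors

Detection: contrast stretch saturating the bottom 0.85 quantile, then
subtraction of 0.5× a σ = 5 px Gaussian blur of the enhanced image (flattening
residual background), global Otsu, connected components, and removal of objects
below 10 px. Compartment membership is decided by the rounded centroid
(soma / neurite / none).

*Roundness* is 4A/(πL²) with L the major axis of the second-moment-equivalent
ellipse — 1 for a circle, b/a for an ellipse; clipped to (0, 1], single-pixel
regions report 1 by convention. *3D semi-axes* come from the eigenvalues of the
physical-coordinate covariance of a component's voxel centers, corrected for
within-voxel spread (+s²/12 per axis) and converted by the uniform-ellipsoid
relation λ = a²/5, so a voxelized ball of radius 1 µm reports (1, 1, 1).
Components spanning a single z-slice are degenerate: the smallest axis is
pinned at half the z-step and flagged. *Oblate/prolate* ellipticities are
(b−c)/(b+c) and (a−b)/(a+b) on sorted semi-axes a ≥ b ≥ c: 0 for a sphere,
approaching 1 for a disk (oblate) or needle (prolate). *Manders* coefficients
M1/M2 are intensity fractions over caller-supplied masks (no automatic
threshold search). Per-ROI summaries report object count (by centroid), total
object area in µm², and percentage area. Nuclei are counted by smoothing,
Otsu, hole filling, a distance-transform watershed to split touching nuclei,
and a 20 µm² minimum-area filter.

## Node-of-Ranvier morphometrics

The Nav1.6 crop is stretched (bottom 10% saturated), Otsu-binarized, and opened
at 100 px. All fragments in a crop are treated jointly as one node. The
oriented bounding box is aligned with the second-moment principal axis of the
foreground (extents covering all pixel corners); a pure minimum-area rectangle
is used only for near-isotropic shapes, because on pixelated masks its angle
quantizes to convex-hull edge directions and wobbles by 1–2°, which measurably
degrades the mirror-symmetry statistic. Metrics: *length* = box major extent ×
pixel size (0.05 µm for the node acquisitions); *fragments* = 8-connected
component count; *solidity* = area / box area (π/4 for a disk); *symmetry* =
Sørensen–Dice coefficient between the mask and its specular image reflected
across the line through the box center parallel to the major axis (one bilinear
resampling, re-binarized at 0.5). The axis is intrinsic, so the statistic is
rotation-invariant, and it decreases monotonically with the generator's
asymmetry parameter.

## Fiber directionality

Local orientation is the eigen-direction of the structure tensor built from
Gaussian-derivative gradients (σ = 1 px) averaged over a Gaussian window. The
window default is σ = 2 px: feasibility runs showed that a wider window (4 px)
mixes neighboring fibers at realistic densities and shrinks the recovered
orientation spread by ~25%. Angles are axial on (−90°, 90°] with 0° along the
image x-axis. The abundance histogram (1° bins) is weighted by energy ×
coherence; a single wrapped Gaussian (baseline + amplitude) is fitted by
bounded least squares, initialized at the argmax bin with the circular standard
deviation, σ constrained to [bin width, 90°]. Flat histograms yield a
near-zero amplitude and are flagged unreliable rather than reporting a
spurious center.

Recovery is assessed against the same peak statistic computed on the
ground-truth orientation sample: with 100–150 fibers at σ = 20° the realized
circular mean itself wobbles by several degrees, so comparing to the
generating mean would measure sampling noise, not the estimator. Median errors
over eight fields are ~0.2–0.4° (center) and ~2–4% (σ).

## Ratiometric pH at membrane contact sites

The ratio is (I_m,long − I_b,long)/(I_m,short − I_b,short), long = 475 nm and
short = 405 nm excitation; adding a constant to a channel and its background
leaves it invariant. Backgrounds default to the median intensity outside a
3 px dilation of the cell mask (an explicit background ROI overrides this).
Calibration membrane ROIs are 2 × 0.5 µm rectangles oriented along the local
boundary tangent, pairwise disjoint.

The calibration fits pH as a **quartic polynomial in the ratio** over the ten
buffer ladder points (pH 3.5–8.0 in 0.5 steps), by default at ROI level (all
individual ROI measurements, not per-buffer means). Outliers are removed
iteratively by z-scores of **jackknife (leave-one-out) residuals** with cut
|z| > 2.5: a corrupted ratio is a leverage point — the quartic bends through
it, so ordinary residuals stay small while the deleted-point prediction error
explodes. Iteration stops at stability, at 10 rounds, or at the
identifiability floor of 6 points. The curve records retained/rejected points,
RMSE, its valid ratio range, and whether it is monotone there (non-monotone
fits are flagged). Estimates outside the valid range are clamped to the
boundary and flagged extrapolated. Contacts are connected components of
mito_mask ∩ dilate(lyso_mask, 2 px), minimum 4 px — an explicit,
resolution-limited proxy for true (≤ 30 nm) membrane apposition, configurable.

**Probe model.** The synthetic generator uses
R(pH) = R_min + (R_max − R_min)/(1 + 10^(hill·(pKa − pH))) with
(R_min, R_max, pKa, hill) = (0.2, 3.0, 5.75, 0.45): pKa at the ladder midpoint
and a shallow slope whose 10–90% response spans roughly the ladder width, so
the ratio carries pH information across the whole calibrated range and the
quartic inverts it to better than 0.04 pH over [4.0, 7.5]. A steep
single-site probe (pKa 7.1, hill 1) is flat below pH ~5.5, which makes the
acid half of the ladder uninvertible at any polynomial order; `ProbeModel` is
a dataclass, so such alternatives are one constructor call away.

## Synthetic scenes and what they do not show

All generators are pure functions of (parameters, seed): Poisson shot noise on
the expected intensity plus Gaussian read noise, with `snr` defined as peak
expected signal over read-noise σ. Defaults: neuron fields 640² px at
0.07 µm/px, one soma of radius 9.1 µm, neurites 2.1 µm wide, 12 + 5 puncta,
SNR 12; node crops at 0.05 µm/px with a superellipse profile and a
ramp-thinned lower flank implementing asymmetry; fiber fields 640² with 120
anti-aliased fibers (bilinear splatting, so deposited intensity per unit
length is angle-independent — nearest-pixel rendering was found to bias broad
orientation peaks by ~2°); ratiometric scenes with planted contact regions
whose expected channel ratio equals the probe model exactly before noise.

The scenes do not emulate optics-accurate PSFs, spectral bleed-through,
intensity vignetting, out-of-focus haze, or the morphological diversity of real
neurons (curved neurites, touching cells, heterogeneous staining). Passing
recovery tests therefore demonstrates the correctness and internal consistency
of the measurement chain under controlled conditions, not field-ready accuracy
on arbitrary micrographs; on real data the printed thresholds remain the
user's responsibility to validate.

## Numerical choices

Quantiles by linear interpolation of order statistics; Otsu thresholds guarded
against constant images (empty mask, logged, never an exception); area filters
remove components strictly below the floor; ray tracing steps 0.5 px and caps
at twice the maximum EDT; oriented-box extents measured over pixel corners
(±0.5), so solidity never exceeds 1; the degenerate single-pixel region reports
roundness 1; empty inputs yield empty outputs with log messages wherever an
empty result is scientifically meaningful (blank field, all-neurite cell).
Problem sizes in the validation runs — 20 convex shapes, 20 neuron fields,
8 fiber fields, 100 calibration replicates, 32 contacts — were chosen so each
statistic's Monte-Carlo error is small against its tolerance.
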