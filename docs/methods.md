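# Methods

This note documents the models, estimators and numerical choices behind
each module, what the synthetic generators do and do not emulate, and the
known limitations.

## Vessel phantoms and ground truth

A phantom is a union of tubes around cubic-spline centerlines sampled at
≤0.5-voxel steps; a voxel belongs to the mask iff its center lies within
the branch radius of the sampled centerline. This rasterization rule makes
the discrete tube volume exactly enumerable, so mask voxel counts can be
asserted against a brute-force oracle. Ground truth stores the sampled
centerline, arc and chord length (voxel and µm, with per-axis anisotropy),
tortuosity, and junction/endpoint coordinates obtained by clustering
coincident branch ends (≥3 ends → junction, 1 end → endpoint). The stored
tortuosity is definitionally arc/chord of the stored centerline, which the
self-consistency test re-derives to 1e-9.

Imaging effects are a Gaussian PSF plus additive Gaussian noise on a
constant background. Shot (Poisson) noise, photobleaching and motion are
deliberately not modelled: every downstream operation is threshold- or
variance-based and first-order insensitive to the noise family, and
omitting them keeps generator truth exact. Consequently, passing tests
demonstrate estimator correctness on well-formed tubular signal, not
robustness to motion artifacts or segmentation failure modes —
segmentation itself (U-net territory) is upstream of this package, which
consumes binary masks (an Otsu fallback is provided for raw intensity and
is clearly a stand-in).

## Skeleton morphometry

Thinning uses 3D medial-axis skeletonization. The voxel adjacency graph
uses 26-connectivity with one cleanup rule: a diagonal edge is removed
when a third skeleton voxel lies strictly closer to both of its ends (an
orthogonal two-step detour exists). Without this rule every right-angle
corner presents three mutually adjacent voxels and is misread as a
junction. Junction voxels (≥3 pruned neighbors) that touch are merged into
one junction cluster; endpoints have exactly one neighbor; branches are
traced through degree-2 chains; a pure cycle is emitted as a closed branch
anchored at its lexicographically smallest voxel, flagged, and excluded
from tortuosity (tallied separately).

**Arc length.** Summing inter-voxel steps along a digital path
overestimates the length of an oblique straight line by up to ~8%
(worst near 22.5°), which would bias every curved branch's tortuosity
upward. Arc length is therefore computed on a Douglas–Peucker
simplification of the path with tolerance 1.0 voxel: staircases collapse
onto their underlying segment (digital lines deviate <0.7 voxel from the
true line), while genuine corners — whose deviation is supra-voxel — are
preserved exactly. On a semicircle of 50-voxel radius the residual error
is ≈1.5%, against ≈5–7% for the raw step sum; on an L-shaped path the
arc remains exactly the Manhattan length. Chord length is the Euclidean
distance between the end voxels. Both are scaled per axis by the voxel
size (two-photon default 2.2 × 2.2 × 3 µm).

Isolated endpoint-to-endpoint branches are included in mean tortuosity by
default (flag to restrict to junction-touching branches); spur pruning is
available but off by default. Junction density counts junction clusters
with z-index below `n_top_slices` (default 50, configurable — the
fixed-top-slab rule is used; adaptive slab selection by intensity
stationarity is not implemented) divided by the physical volume of those
planes in mm³.

## Radon velocimetry

Kymographs are blocks of at most 250 ms (full blocks have exactly
⌊0.25·line rate⌋ lines; a trailing remainder is kept if ≥50 lines, else
dropped — short blocks give high-variance angle estimates). Each
mean-subtracted block is projected at angles over (0°, 180°] in 1° steps,
then re-swept at 0.1° within ±2° of the variance peak. Including 180°
exactly in the sweep lets stationary streaks resolve to θ = 90° and v = 0
with no floating-point residue. The angle convention (diagrammed in the
module docstring): θ is measured so that streaks parallel to the time axis
sit at 90°, and v = (pitch/period)·cot θ, signed by travel direction.

The quality score is peak variance / median variance over the coarse
sweep, with an acceptance floor of 2.0 (configurable). The prior art this
step follows refines "based on SNR" without publishing a formula; the
peak-to-median ratio is this package's documented stand-in. Session
velocity is the arithmetic mean over accepted blocks.

Angle resolution bounds relative error by dθ·(1+s²)/s for slope s
px/line, so precision degrades toward both very small and very large
slopes; across 0.1–10 mm/s at the default constants the median |error| is
≈0.3% and the worst case (10 mm/s ≈ 32 px/line) can reach ~10%.

The synthetic kymograph places cells at Poisson-like random positions
(mean gap = `streak_spacing_px`): a strictly periodic train aliases the
Radon angle at high slope, which random spacing — like real capillary
flow — avoids.

FWHM diameter: background = median of the outer 10% of samples, half
level = background + (max−background)/2, crossings linearly interpolated,
outermost pair defines the width. Flow is Q = v·π·(d/2)² using the
measured RBC velocity directly; a flag applies the parabolic-profile ½
factor for users who want mean rather than centerline velocity.

## Amyloid quantification

Preprocessing: per-slice 3×3 median filter; per-slice Gaussian σ = 0.4
voxels; subtraction of a heavily blurred copy (σ = 50 px default,
configurable — the blur scale defining "low frequency" is a package
choice) of the z-average image, re-centered to zero mean so the stack's
overall level and depth profile are untouched; then z-planes are split
into 4 equal depth bins and each bin is rescaled multiplicatively to the
shallowest bin's mean (bins with near-zero mean are left unscaled to avoid
sign flips).

CAA: per vessel ROI on the MIP, threshold = mean + 1.5·SD of the amyloid
intensity inside the ROI, strict inequality. Two consequences are
inherent to this estimator and documented rather than patched: a
perfectly uniform ROI yields 0% coverage (SD = 0), and coverage fractions
above ≈31% saturate to 0% on bimodal walls because the threshold rises
past the bright mode (for a {0,1} mixture, 1 > mean+1.5·SD iff
p < 1/3.25). Recovery tests therefore exercise the sub-saturation regime.
CAA voxels are back-projected from MIP pixels into the 3D vessel mask
before plaque segmentation.

Plaques: threshold >0.6× the volume maximum after CAA removal; components
labeled 8-connected per z-slice with a strict >15-pixel filter (default),
or 26-connected in 3D behind a flag. The per-slice reading follows the 2D
language of the procedure; on a sphere it trims the few-pixel cap slices,
whereas the 3D mode recovers the enumerated ball exactly. Session values
are arithmetic means over stacks.

## TOF tracking

Vesselness is the Frangi tubularity score (α = β = 0.5, γ = half the
maximal Hessian Frobenius norm per scale — library default), maximum over
scales, normalized to [0,1]. After thresholding and removal of components
<100 voxels, the map is thinned and refined: endpoint pairs in different
components are bridged when their distance is ≤8 voxels and the
connecting segment deviates <30° from both endpoint tangents (tangent =
direction over the last ≤5 skeleton voxels), iterating until no merge.
The 8-voxel default accounts for thinning retracting ~1–2 voxels at each
free end, so a 3–4-voxel mask gap still closes while parallel vessels
tens of voxels apart never bridge.

Path reconstruction assigns every skeleton voxel to exactly one path
(junction-cluster voxels go to the first incident path; leftovers become
flagged singletons; cycles split at their lexicographically smallest
voxel) — the partition property is asserted on random trees. Diameter at
a path voxel is twice the Euclidean distance transform computed with the
physical voxel size as sampling (equivalent to isotropic resampling but
exact); this overestimates thin-cylinder diameters by roughly half a
voxel because background is measured center-to-center. The small/large
split is at the subject median with ties going to small; it is refused
outright for a single segment.

## Trajectory statistics

The interaction model is plain OLS with covariance σ²(XᵀX)⁻¹; repeated
measures per subject are treated as independent (no random effects),
which is a stated limitation. Johnson–Neyman boundaries are the real
roots of (β₃²−t²v₃₃)m² + 2(β₁β₃−t²v₁₃)m + (β₁²−t²v₁₁) with
t = t(1−α/2, df); each sub-interval's significance is decided by testing
its midpoint, which also resolves the no-real-roots case. The closed form
is verified against a dense grid of pointwise t-tests on randomized fits.
Note the boundary structure: at a moderator value where the conditional
effect crosses zero exactly, no α makes it significant, so "the whole
range" is only attainable when θ(m) has no zero crossing in range.

Piecewise regression is two independent simple regressions on either side
of the knot (default 8 months), matching separate per-side p-values
rather than a continuous segmented fit. The sigmoid is the 4-parameter
logistic fit by Levenberg–Marquardt from three starts (t₀ at the age
quartiles), best SSE wins, orientation normalized to k > 0; a
Gaussian-CDF form with the same parameterization sits behind `form=`
(the two differ by <0.05 month in recovered inflection on clean logistic
data). Constant data is flagged non-converged (k unidentifiable).

LOESS is local linear with tricube weights over the ⌈span·n⌉ nearest
points, evaluated on a 100-point grid, with a seeded bootstrap pointwise
band (500 resamples by default). At span = 1 the weights are defined as
uniform so the smoother coincides with the global linear fit — the
documented limit convention. Cross-species overlay z-scores each curve
against its own smoothed values and maps age to (age−min)/(max−min),
overlaying on a shared [0,1] grid; the normalized-age mapping, span and
resample count are package choices recorded in the outputs.

ANOVA/Tukey delegates to the standard HSD implementation; the two-group
case collapses to the pooled t-test (q = t√2), asserted to 1e-6.

## Transcriptome overlap

All gene symbols are uppercased before comparison, which doubles as the
mouse→human mapping rule (Mmp2 → MMP2); no orthology service is consulted
(a hook accepts an explicit table). FDR filtering is strictly <0.05.
Genes in several marker sets count under every matching cell type — the
per-type counts are not mutually exclusive. The two-stage human overlap
is monotone by construction (stage 2 ⊆ stage 1) and atlas cell types
missing from either human table are reported as unmatched, never silently
dropped. The omics generator assigns true non-nulls FDR < 0.05 with a
configurable detection power and nulls FDR ≥ 0.05 deterministically, so
set-level truth is exact.

## End-to-end experiment

`vasotrace.workflow` simulates the longitudinal design: per arm
(control/model) and age, a sinusoidal-centerline phantom whose amplitude
follows an arm-specific logistic trajectory (model arm inflection 8
months, control 15 months, amplitude 0.8→6 voxels, jitter SD 0.3), with
tortuosity *measured* by the skeleton pipeline so the statistics see real
estimator noise. The interaction test runs on the early-life window
(≤12 months), where the arm difference grows monotonically; over the full
lifespan the control arm's late rise closes the gap and a linear
age×group term is the wrong alternative — the full-range pattern is
instead checked qualitatively (early rise in the model arm, late rise in
controls).

## Problem sizes

Test and acceptance runs use phantoms of ~48–110 voxels per side, 200
kymographs for the velocity sweep, 50 seeds for CAA recovery, 500 null
simulations for type-I calibration, 200 noisy sigmoid fits, 1000 random
fits for the Johnson–Neyman oracle, 100 random trees for the partition
property and 100 seeded end-to-end cohorts. These sizes give binomial
confidence comfortably inside the asserted bands while keeping any single
check at most a couple of minutes on one core.

## Known limitations

* No subject-level random effects; longitudinal correlation is ignored.
* CAA coverage saturates above ≈31% on bimodal walls (property of the
  mean+1.5·SD rule, not of the implementation).
* Diameters from the distance transform carry a ~half-voxel positive
  bias on thin vessels.
* The synthetic generators do not emulate motion, bleaching, shot noise
  or segmentation errors, so results bound estimator error, not
  end-to-end acquisition error.
* Gap-closing parameters are geometric heuristics; the refinement stage
  is a reconstruction of the cited tracking pipeline's intent, not a
  claim of exact equivalence.
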