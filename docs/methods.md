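# Methods

## Contour model and geometric conventions

LA endocardial contours are open polylines in image-plane millimetres
(y increasing downward as in rasters; every operation is orientation-
agnostic), running from one mitral-annulus insertion to the other — the
valve plane is not atrial wall. The centroid is the arc-length-weighted
polyline centroid with the endpoint chord standing in for the valve plane,
so point density cannot bias the centre; a raw vertex mean would move with
resampling. Contours are resampled to a uniform arc-length grid (default
120 points) before any per-segment quantity, and per-point radii are pooled
into 12 contiguous segments. Neither count is dictated by the measurement
model; 12 matches common atrial segmentation granularity, divides 120, and
both are configurable. The constructor accepts 2-point polylines so the
primitives can be exercised on analytic shapes; file readers and
`ContourSequence` enforce the ≥ 8-point input invariant.

## Strain and radial motion

The reference frame is frame 0 of the cine — the acquisition trigger, where
the LA sits near minimum volume — so the reservoir peak is positive.
Longitudinal strain is Sl(t) = (Lt − L0)/L0 on polyline lengths. Radial
motion fraction is Mr(t) = (Mt − M0)/M0 per segment, averaged, with radii
measured toward the *reference-frame* centre of mass held fixed for the
whole cycle: expansion is positive, and ventricular translation deliberately
registers as radial motion so the MV decomposition has something to
separate. Under a uniform scaling of the contour about that centre by
(1 + s), both Sl and Mr equal s exactly; a rigid translation leaves Sl at 0.

Strain rates use centred finite differences (one-sided at the ends) on
times in ms, reported in s⁻¹. A 3-point moving average before
differentiation is the pipeline default (20-phase cine derivatives are
noise-amplifying) and is off at the function level so exactness on clean
ramps holds at the call site; the setting is recorded in run metadata.
The cohort tables report strain in percent and rates in s⁻¹; a reservoir
strain of 33% peaking at ~1.3 s⁻¹ is the healthy scale.

## Phase detection

No ECG timing exists in the data model, so phases come from curve shape:
the reservoir peak is the global maximum of Sl; atrial-contraction onset is
the mid-diastolic shoulder — the sample between the peak and cycle end,
constrained to the last 40% of the cycle, with the smallest strain-rate
magnitude. Ties (a genuinely linear or flat conduit tail makes the rate
constant) resolve to the latest tied sample, where passive emptying
actually ends. An explicit onset time can override the rule. Monotonic or
flat curves raise a phase-detection error rather than guessing.

Phase amplitudes: R is the curve value at the peak; A is the value at
onset minus the end-of-cycle value; C = R − A, making R = C + A an exact
identity of the extraction, not an approximation. Rate indices are the
signed extrema within each phase window; E′/A′ ratios are magnitude
ratios. View averaging is field-wise arithmetic mean with ratio fields
recomputed from the averaged numerators and denominators.

## MV decomposition

Geometry is frozen at the reference frame: the MV centre is the midpoint of
the annulus landmarks, the axis the unit vector from the LA centre of mass
toward it. Freezing matters — the decomposition separates ventricular drag
from intrinsic deformation, and re-estimating the axis per frame would
absorb the very translation it is meant to expose. Per segment, the mean
displacement vector from the reference position is projected on the axis
and its normal; the projected *magnitudes* are normalised by the same
reference radii M0 used for Mr and averaged over segments. Magnitudes
rather than signed projections because under the near-isotropic expansion
of the reservoir phase signed axis-projections cancel across segments,
which would pin cMr near zero — incompatible with the observed
commensurability of cMr, pMr and Mr (and with pMr_R exceeding Mr_R in
control cohorts). Consequently cMr + pMr ≠ Mr in general; the tested
contract is exact recombination, (d·u)² + (d·v)² = |d|² per segment and
frame. A degenerate axis (LA centre on the MV centre) is an error, not a
guess.

## Volumetrics

LV: summation of discs over short-axis slices (shoelace areas ×
thickness + gap), mass from the end-diastolic epi−endo shell at
1.05 g/mL. LA: biplane area-length V = 0.85·A₂·A₄/min(L₂, L₄), the
standard choice when only long-axis views cover the atrium, with a
single-plane fallback. BSA by Mosteller (Du Bois selectable), BMI as
weight/height². Indexing is plain division by BSA.

## Dixon fat quantification

Intra-myocardial fat fraction is the septal-ROI mean of F/(F+W) × 100;
zero-signal voxels are excluded and counted in QC. No T2* or bias-field
correction is attempted. Epicardial fat is segmented by K-means (k = 2,
adipose vs non-adipose — the decision surface is a single intensity
threshold; k configurable) on fat-image intensities inside the whole-heart
mask, seeded k-means++ with 10 restarts, 300-iteration cap, tolerance 1e-6,
hence deterministic given a seed and invariant to positive intensity
scaling and to voxel order. The adipose cluster is the one with the highest
centroid; absolute volume is voxel count × voxel volume, the fraction
divides by the full mask volume (the "whole heart" denominator includes the
epicardial envelope).

## Phantoms: what they emulate and what they do not

**LA cine phantom.** An elliptical arc (base radius 30 mm, eccentricity
0.15, 220° span) scaled uniformly about its reference centroid along a
piecewise-cosine strain waveform — rise to the reservoir target at
t_peak (default 0.4 of the cycle), fall to the contraction amplitude at
onset (0.75), return to zero — plus a rigid translation along/across the
MV axis following the same time profile. Cosine segments make the phase
times exact stationary points of the rate curve and the phasic amplitudes
exact by construction. Defaults are the healthy-control condition
(Sl_R 33.2%, Sl_A 16.7%, 20 frames over a 1000 ms cycle, zero noise); the
decomposition configuration adds translations of 13.25/15.95 mm, calibrated
once so cMr_A and pMr_R sit at control-cohort scale (≈ 20.3 / 53.3%).
Three views are rotations/squeezes of the same shape with amplitude
multipliers (0.98, 1.00, 1.02 — mean exactly 1) so view averaging has
genuine spread yet an unbiased mean. Ground truths are closed-form
(perimeter ratios, waveform values), never computed by the code under
test. Not emulated: true feature-tracking correspondence errors,
through-plane motion, irregular RR intervals — so passing recovery tests
demonstrates correctness of the measurement chain, not robustness of
tracking on real cine data.

**Dixon phantom.** Concentric spheres — blood pool, myocardial shell with a
set fat fraction (default 6%), epicardial fat shell — with radii solved
from target volumes (defaults: 176.4 mL fat in an 840 mL mask — the
control-cohort scale) on a 64³ grid of 2 mm voxels; Gaussian channel noise
(SNR 10 ⇒ σ = 90 at fat intensity 900), clipped at zero. Truths are voxel
counts: what a perfect segmentation of the digital object would measure.
At SNR 10 the class separation is ~9σ, so K-means recovery is essentially
exact; the septal-ROI fat fraction, a mean of the *ratio* F/(F+W), is
biased upward by noise (≈ +0.6 pp at SNR 10) — visible in the analysis
driver and expected of the estimator, not a defect. Not emulated: coil
shading, fat–water swaps, partial-volume beyond voxelisation, non-spherical
anatomy.

**Cohort generator.** Independent normal draws per variable from the
published control/ObT2D group means and SDs. No intra-subject correlation
structure, so it supports calibration and power exercises, not multivariate
claims.

## Statistics

Normality is checked per group by Shapiro–Wilk at α = 0.05; both-normal
pairs get the equal-variance independent-samples t test (Welch by flag),
otherwise Mann–Whitney U (exact for tie-free samples of n ≤ 8, normal
approximation with tie/continuity correction beyond). Significance is
p < 0.05, two-sided, *uncorrected for multiplicity* — the comparison tables
report raw p-values, deliberately, and readers should treat marginal
results accordingly. Pearson r uses the t transform for p. ICC is the
two-way, absolute-agreement, single-measure form ICC(2,1) computed from
ANOVA mean squares, with ICC(3,1) by flag. Under a true null at the
study's group sizes (19/20) the gated comparison rejects at 5.1% over
10⁴ simulations.

## Numerical choices and degenerate inputs

Zero-length contours, zero radii, empty ROIs, constant images under
clustering, zero-variance correlations and degenerate ICC tables all raise
typed errors rather than returning NaN. Frame times must be strictly
increasing with t₀ = 0; fewer than 10 frames is rejected as insufficient
temporal resolution. All randomness flows from explicit seeds; pipeline
stages derive per-(stage, subject) streams by CRC32 hashing so adding a
subject never perturbs another's draws, and reruns are byte-identical.

## Problem sizes

Default problem sizes — 120-point contours, 20 cine frames, 64³ Dixon
grids (48³ voxels at 2.5 mm in cohort runs), 39-subject cohorts, 10⁴ null
simulations — were chosen as the smallest sizes at which discretisation
error is negligible against the 2% recovery bands; the full test suite and
the acceptance script each run in well under a minute of CPU apiece for
the phantom work, with the null-simulation calibration dominating at ~10 s.

## Known limitations

- The A-onset shoulder rule assumes a discernible mid-diastolic plateau;
  tachycardic fusion of E and A would defeat it (override available).
- cMr/pMr normalisation and sign conventions are package choices; the
  decomposition literature has not standardised them, so absolute values
  are comparable within-pipeline only.
- The Dixon fat-fraction estimator inherits ratio-of-noisy-channels bias.
- The BMI-adjusted comparison reported alongside the original cohort
  analyses is not implemented: the adjustment model is unspecified, and
  guessing one would imply comparability we cannot verify.
- Echocardiographic inputs are treated as given values, never recomputed.
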