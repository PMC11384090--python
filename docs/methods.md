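# Methods

## Problem and model

Proton-density fat fraction (PDFF) of vertebral bone marrow is a
quantitative MRI biomarker: the fraction of MR-visible proton signal
attributable to fat, in percent, computed from chemical-shift-encoded
(Dixon) acquisitions. Vertebral bodies vary in size and shape between
lumbar levels and between subjects, and their marrow fat is spatially
inhomogeneous, so voxel-wise distributions cannot be compared directly
across vertebrae. `vertemap` addresses this by registering every segmented
vertebral body onto one *standardized elliptical cylinder* and reading the
fat-fraction distribution off three perpendicular mid-planes of that
template, after correcting each vertebra's sagittal inclination.

The pipeline per vertebra is:

1. **ROI extraction** — crop the labelled vertebra to its bounding box plus
   a margin (default 2 voxels); keep the largest connected component if the
   label is fragmented; the unweighted mask centroid is the center of mass
   (com).
2. **Inclination estimation** — in the mid-sagittal mask slice (at the
   com's horizontal index), take for every dorsoventral column the most
   inferior masked pixel; run a straight-line Hough transform over these
   edge points (in mm) and report the dominant angle. Positive angle means
   the ventral end points inferior.
3. **Inclination correction** (optional) — rotate scalar and mask about the
   horizontal axis through the com by the estimated angle, resampling in mm
   space (linear for the scalar, interpolated-indicator ≥ 0.5 for the
   mask), padding the grid so no masked voxel is lost.
4. **Template mapping** — one-dimensional linear interpolation applied axis
   by axis:
   * *transverse map* (33 × 41): every mask-crossing image row of the
     mid-transverse plane is resampled horizontally to 41 samples; the row
     stack is resampled dorsoventrally to 33 rows; each template row is
     then compressed to the elliptical chord width and centered. Pixels
     outside the ellipse are invalid (NaN).
   * *sagittal* (20 × 33) and *coronal* (20 × 41) maps: per axial slice the
     masked run in the mid-plane is resampled to the template width, then
     the slice stack is resampled head–feet to 20 rows.
5. **Statistics** — mean/min/max/SD over masked voxels (volumetric) and
   over the valid template pixels (per plane and pooled across the three
   planes). SD is the inhomogeneity measure; the sample convention (n−1)
   is used everywhere.

Method agreement between map-derived and volumetric values is summarized
by Bland–Altman bias and 1.96·SD limits of agreement (differences taken as
maps − volumetric). Group contrasts use Welch's t-test when both samples
pass Shapiro–Wilk normality at α = 0.05 and the two-sided Mann–Whitney U
test otherwise; segmentation masks are scored against a reference with the
standard confusion-matrix family (Dice, Jaccard, precision/recall, FDR,
FNR, FOR, FPR, NPV, TNR, accuracy) plus absolute and relative volumetric
error (relative to the reference volume).

## Template geometry

The elliptical base is sampled with 20 points on the major (horizontal)
semi-axis and 16 on the minor (dorsoventral) semi-axis. We read these as
*per semi-axis* counts and use the symmetric odd grid 2n+1 (both semi-axis
endpoints plus a well-defined center pixel): 41 × 33 transverse nodes. The
20 longitudinal sampling points are read as 20 total rows, since the long
axis has no semi-axis symmetry. The template footprint is elliptical:
node (i, j) is valid iff (i/20)² + (j/16)² ≤ 1; each transverse row is
shrunk to its chord width rather than masking a rectangular map. All three
counts are configurable (`template.n_major/n_minor/n_long` ↔
`TemplateGeometry`).

Two consequences hold by construction and are tested as theorems:

* **Smoothing bound.** Every template pixel is a convex combination of
  masked voxel values, so map minimum ≥ volumetric minimum and map maximum
  ≤ volumetric maximum on *every* input. The template systematically
  overestimates the minimum and underestimates the range/SD — the map SD
  is a smoothed inhomogeneity measure.
* **Mid-plane pooling bias.** Pooled map statistics average the three
  mid-planes, and the sagittal/coronal planes pass through the template
  axes where a radially varying field sits below (or above) its volume
  average. For a field with radial component r·(u²+v²) the pooled mean
  differs from the volumetric mean by ≈ −0.087·r in closed form. This
  small, sign-carrying bias is inherent to mid-plane sampling, not an
  implementation artifact; the cohort Bland–Altman in the acceptance
  script shows the corresponding small bias with ~±1 % limits of
  agreement.

## Inclination estimation

The Hough accumulator runs over angles in ±30° at 0.5° steps (defaults;
`hough.half_range_deg`, `hough.resolution_deg`). For each angle the edge
points' line offsets are scanned with a sliding window rather than fixed
offset bins, so votes never split across a bin edge. The window width
defaults to the ROI's slice spacing: detected edge z-coordinates are
quantized at exactly one slice, so a pitch-matched window captures every
inlier of the true orientation while the staircase of a wrong orientation
spreads beyond it. Estimates from fewer than 5 edge points
(`hough.min_edge_points`) are marked invalid and no correction is applied.

Two numerical choices matter and were fixed after explicit comparison:

* **Plateau tie-break.** Voxelized edges support a plateau of angles with
  equal (maximal) votes. Taking the plateau's *median* is unbiased;
  preferring the smallest |angle| over the whole plateau shrinks every
  estimate toward zero by up to the plateau half-width (~2° at 20° tilt).
  The small-|angle| preference survives only for exact two-way ties.
* **Mask resampling.** Under rotation the mask is transported as a linearly
  interpolated indicator thresholded at 0.5 (majority rule). This keeps
  labels crisp while roughly halving the surface-voxel churn of
  nearest-neighbour sampling (round-trip Dice 0.989 vs 0.947 on a
  15 mm-scale body at 10°).

Angle recovery is resolution-limited by acquisition geometry: with 3 mm
slices over a ~25 mm vertebral depth, a 5° tilt displaces the inferior
edge by tan(5°)·25 ≈ 2.2 mm — less than one slice — so *no* line detector
can resolve it from the rasterized mask. The recovery tests therefore use
phantoms with 0.8 mm slice pitch to characterize the estimator itself
(≤ 1° error over ±20°, zero residual after closed-loop correction); at the
clinical 3 mm pitch the estimate quantizes to roughly ±6° steps, which is
the honest precision of mask-based inclination at that resolution.

## Mid-plane selection

The three mid-planes are sampled at the exact center-of-mass coordinate by
linearly blending the two bracketing voxel planes (mask-weighted, so a
pixel masked on only one side takes that side's value). Snapping to the
nearest voxel plane instead would add a bias of (plane offset × local
gradient) — up to ~0.3 % PDFF at 3 mm slices — large enough to dominate
the mean-agreement budget below. With blending the choice of a tie rule
becomes irrelevant.

## Synthetic phantoms

The generator models each vertebral body as a superellipse cylinder
|x/a|ⁿ + |y/b|ⁿ ≤ 1, |z| < h/2 (n ≥ 2; n ≈ 2.5–3.5 gives the
rounded-rectangular cross-section of real bodies), optionally tilted about
the horizontal axis, rasterized on an anisotropic grid (default
1.2 × 1.2 × 3.0 mm, the acquisition-like resolution) and filled with an
analytic field

    PDFF(u, v, w) = base + gᵤu + gᵥv + g𝓌w + r·(u² + v²),

evaluated in the body's own normalized frame *before* tilting, plus
optional seeded Gaussian noise, clipped to [0, 100]. Background is exactly
0 % so any mask-leakage bug depresses means detectably. Because the
standardization maps every vertebra back onto this normalized frame, the
analytic field is the exact ground truth for the standardized maps —
bodies of different size with the same normalized field must yield the
same maps, which is the package's headline shape-independence test
(tolerance: ≤ 2 % PDFF pixel-wise over isotropic rescaling by 0.7–1.3).

Default cohort conditions (`cohort_fixture`): five vertebrae per subject,
semi-axes a ∈ [13, 17] mm, b ∈ [9, 13] mm, heights 25–35 mm (volumes
≈ 10–25 ml), exponents 2–3.5, inclinations ±12°, base fat fraction 25–55 %
with a mild inferior-to-superior decrease (lumbar marrow is fattier at
L5), per-axis gradients ±8 %/unit, radial amplitude ±5 %, voxel noise SD
3–8 %. These produce per-vertebra voxel SDs of roughly 5–11 % and maxima
reaching 50–90 %, spanning the values reported for adult lumbar marrow
across age and sex groups.

What the phantom does *not* model: trabecular texture, T2*/field
inhomogeneity, Rician noise on complex signal, partial-volume mixing with
cortical bone, and real spine curvature. Passing tests therefore
demonstrate the geometry and statistics of the method, not robustness to
MR physics confounds.

The z-interval of the rasterizer is half-open ([−h/2, h/2)): with a closed
interval, slice centers landing exactly on both endplates count one slice
too many (a 10 % volume bias for a 30 mm body at 3 mm slices). Rasterized
mask volumes agree with the analytic superellipse-cylinder volume
4abh·Γ(1+1/n)²/Γ(1+2/n) to < 5 % at default resolution, with
monotonically shrinking error under grid refinement.

## Test conditions and error budgets

Property tests fix their phantom resolution to keep voxelization below the
property tolerance being verified, while the generator default stays at
the acquisition-like 1.2 × 1.2 × 3.0 mm:

* mean-agreement and shape-independence suites: 1.5 mm slices (the
  mid-plane blend and run-extent quantization then contribute ≲ 0.1 %);
* inclination suites: 0.8 mm slices (see above).

The mean-agreement check (noiseless linear+radial fields, 20 random specs,
|pooled map mean − volumetric mean| ≤ 0.5 %) budgets 0.35 % for the
inherent pooling bias — which caps the radial amplitude of the sampled
fields at 4 %/unit², via the 0.087·r closed form — and 0.15 % for
discretization. It is restricted to elliptical (n = 2) cross-sections:
for super-elliptical bodies the elliptical template introduces an
additional genuine shape-mismatch bias, the same class of effect the
method exhibits on real vertebrae, so exact mean preservation is only an
analytic property of the elliptical case. The signed bias is recorded
alongside.

Group-test machinery is calibrated under the null: with two N(0, 1)
samples of n = 15, 2000 replications, the Shapiro-gated Welch/Mann–Whitney
procedure rejects at 5.2–5.5 % depending on seed (nominal 5 %). The
cohort-level type-I check aggregates over 20 replications × 5 vertebrae
(100 tests) because "no rejection anywhere in a replication" is itself a
multiplicity-affected event with probability ≈ 0.95⁵ ≈ 0.77 under the
null — an aggregate rate is the statistically meaningful calibration.

## Degenerate inputs and edge policies

* PDFF values outside [0, 100] are clipped on read (count logged), not
  rejected: reconstruction noise routinely produces small excursions.
* Oblique acquisitions are resampled to the nearest canonical axis-aligned
  grid (linear for scalars, nearest for labels) with a prominent log line;
  axis-aligned files are reoriented losslessly. Files with missing or
  singular orientation metadata are rejected with instructions to
  construct the volume manually.
* Stray label values are zeroed with a warning; a label split into several
  components keeps the largest.
* Non-contiguous masked runs within a row (slice-scale concavities) are
  interpolated across between the flanking masked voxels — background
  never enters the template.
* Masks thinner than two slices cannot support sagittal/coronal maps and
  raise; a mid-sagittal slice with fewer than 5 edge columns yields an
  invalid inclination estimate (angle 0, no correction).
* Relative volumetric error against an empty reference mask is undefined
  and reported as NaN.

## Problem sizes

Default test phantoms are single vertebrae of ~3 000–25 000 masked voxels
on grids of ≲ 60³; cohort-level checks use 6–8 subjects × 5 vertebrae.
The full suite runs in well under a minute on one core; the acceptance
script recomputes everything in a few seconds.

## Known limitations

* Only the sagittal-plane inclination is corrected; coronal tilt and axial
  rotation are out of scope, as is any non-rigid registration.
* The inclination angle at 3 mm slice pitch is quantized (~±6°); treat
  per-vertebra angles at clinical resolution as coarse indicators.
* Pooled map statistics carry the mid-plane sampling bias described above;
  comparisons should stay within one quantification route (maps vs maps,
  volumetric vs volumetric), which is how the tooling reports them.
* The segmentation itself is an input: the package evaluates masks but
  never produces them.
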