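# Methods

This note documents the models, conventions and numerical choices behind
`lungqct`, and what the phantom-based validation does and does not show
about real CT data.

## Coordinate and data model

All volumes live on regular grids with 0-based voxel indices and the map
`world = spacing · index + origin` (mm) per axis, arrays indexed `(i, j, k)`
along world `(x, y, z)`. HU volumes are integer-valued (CT convention) and
restricted to the scanner range [−1024, 3071]. Lobe masks label the five
lobes LUL, LLL, RUL, RML, RLL (0 = background); regions RL, LL and WL are
unions of lobes. NIfTI and MetaImage files round-trip through SimpleITK;
skeletons are JSON (`points`, `edges`, `branches`); tables are CSV written
at 6 significant digits.

## Airway morphometry

A branch is an ordered run of centerline points. Metrics are measured on
the plane orthogonal to the local centerline tangent at a configurable
arclength station (default mid-branch, 50%, which avoids bifurcation
flare). The plane is resampled at `min(spacing)/4` with linear
interpolation and smoothed with a Gaussian of σ = 1.0 × voxel spacing
(physical units) before the lumen boundary is extracted as the sub-pixel
0.5-level contour (marching squares). The smoothing step matters: the
0.5-level contour of a raw bilinearly interpolated binary mask inherits the
jagged voxel boundary and overestimates perimeter by ~6–9% across the
spacings we test, which would both break the isoperimetric bound `Cr ≤ 1`
and destroy convergence of `D_h`; with physically scaled smoothing the
perimeter error decays with spacing (measured ~1.5% → 0.7% → 0.3% over 1.0
→ 0.5 → 0.25 mm on a 5 mm-radius tube). Contour area comes from the
shoelace formula, perimeter from polygon arclength; the contour enclosing
the plane center is taken, nested contours raise a non-simply-connected
error, and disjoint contours from sibling branches crossing the plane are
ignored.

Derived quantities use equivalent-area diameters: `D_inner = 2√(LA/π)` and
`D_outer = 2√((LA + wall area)/π)`, which makes `Cr = π·D_inner/P_e`
exactly 1 for an analytic circle. Wall thickness defaults to the diameter
difference `D_outer − D_inner` — twice the physical wall — matching the
description of WT as a difference of average diameters; the `radial`
convention (half that) is a config switch because published WT conventions
vary, and the convention used is stamped into outputs.

Daughter direction vectors run from the bifurcation point to the point 30%
along the daughter's arclength (configurable): short spans are
noise-sensitive, full spans bend-sensitive. The bifurcation angle is the
cosine-law angle between the two daughters, clamped into [−1, 1] before
`arccos`; at a trifurcation the pairwise daughter angles are averaged.
Lobar subgroup rows aggregate member branches by arithmetic mean.

Note on conditioning: the angle is rotation-invariant to ~1e−9 degrees for
generic geometry, but `arccos` is ill-conditioned near 0° and 180°, where
only ~1e−5 degrees is achievable in double precision; the property tests
reflect this.

## Reference regressions and normalization

The three published tracheal regressions (diameter, luminal area, wall
thickness as functions of age in years, height in meters, and binary sex)
are evaluated verbatim, including the logged leading constant and the
height² terms of the wall-thickness equation, which we deliberately do not
"correct". The publication writes `log` without a base and both natural and
base-10 give self-consistent diameter/area pairs, so the base is a
mandatory parameter (default natural) recorded in every output. Heights
above 3 m are rejected with a centimeters hint rather than silently
converted, because demographic tables commonly report cm while the
equations need m. Normalization is a plain ratio to the reference value.

## HU classification

The five primary classes tile integer HU up to 60 with inclusive endpoints;
emphysema is strictly below −950, i.e. ≤ −951 on integers — the only
reading under which the printed ranges tile without gap or overlap.
Fibrosis (−500..0) overlaps semi-consolidation and consolidation by
construction and is reported as an overlapping mask, never subtracted, so
class percentages do not sum to 100 once Fibr is included; the identity
`Fibr = (Semiconso ∪ Conso) ∩ {HU ≤ 0}` holds exactly and is asserted.
In-mask voxels above 60 HU form an explicit "Dense" remainder rather than
being forced into consolidation. Percentages divide by all in-mask voxels
of the region by default; an `aerated` denominator (HU in [−1000, 0]) is
available because the denominator convention for published per-lobe
percentages is ambiguous. The aerated-lung histogram uses 1-HU bins over
the closed range −1000..0.

## Vessel profiles

`BVk` sums the volume of vessel voxels with local cross-sectional area
strictly less than k mm² ("less than" read literally), voxel-wise rather
than per segment, since segment-level assignment by upstream software is
not reproducible here; local area is an input attribute, with a `πr²`
helper for radius fields. The profile is cumulative by construction, and
`BV20 ≤ TBV` with equality only when no vessel reaches 20 mm².

## Deformation metrics

Gradients are central differences in world millimeters (one-sided at
boundaries), exact for affine fields at interior voxels — the basis of the
closed-form oracle tests. Principal stretches are square roots of the
eigenvalues of `FᵀF`; voxels with non-positive eigenvalues (folded fields)
become NaN and drop out of summaries. The ADI/SRI formulas adopted here are
the eigen-stretch ratio forms

    ADI = √(((λ₁−λ₂)/λ₂)² + ((λ₂−λ₃)/λ₃)²)
    SRI = (2/π)·atan2((λ₁−λ₂)/λ₂, (λ₂−λ₃)/λ₃)

— scale-free, rotation-invariant, ADI = 0 iff isotropic, SRI ∈ [0, 1] with
0 = slab-like (λ₁ = λ₂ > λ₃) and 1 = rod-like (λ₁ > λ₂ = λ₃); the
isotropic case maps to SRI = 0 via atan2(0, 0) = 0. The polarity is a
package convention, configurable in the pipeline config and stamped with
the formulas into output metadata. Regional summaries report median and
quartiles per region; apex-to-base profiles take slice medians at depth
fractions 0.2/0.4/0.6/0.8 of the in-mask extent along the cranio-caudal
axis, apex by default at the high end of axis 2.

## Cohort simulation and statistics

The cohort generator emulates the two-visit design: default n = 31 subjects
and Gaussian scan intervals of 360.10 ± 15.38 days truncated at > 0,
matching the cohort shape this pipeline targets. Per metric,
`followup = baseline·(1 + effect_rel) + effect_add + ε`, `ε ~ N(0, σ)`, so
a null effect gives mean-zero paired differences by construction. Gaussian
noise is a stand-in — the underlying study reports only means and SDs, not
a noise model.

Progression is `((var_f − var_b)/var_b)·(avg interval / individual
interval)`, with the cohort-average interval defaulting to the sample mean
(360.10 days in the emulated design). This assumes an approximately
constant per-day rate; with a 4% interval CV the Jensen bias of the
interval ratio is ≲ 2·10⁻³ relative, far below the effect sizes of
interest. Progression-recovery validation uses baseline 100 ± 10 with noise
σ = 5 (a 5% measurement noise typical of these metrics) so the 3-SE
recovery band over 10³ replicate cohorts is well separated from that bias.

Paired comparisons gate on a Shapiro–Wilk test of the paired differences at
α = 0.05 (the statistic concerns differences, not the arms): normal →
paired t, non-normal → Wilcoxon signed-rank with Pratt zero handling, exact
distribution when n < 25 with no zeros or ties, otherwise the normal
approximation with continuity correction. Calibration is checked against
two null families: Gaussian differences, and sign-symmetrized lognormal
differences (random sign × lognormal magnitude). Symmetrization is
essential to the second check — the Wilcoxon null is symmetry about zero,
which a mean-centered lognormal violates — and it exercises the non-normal
branch with genuinely heavy tails. Both branches hold a 5% type-I error
within [0.04, 0.06] at n = 31 over 10⁴ replicates.

Multiplicity uses Benjamini–Hochberg step-up q-values — the standard
default, since the original Q-value procedure is unstated — applied within
declared metric families (configurable map, one family by default), with
the method recorded in outputs; q ≥ p always holds for BH. The Spearman
matrix uses average-rank ties and pairwise-complete observations, requires
≥ 3 complete pairs per variable pair, and flags constant variables (NaN
correlations) rather than fabricating values.

## Pipeline and reproducibility

All randomness flows through seeded `numpy` Generators; fixed seed means
bit-identical phantoms. The pipeline runner writes a JSON manifest holding
the config snapshot (every ambiguous convention made explicit), package
version and input checksums; deterministic stages are bit-identical across
reruns, and a rerun with unchanged inputs and config skips stages by
checksum. Registration itself is out of scope — displacement fields are
inputs produced by external B-spline registration tooling; the deformation
module consumes the standard vector-image formats such tools write.

## Validation design and problem sizes

Phantoms are built so downstream recovery is sharp: parenchyma phantoms
allocate class voxel counts by largest-remainder rounding and draw HU from
the open interior of each class range, so fraction recovery is exact (a
test of the classifier, not of tie-breaking or sampling noise); vessel
segments are laid out disjointly with volumes matched to within one voxel;
affine displacement phantoms carry closed-form tensors; tube phantoms carry
analytic cross-section measures. Geometry convergence is assessed with the
tube at a generic (tilted) orientation — a voxel-aligned axis puts the
lattice in a symmetric special position whose coarse-grid error is
anomalously low, masking the true convergence order.

Problem sizes used in the validation battery — 64³ deformation grids,
~15³–30³ classification grids, 10³ replicate cohorts for effect recovery,
10⁴ replicates for test calibration — were chosen as the smallest sizes at
which the quantities stabilize well inside their tolerance bands.

## Limitations

The phantoms validate the measurement and statistics machinery, not the
upstream segmentation, branch labeling, super-resolution enhancement, or
registration that produce the inputs in a real study; passing tests say
nothing about errors those stages introduce. Tube phantoms are straight,
single-material and noise-free — no scanner noise, beam hardening, partial
volume from neighboring structures, or non-circular pathology beyond
ellipses. The lobe partition is a geometric block layout, not anatomy. The
cohort generator's Gaussian noise and truncated-Gaussian intervals are
modeling conveniences. The WT and SRI polarities, the reference-equation
log base, and the percentage denominator are genuinely ambiguous
conventions surfaced as explicit parameters; results are only comparable
across studies when those stamps agree.
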