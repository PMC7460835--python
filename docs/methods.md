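# Methods

This note documents the models, numerical choices and assumptions behind
`leafseal`, in the order the pipeline uses them.

## Synthetic leaf cohorts

The generator reproduces the structure of the wound-sealing experiment:
a leaf with a ring incision at the apical-third boundary carries painted
markers at the apex (p1), 2 mm above (p5) and below (p9) the incision,
the base (p17) and halfway between p9 and the base (p13); the remaining
12 markers are virtual, equally spaced in arc length between painted
neighbours at t₀ and carried by arc-length proportionality afterwards.
Frames are sampled at 1/6 Hz for 60 min (601 frames).

**Contraction time-course.** Each segment's arc length follows
L(t) = L₀ (1 + ε∞ (1 − e^(−t/τ))). The saturating-exponential form is a
surrogate for hydraulic stress relaxation — observed median contraction
curves saturate, but no functional form is established — and is a
config-visible choice (`tau_min`, default 10 min, chosen so the
contraction is ≈ 99.75 % complete at 60 min). Contraction is applied as
uniform arc-length scaling within each segment about its proximal
(base-side) boundary, with segments re-stacked from the base; the
intra-segment strain profile of real leaves is unknown.

**Geometry.** Straight leaves lie on a vertical line (origin at the
base, y upward). Recurved leaves lie on a circular arc — the simplest
one-parameter recurved midline — with default radius 40 mm for a
27.4 mm leaf (≈ 39° of arc), matching the visual impression of a gently
recurved leaf. Default lengths are the species means: 45.5 mm
(straight) and 27.4 mm (recurved).

**Noise and cohorts.** Tracking error is isotropic Gaussian per
coordinate per frame; its magnitude is unreported for the real setup, so
the default sd of 0.02 mm (≈ 1/50 of the leaf diameter, sub-pixel for
the cameras used in such rigs) is an assumption. Cohorts follow the
2 species × 2 RH × 10 leaves design. Per-leaf plateaus are drawn
Normal(group mean, `between_leaf_sd`, default 0.01) truncated to
(−1, 0]; group plateau means are assumptions ordered to match the
study's findings (strongest contraction in the incision region of the
straight-leaved species; stronger contraction at low RH). Per-leaf
seeds derive from the cohort seed through one `numpy` generator, so
cohorts are reproducible leaf-by-leaf.

**What the generator does not emulate:** perspective error of the
two-camera rig, leaf bending or twisting out of plane, marker dropout,
gravity differences between mounting orientations, and any correlation
structure of tracking error along the leaf. Passing recovery tests
therefore demonstrates correctness of the measurement chain under the
stated noise model, not robustness to all failure modes of real video
tracking.

## Kinematics

For straight leaves the segment length is the |Δy| of the boundary
markers (the convention used for the upright-mounted species). For
recurved leaves each frame's 17-marker cloud is fitted with a
least-squares polynomial midline and segment lengths are arc lengths
along the fit:

- The cloud is first rotated (about the origin) to its principal axis,
  which keeps the curve single-valued even for strongly recurved or
  vertically mounted leaves. Polynomial degree defaults to 3 and is
  configurable; the conformance suite passes at degrees 3–5.
- Boundary markers map to the curve by nearest-point projection, solved
  as a root of the distance gradient (well conditioned where the
  squared distance itself is flat); arc length is adaptive quadrature of
  √(1 + y′²) to relative tolerance 1e-8.
- ε(t₀) = 0 holds exactly by construction; ε and ε* are invariant under
  uniform coordinate scaling to < 1e-12.

On noiseless synthetic leaves the recovered lengths match the
generator's closed form to ≈ 1e-4 relative at degree 3 and < 1e-6 at
degree 5 (the residual is polynomial-vs-arc approximation error, not
quadrature error). Missing frames or markers are errors, never
interpolated. The per-leaf scalar ε̂ is the median of the final 5
frames (30 s), which suppresses tracking noise without biasing the
saturated plateau.

## Rank-based statistics

The Scheirer–Ray–Hare test replaces responses by mid-ranks over the
whole dataset, decomposes the rank sums of squares of the two-way
layout, and refers H = SS_effect / MS_total (MS_total = SS_total/(N−1))
to χ² at the effect's degrees of freedom. Balanced designs use the
closed-form cell-mean decomposition; unbalanced ones use type-II sums
of squares via an OLS fit (statsmodels). Alongside H, the ordinary
rank-ANOVA F with its denominator df is reported, because published
analyses of this design frequently state F. A constant response makes
every rank equal; the result is then flagged degenerate with H = 0,
p = 1. At 10 observations per cell the χ² referral holds the null
rejection rate of each effect at ≈ 0.044 (5000 replicates), slightly
conservative as expected for a rank χ² test at moderate N.

Pairwise Wilcoxon rank-sum tests report U of the first sample (its rank
sum minus n₁(n₁+1)/2; software conventions differ and none is canonical)
and use: the exact null when both n ≤ 12 and no ties; full permutation
enumeration when ties are present and the labeling count is ≤ 2·10⁵;
otherwise the normal approximation with tie correction and continuity
correction. Bonferroni adjustment multiplies raw p by the number of
comparisons, capped at 1. Significance bands are ns (> 0.05),
\* (≤ 0.05), ** (≤ 0.01), *** (≤ 0.001), boundaries inclusive.

Shapiro–Wilk, Levene (median-centered by default), paired/unpaired t
and Spearman correlation are thin scipy wrappers kept behind one module
surface; the paired t on identical vectors is defined as (t, p) =
(0, 1) rather than NaN.

## Morphometry

The cross-section is modelled as five concentric layers (epidermis with
bladder cells, chlorenchyma, peripheral vascular net, hydrenchyma,
central vascular strand). Layer thickness is the outer intercept minus
the intercept of the adjacent inner tissue, so thicknesses telescope to
the outer intercept along every measurement line. Terete sections are
measured along the minor/major diameters under a centro-symmetry
assumption; triquetrous sections along the three interior angle
bisectors r₁–r₃ (foot placed by the angle-bisector theorem) and a side
bisector r₄, defined here as the segment from the designated side's
midpoint along the inward normal to the far boundary — which side
carries r₄ is configurable, since the measurement protocol leaves it
open. Shrinkage of embedded sections is γ = 100·(fresh − embedded)/fresh
with the exact inverse correction 1/(1 − γ/100).

Surface-area-to-volume ratios use geometric idealizations: a cone for
(semi-)terete leaves and an irregular tetrahedron (from four vertices)
for triquetrous ones, both validated against closed forms and a
convex-hull mesh oracle rather than against any published sa/vol
figures, whose exact measurement protocol is not reproducible from
printed values.

Units: tissue-level quantities in µm, whole-leaf in mm, with explicit
converters. `CellGeometry` rejects wall thicknesses that are not small
against the cell diameter, which catches mm/µm mix-ups at the boundary.

## Biomechanics

**Elastic modulus** is the slope of the best linear region of the
pre-peak stress–strain trace: all contiguous windows covering ≥ 20 % of
the pre-peak points are scored by R², the best window wins (ties to the
longer, then earlier window), and a best R² below 0.9 is an error with
diagnostics rather than a number. The window fraction and R² threshold
are conventional choices for tensile-test analysis and are exposed as
parameters. The extraction is deterministic, idempotent and stable to
2× resampling within 0.5 %. **Tensile strength** is the maximum stress;
**Poisson's ratio** the negative slope of lateral vs. axial strain.

**Parenchyma modulus.** Hydrenchyma and chlorenchyma cannot be gripped
for tensile testing; their stiffness is derived from cell geometry and
turgor by the linear-in-turgor relation

    E = k_w · E_cw · (t_cw / d_c) + k_P · P,

a cell-wall-network term plus turgor stiffening. The classical
derivation of this relation is only cited, not printed, in the
literature this package reproduces, and was not accessible when the
package was written; the implemented form was therefore reconstructed
from its documented shape (linear in P, wall term surviving at P = 0)
with the coefficients k_w = 4 and k_P = 27/8 fixed by requiring the
relation to reproduce all four published median input→output sets
(two species × two tissues) — an overdetermined constraint (four
equations, two coefficients) that the form satisfies with margin at the
published 2-decimal precision. The tissue Poisson's ratio is validated
(0 ≤ ν ≤ 0.5) but does not enter the default coefficients: across the
published ν range (0.29–0.35) no ν-dependence is identifiable at that
precision. Both coefficients are keyword arguments, so a reader with
the original derivation at hand can substitute it directly.

**Ratio tables** divide per-species medians and round half away from
zero to two decimals, the convention consistent with every published
ratio (e.g. 0.4545 → 0.45, 0.666 → 0.67).

## Pipeline and reproducibility

Stages exchange tidy CSV under `run/<stage>/`; every output table
carries run id, seed and config hash. All randomness flows from one
seed; re-running an identical config is bit-identical for every
deterministic stage, and downstream stages can be re-run alone from
existing intermediates. The acceptance script sizes its simulations to
single-core minutes: 10 cohort seeds × 40 leaves for noisy parameter
recovery and 5000 replicates for the null calibration, which bound the
Monte-Carlo error of the reported rates at ≈ 0.003.

## Known limitations

- The synthetic cohort's plateau magnitudes are assumptions; only their
  ordering is anchored in the published findings, so cohort-level
  statistics on synthetic data demonstrate the machinery, not the
  published effect sizes.
- The species-level field results (published F statistics, thickness
  tables) depend on the original recordings and are deliberately not
  re-derived; the package validates against closed forms, enumeration
  oracles and the published worked-example values instead.
- The parenchyma-modulus coefficients are a reconstruction (above);
  they are exact at the published reporting precision but should not be
  extrapolated far outside the calibrating range of cell geometries and
  turgors.
- Per-frame midline fitting assumes all 17 markers are visible in every
  frame; occlusion handling is out of scope.
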