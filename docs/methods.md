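# Methods

This note documents the models, conventions and parameter choices behind
`soapct`, in the order data flows through the pipeline.

## Phantom model

A phantom is a rectangular soap block (default +100 HU) in air
(−1000 HU), with an air-filled wound cavity, optional metal fragments
(+3000 HU spheres) and Gaussian acquisition noise (default sd 5 HU),
sampled at voxel centers (physical position = origin + index · spacing,
0-based indices, z = block long axis = shot direction). The intensity
defaults leave wide margins on both segmentation rules: the block/cavity
threshold at half the soap intensity (+50 HU) and the metal threshold at
2000 HU.

The cavity is a surface of revolution about an axis through the center of
the entry face, tilted by `tilt_deg` in the x–z plane; its radius profile
r(d) over depth d ∈ [0, L] comes in five families:

| family | profile | emulates |
|---|---|---|
| `tumbling_spindle` | narrow channel (neck, default 4 mm) plus Gaussian bulge of radius `max_radius` at `max_depth` (default 2L/3), width L/8 | dimensionally stable bullet tumbling deep in the block (~200 mm in a full-size block) |
| `early_opening` | smoothstep rise to `max_radius` over the first quarter of L, then linear taper to 35 % | expansion triggered immediately by a tip insert |
| `tear_shaped` | r_max (t e^{1−t})^α with t = d/`max_depth` (default L/3), α = 1.5, floored at the neck | continuously expanding deforming bullets |
| `cylinder`, `ellipsoid` | analytic reference shapes | calibration tests |

All families except the ellipsoid open at the entry face with at least the
neck radius (the voxelized cavity must connect to the outside, as a real
wound channel does). The ground-truth record carries

- the analytic cavity volume π ∫ r(d)² dd (dense trapezoid on 4096
  points; exact to ~10⁻⁶ relative for these smooth profiles; the tilt is
  a rigid rotation and volume-preserving);
- the true axis unit vector and tilt;
- the maximal inscribed sphere computed from the profile: for an axis
  point at depth d₀ the nearest boundary is the entry plane (d₀), the
  exit cap (L − d₀) or the lateral surface (min over d of
  √((d−d₀)² + r(d)²)); the profiles vary slowly near their maximum
  (|r′| < 0.3), so the optimal center lies on the axis;
- fragment centers/radii and injected streak-speck positions.

Fragments are placed by rejection sampling in the soap 1–4 mm outside
the cavity surface at depths 0.25–0.95 L, pairwise separated by ≥ 3 mm;
radii default to 1.5–3 mm, so every true fragment (≥ ~14 mm³) is above
the small-fragment cut and can never be discounted by the streak rule.
Streak artifacts near fragments of radius at or above the median are
modeled as (a) six thin radial spokes of alternating ±500 HU within 5 mm
of the fragment — visible texture that stays below the metal threshold —
and (b) one or two single-voxel bright specks (+3000 HU) at 2–3.5 mm from
the fragment surface, which *do* cross the metal threshold and exercise
the exclusion rule. This is an artifact phenomenology, not a CT physics
model; no beam hardening or reconstruction is simulated.

All randomness comes from one `numpy` generator seeded by `spec.seed`;
the same spec renders a bit-identical volume.

## Segmentation

Region growing with a global intensity criterion equals keeping the
seeded connected component of the thresholded image, which is how it is
implemented. Block and cavity use 6-connectivity (compact regions);
fragments use 26-connectivity (small, possibly diagonal specks). The
interactive workflow's two inputs — the first and last cavity
slice — are accepted as parameters; omitting both switches to a fully
automatic mode that takes the largest interior air component not touching
the lateral volume boundary.

The soap intensity is estimated as the median of the upper class of a
two-class Otsu split (512 bins). If the two class medians are less than
200 HU apart the histogram is effectively unimodal (no air present) and
the overall median is returned; the air–soap separation in any real scan
is > 500 HU, so the guard only triggers on degenerate inputs.

Cavity seeds are the sub-threshold voxels of the first slice inside the
block's 2-D convex hull there; exterior air is additionally excluded by
restricting to the block's lateral bounding box. If several seeded air
components exist, the largest is kept.

The streak-exclusion rule discounts fragments of volume ≤ `small_max_mm3`
(default 8 mm³) whose surface-to-surface distance to any larger fragment
is ≤ `proximity_mm` (default 5 mm), implemented with a spacing-aware
Euclidean distance transform to the large-fragment voxels. Neither cut is
dictated by the workflow being reproduced, so both are configuration with
the defaults above and are echoed in outputs. At proximity 0 nothing is
excluded, and the counted number is non-increasing in the proximity.

## Morphometry

- **Volume** is voxel count × voxel volume (mL). No partial-volume
  correction is applied; on phantoms the voxel-center quantization errors
  largely cancel (recovery ≲ 0.3 % at 1 mm voxels).
- **Area profile** is the per-slice voxel count × in-plane voxel area
  along z, with depth measured from the first mask slice.
- **Principal axes** come from PCA (eigenvector of the covariance of the
  unweighted, spacing-scaled voxel coordinates); the sign is fixed so the
  z-component is nonnegative. If the top two eigenvalues are within a
  factor 1.2 the axis is flagged degenerate (warning) but still returned.
  The deflection angle uses |cos|, folding antiparallel eigenvectors to
  0° and bounding the angle to [0°, 90°].
- **Maximal inscribed sphere**: the Euclidean distance transform inside
  the cavity (spacing-aware) is maximized; ties break toward smallest z,
  then y, then x. Center-to-center distances track the smooth cavity
  surface well — the half-voxel digitization errors of the jagged voxel
  boundary largely cancel in the minimum over directions — but the
  candidate centers are quantized to the grid, so the maximum is refined
  on a 3-fold subsampled window around the coarse argmax, measuring from
  subvoxel candidate centers to the same coarse background-voxel centers.
  The reported radius subtracts half a voxel (the boundary lies between
  the last cavity and the first background voxel center); a single-voxel
  cavity thus reports half a voxel. Observed recovery error on phantoms
  is ≤ ~0.7 voxel. The refinement is local to the coarse argmax; a
  distant near-tie could in principle be missed by a fraction of a voxel,
  which is within the same tolerance.
- The depth of maximal damage is the sphere center's z relative to the
  first cavity slice (the entry face), in mm. For near-spherical cavities
  the distance field is almost flat in z and the depth is intrinsically
  ill-determined; the peaked families recover it to a few mm.

## Cutting-method model

Radii between delineation knots are linear (the truncated-cone
assumption) — no spline smoothing, matching the geometry the method
defines. The paired cutting-vs-CT test is a two-sided Wilcoxon
signed-rank by default (the comparison's distribution is not known to be
normal), with the paired t-test as an option. Whether delineations record
radii or diameters is accepted via a flag on CSV input. When the study
pipeline simulates the method, knots are read off the *maximal*
cross-sectional area within each 2 cm window (a delineator traces the
widest silhouette) plus 0.3 mm click noise; this reproduces the expected
direction of the method's systematic error — overestimation relative to
the voxel-wise CT volume — qualitatively, not to any particular printed
value.

## Ballistics

Deposited energy is ½ m_in v_in² − ½ m_exit v_out², masses in kg. A
multi-fragment exit is treated as a single effective exit speed (one
light-barrier measurement per shot). The grain is fixed at its exact
avoirdupois definition, 0.06479891 g. Exterior ballistics (drag,
distance-to-speed mapping) is out of scope: a test condition is simply a
bullet at an impact speed.

## Statistics

Fits of volume over energy are least squares on the basis {E} or
{E, E²} with *no intercept*: zero deposited energy produces no cavity,
and the constraint removes one degree of freedom. R² is computed against
the grand-mean baseline, 1 − RSS/Σ(y−ȳ)²; through-origin R² conventions
differ between packages and this one can be negative when the constrained
fit does worse than the mean — stated here prominently because the
choice changes numbers.

Model selection stores the plain least-squares AIC, n ln(RSS/n) + 2k
with k counting coefficients plus the noise variance, but *selects* by
the small-sample corrected AICc = AIC + 2k(k+1)/(n−k−1) by default. The
reason is quantitative: with n = 8 shots per bullet the plain-AIC
selection statistic is scale-free under a true linear law and picks the
spurious quadratic with probability P(F(1,6) > 6(e^{1/4}−1)) ≈ 0.24 at
*any* noise level, which no reasonable recovery target survives; AICc is
the standard correction in the n ≲ 40k regime and is what the
Prism-style analysis workflows this layer mirrors use. With AICc, a true
linear law is recovered in ~95 % and a convex quadratic (curvature ~50 %
of the signal at the top energy) in ~100 % of replicates. Plain-AIC
selection remains available (`criterion="aic"`). Only the Δ between the
two candidate fits is meaningful, not absolute AIC values.

ANCOVA compares slopes by the homogeneity-of-slopes F-test (full model:
per-group intercepts and slopes; reduced: common slope), one-way ANOVA
uses the classical sum-of-squares decomposition, and Tukey's HSD uses the
studentized-range distribution with Satterthwaite-free unequal-n
standard errors √(MSW/2 (1/nᵢ + 1/nⱼ)). All three are computed from the
formulas directly (scipy supplies only the reference distributions) and
are verified in the tests against statsmodels and an exhaustive
permutation oracle. The significance level defaults to α = 0.05,
configurable. Under 500-replicate null simulations both tests reject
within ±3 percentage points of α.

## Study pipeline and problem sizes

The synthetic study mirrors the factorial design (4 bullets × 4 speeds ×
2 shots = 32 blocks; speeds 600–900 m/s for ILS, 550–850 for TAG/TSX,
500–800 for NVU). Generating laws are the package's study conditions:

- volume–energy: linear 0.05 mL/J (ILS) and 0.06 mL/J (TAG); quadratic
  0.03 E + 1.0·10⁻⁵ E² (TSX) and 0.03 E + 1.1·10⁻⁵ E² (NVU), with
  multiplicative log-normal repetition noise (sd 5 %);
- exit model: exiting mass fraction scaling linearly with speed up to the
  catalogue's top-speed values (99.4 / 64.9 / 73.6 / 54.7 % for
  ILS/TAG/TSX/NVU), exit speed 0.25 v_in;
- deflection: Gaussian tilt, mean 6° (sd 0.8°) for the tumbling ILS and
  1.2–1.5° (sd 0.4–0.5°) for the others, clipped at 0;
- fragments: Poisson counts scaling with energy, expected 0 / 5 / 4 / 14
  at top energy for ILS/TAG/TSX/NVU, capped at 20 for placement. Real
  lead-core bullets shed hundreds of fragments; the study scales the
  counts down so phantoms remain geometrically placeable, which preserves
  the ordering and the count-vs-energy trends but not absolute numbers.

The per-bullet cavity family solves its `max_radius` so the analytic
volume hits the law's target (bracketed scalar solve), making measured
volume directly comparable to the generating law.

Block sizes: `PhantomSpec` defaults to a full-size 250 × 250 × 400 mm
block at 1 mm isotropic voxels; the study and the recovery suite use
110 × 110 × 280 mm blocks at 1 mm (≈ 4.3 M voxels per shot) so cavities
at realistic depths (tumbling bulge near 150–160 mm) fit while a full
32-shot study runs in about a minute per pass on one CPU. Everything is
configurable. Each shot's randomness derives from `(study seed, shot
index)`, so reports are byte-identical across re-runs of the same seed;
timings are logged but never written into reports.

## What phantom validation does and does not show

The phantoms share the segmentation thresholds' *assumptions*: binary
tissue/air rendering, no partial-volume blur at the cavity wall, no beam
hardening, cupping or scanner drift, Gaussian noise, and cavities that
are true surfaces of revolution. Passing the recovery suite therefore
demonstrates the correctness of the geometry, segmentation logic,
morphometry and statistics — not robustness to reconstruction artifacts,
to soap inhomogeneity, or to cavities with strongly non-circular cross
sections (where the cutting method's circularity assumption is exactly
the weakness the CT method addresses). Fragment *size* distributions are
likewise idealized spheres well above the exclusion cut; the rule's
behavior on borderline real fragments depends on the configured cuts.

## Known limitations

- Cavity families are surfaces of revolution; real cavities have
  elliptical sections and fissures.
- The exclusion rule is purely geometric; no metal-artifact-reduction.
- No resampling or registration: volumes are analyzed on their native
  grid, and the two compared masks must share it.
- Temporary-cavity dynamics are out of scope; only the permanent cavity
  captured by the mask is quantified.
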