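# Methods

This note documents the models implemented in `panospec`, the defaults and
their rationale, the numerical choices, and the known limitations.

## Coordinate conventions

All modules share right-handed patient-like axes: x = left–right,
y = posterior–anterior, z = inferior–superior. Voxel grids are indexed
`(i, j, k) ↔ (x, y, z)`, world coordinates are in mm at voxel centers, and
`origin` is the world position of voxel `(0, 0, 0)`. The NIfTI-1 header
stores geometry in float32; spacings and origins are rounded to 1e-6 mm on
read so written values like 0.67 mm round-trip exactly.

## Synthetic head phantom

The phantom supplies ground truth for every downstream stage. It is built
from solids whose volumes have closed forms, so voxelization can be checked
against analytic expectations:

* **head** — ellipsoid of soft tissue, default semi-axes (70, 75, 55) mm;
* **dental arch** — the symmetric quartic `y(x) = a₀ + a₂x² + a₄x⁴`
  (default 35 − 0.018·x² − 6·10⁻⁶·x⁴ over |x| ≤ 45 mm, head-centered),
  swept vertically as two bone walls of half-width 3 mm: a mandibular body
  (z ∈ [−28, −8] mm) and a maxillary body (z ∈ [8, 28] mm);
* **teeth** — 14 vertical cylinders (radius 4 mm) centered on the arch at
  equal arc-length stations, occupying the occlusal band z ∈ [−8, 8] mm
  between the two jaw walls (so tooth and wall volumes add exactly), each
  with a coaxial 1 mm-radius soft-tissue root canal;
* **air gap** — an axis-aligned air box behind the arch (40 × 12 × 16 mm)
  mimicking the pharynx / tongue–palate gap that causes the classic dark
  band in panoramic images.

HU assignments are air −1000, soft tissue 40, bone 1200, tooth 1800, with
optional Gaussian jitter (σ configurable, default 0). The wide separation
makes pure threshold segmentation exact on noise-free phantoms, which turns
segmentation into a testable oracle rather than a tuning exercise. The
default grid is 160×160×120 at 1 mm isotropic — large enough to hold the
anatomy with margin, small enough that the full pipeline runs in seconds.

The phantom emulates *structure classes* (arch, teeth, root canals, air gap),
not population anatomy: no cortical/trabecular distinction, no vertebral
column, no sinuses, no tooth-shape variation. Tests passing on the phantom
therefore validate geometry and physics plumbing, not anatomical realism or
segmentation robustness on clinical CT.

## Segmentation

Air splits off at HU < −400; bone at a blended score ≥ 300, where the score
is `(1−w)·HU + w·S` with `S` the multi-scale Hessian sheetness response and
`w` the blend weight (default 0 → pure thresholding). These are standard CT
tissue ranges and fully configurable — clinical thresholds would need tuning
per scanner/protocol. Teeth are labeled BONE: the forward model has exactly
two attenuating basis materials.

The sheetness filter responds to bright plate-like structures (cortical
shells). At each scale σ (mm, converted to voxels per axis) the Gaussian
Hessian is computed with σ² normalization; with eigenvalues sorted by
magnitude |λ₁| ≤ |λ₂| ≤ |λ₃|,

    S = |λ₃| · exp(−(|λ₂|/|λ₃|)² / (2α²))   if λ₃ < 0, else 0,   α = 0.5.

Blobs (|λ₂| ≈ |λ₃|) are suppressed; homogeneous regions give zero. The mean
HU is subtracted before filtering because scipy's truncated derivative
kernels do not sum exactly to zero — without this a constant volume picks up
a spurious response of order 10⁻⁴ × its level. The response carries HU units
(after σ² normalization), so blending with raw HU is dimensionally sane.

## Dental arch and panoramic trajectory

The occlusal plane is auto-detected as the z of maximum bone cross-section
(optionally restricted to a jaw window, or fixed by the user). Bone occupancy
in a ±12 mm slab is collapsed along z, and the even quartic is fitted by
least squares about the bone center of mass in x.

The fit uses the per-column **bone centroid** in y, not the anterior-most
bone voxel. The anterior edge sits one wall half-width (+ tooth radius at the
crowns) buccal of the true arch curve, a systematic ~3–4 mm bias; the
centroid of the (symmetric) wall cross-section is unbiased. On the default
phantom the fitted curve is within 0.7 mm RMS of the generating quartic over
the tooth-bearing span.

The trajectory places C equally spaced arc-length stations on the fitted
curve. Per station the central ray runs along the outward arch normal — the
normal is evaluated analytically from the quartic derivative, so
central-ray ⊥ tangent holds to machine precision — with the source
400 mm behind the arch point (lingual side) and the detector column 100 mm
in front (buccal side). Rows form a vertical fan from the source through R
detector pixels centered on the arch plane; the default row pitch spans a
120 mm vertical field at the arch (magnification d_sd/d_sa = 1.25). Defaults
C=700, R=500 give a plausible panoramic scale and are fully configurable.

This focal layer is sharp exactly on the arch curve. A real
orthopantomograph's moving rotation center, focal-trough depth blur and
vendor kinematics are deliberately not modeled: the normal-ray sweep
reproduces the projected-thickness semantics of the panoramic layer, which is
what the spectral synthesis consumes.

## Forward projection

Material thickness images are exact line integrals of the label indicator
functions. Because labels are piecewise constant on voxels, an
Amanatides-Woo / Siddon traversal that accumulates the chord length spent in
each crossed voxel is *exact* — no step-size or interpolation error — and all
three materials are accumulated in one numba-compiled pass. Consequences used
as tests: per-pixel `t_AIR + t_SOFT + t_BONE` equals the ray's chord through
the grid bounding box; projection is additive over disjoint masks; rays that
miss the grid give 0 (not NaN). Entry points are nudged by 10⁻⁹ of the chord
to avoid landing exactly on voxel faces; boundary-tie attribution is
therefore well defined and the error bounded by that nudge.

## Spectral model

**μ(E) tables.** Embedded mass-attenuation node values for ICRU-44 soft
tissue and cortical bone compositions (and aluminium for filtration) at
20–150 keV, multiplied by nominal densities 1.06, 1.92, 2.699 g/cm³, with
log–log interpolation (exact at nodes). The basis materials of any published
study are not reprinted here; users needing a specific table can substitute
one.

**Tube spectrum.** Kramers bremsstrahlung `(kvp − E)/E` on bin centers,
attenuated by the configured aluminium filtration (default 2.5 mm), clipped
above the tube voltage and renormalized; defaults 120 kVp, 64 bins on
[20, kvp] keV. Characteristic tungsten lines and anode self-filtration are
not modeled; `Spectrum.from_csv` loads a measured spectrum instead. A
single-bin spectrum degenerates to monoenergetic, which makes the
Beer–Lambert/PVMI identity `−ln(N/N₀) = A` an exact test.

**PAN display.** The attenuation view `−ln(N/N₀)` is the default display
(dense structures bright, as in radiographs); raw expected counts are always
retained. N₀ defaults to 10⁵ expected photons per pixel; no Poisson sampling
is added (ideal detector).

**Decomposition.** `recover_thickness` inverts two PVMIs through the 2×2
system `[[μ_b(E_A), μ_s(E_A)], [μ_b(E_B), μ_s(E_B)]]`; it is the algebraic
consistency inverse of the PVMI synthesis (round-trip exact to solver
precision) and can return negative values on inputs that did not come from
non-negative thicknesses.

## Reader-study statistics

Scores are ordinal 1–5 per (reader, case, modality, criterion); the five
criteria are bone-structure image quality, visualization of diagnostic
details, artefacts, overall image quality, and diagnostic acceptability.
Aggregation reports per-reader mean ± SD per (modality, criterion), the
across-reader average (unweighted mean of reader means — readers score equal
case counts), and per-modality total points (sum of all reader means across
criteria, out of 5 × criteria × readers).

The paired Wilcoxon signed-rank test drops zero differences (the classical
convention, also the default of mainstream statistical software), assigns
mid-ranks to tied |d|, and reports W = min(W⁺, W⁻) with a two-sided p-value.
For n ≤ 15 the p-value is exact, by enumerating all 2ⁿ sign assignments
conditionally on the observed mid-ranks — enumeration over doubled ranks via
convolution, so tied |d| are handled exactly. For larger n the normal
approximation with tie correction (−Σ(t³−t)/48 in the variance) and a 0.5
continuity correction is used. Significance is judged two-sided at α = 0.05;
no multiplicity correction is applied by default (a Holm/Bonferroni switch
exists) since each comparison is reported descriptively alongside its raw p.

A score-table simulator draws baseline scores from a configurable categorical
distribution and couples shifted modalities as `clip(baseline + shift, 1, 5)`,
which forces a known sign on every nonzero difference — the end-to-end test
that every +1-shifted comparison is significant with positive direction.

Raw per-case scores of published reader studies are generally not available;
what can be recomputed from a printed summary table is the aggregation
arithmetic. With 17 cases per reader, printed per-reader means are multiples
of 1/17, so integer score vectors reproducing them exist; the acceptance
script reconstructs such vectors and recomputes the across-reader average
column through `aggregate_scores`.

## Problem sizes and determinism

Default test/acceptance sizes: phantom 160×160×120 @ 1 mm (coarse 80×80×60
@ 2 mm where only structure matters), panoramic geometry 700×500 (reduced for
oracle-by-oracle checks), 50–120 random rays for projector oracles, n ≤ 12
for enumeration cross-checks. All randomness flows through
`numpy.random.default_rng` seeds; identical parameters (including seed) give
bit-identical phantoms and images.

## Known limitations

* No scatter, detector noise, energy-bin response, focal-spot penumbra, or
  dose modeling — the simulation targets ideal-detector image formation.
* The phantom's anatomy is schematic; segmentation robustness on clinical CT
  (metal, motion, low dose) is untested and out of scope.
* The arch trajectory is a normal-ray sweep, not vendor orthopantomograph
  kinematics; absolute panoramic distortion patterns will differ.
* μ tables are 8-node log–log interpolants; sub-percent accuracy between
  nodes is adequate for image synthesis but not for dosimetry.
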