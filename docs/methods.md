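# Methods

This note records the modelling and numerical choices behind `subshape`,
in enough detail to re-derive every default. Units are millimetres (mm),
mm² and mm³ throughout; intracranial volume (ICV) is in mm³.

## Surfaces and discrete geometry (`mesh.py`)

Structures are closed, oriented, genus-0 triangle meshes. `validate()`
checks Euler characteristic V − E + F = 2, edge-manifoldness (every edge
in exactly two faces), consistent winding, and outward orientation
(positive signed volume).

- **Enclosed volume** — divergence theorem: V = Σ_f det(v₀, v₁, v₂)/6
  over faces.
- **Vertex areas** — barycentric: one third of the incident face areas.
  These areas are strictly positive on a valid mesh and sum to the total
  surface area, which makes the logJD conservation law below exact.
- **Mean curvature** — the Meyer cotangent discretization with mixed
  Voronoi areas: H_i = ‖K_i‖/2 where K_i is the discrete
  Laplace–Beltrami applied to the coordinates, signed by the outward
  normal. On a unit icosphere with 2562 vertices this is within 5% of
  the closed form 1/r, and it obeys the 1/r scaling law.

File I/O covers ASCII PLY, OBJ and legacy VTK (hand-rolled writers and
readers, so overlays can carry named per-vertex scalar fields; the VTK
dialect is POLYDATA + POINT_DATA).

## Shape descriptors (`features.py`)

**Medial curve.** The mesh is sliced by `n_sections` (default 12) planes
orthogonal to its first principal axis; the medial point of each slice
is the length-weighted centroid of the cross-section boundary, and a
cubic spline through the ordered centroids is sampled densely. The curve
is rigid-equivariant by construction (slicing commutes with rotation).
This works well for the elongated, gently curved templates used here;
strongly C-shaped structures would need a true skeletonization.

**Atlas-side medial curve with similarity transport.** In cohort
analysis the medial curve is *not* re-skeletonized per subject.
Skeletonizing each subject individually lets the curve chase focal
deformations — a dent pulls the centroids toward itself, which partially
cancels the very thickness change one is trying to measure (in
simulation this cut patch sensitivity by a factor of ~5). Instead the
template is skeletonized once, and the curve is carried to each subject
by the least-squares similarity transform (Kabsch rotation + isotropic
scale + translation) fitted over all corresponded vertices
(`transport_curve`). A global similarity fit is insensitive to focal
effects, so subject-level pose and size are absorbed while local
anatomy is preserved as signal.

**Radial distance (RD).** RD_i is the Euclidean distance from vertex i
to the nearest sample of the (transported) medial curve — a local
thickness proxy. Vertices that fall exactly on the curve are floored at
1e-9 mm with a warning. Closed forms: a sphere against a degenerate
centre-point curve gives RD = r to 1e-6; cylinder-wall vertices against
the axis give RD = ρ to 2%.

**Log-Jacobian (logJD).** With corresponded meshes,
logJD_i = log(area_subject(i)/area_template(i)) using barycentric
vertex areas. Identity map gives 0, uniform scaling by s gives exactly
2·log s, and Σ_i area_template(i)·exp(logJD_i) equals the subject
surface area identically.

## Synthetic cohorts (`synthetic.py`)

**Templates.** 14 bilateral shape structures (ellipsoids and bent tubes
at icosphere resolution 3, 642 vertices) plus 4 volume-only midline
structures (corpus callosum, lateral and third ventricles). Right-side
templates are mirror images of the left with orientation restored.
Template volumes match typical adult subcortical volumes within 5%.

**Covariates.** Marginals mimic an HIV case-control study: cases n=63
(age ≈ 64.7 ± 4 y), controls n=31; binary covariates (sex, viral
detectability, HAND status) are drawn as *exact counts* — e.g. exactly
2 of 63 cases are female — rather than independent Bernoulli draws, so
small-sample marginals match the design. Disease-specific fields (nadir
CD4, time since diagnosis, viral load) are NaN for controls and
truncated at zero for cases. ICV is normal around 1.4e6 mm³.

**Subject generation.** Each subject's template is scaled by
(ICV/ICV_ref)^{1/3} (isotropic head-size scaling), then perturbed by
smooth noise: i.i.d. normal displacements along vertex normals
(sd 0.5 mm), graph-smoothed for 10 averaging iterations. Seeds derive
from `SeedSequence([seed, stream, subject, structure])`, so every
subject×structure is independently reproducible.

**Implanted effects.** `EffectSpec(structure, amplitude, ...)` supports
two types, both multiplied by the subject's predictor value (default
`HIVStatus`, so controls are untouched):

- *volume*: the whole structure scales by (1 + amplitude)^{1/3}.
- *thickness*: vertices inside a geodesic patch move along template
  normals by amplitude × RD_template × w, where the window w is 1 inside
  0.6 × radius (plateau) and falls to 0 at the radius with a cosine
  taper. The `window > 0` vertex mask is stored as ground truth.
  `suggest_patch_center` returns the template's thickest vertex
  (argmax RD), the canonical placement: a percent-of-thickness effect is
  only detectable where there is thickness to lose.

Note a geometric attenuation: displacement is along the *normal*, while
RD is measured toward the medial curve, so the measured RD change is
roughly cos(normal, radial) ≈ 0.7 of the nominal amplitude × RD. This is
deliberate (the generator perturbs geometry, not the measurement).

`default_effect_menu()` holds the default group-difference volume
effects: corpus callosum −10.7%, left pallidum −7.6%, left putamen
−5.7%, thalami −5.9/−6.3%, and ventricular enlargements +12.7/+8.0/+15.5%.

## Vertex-wise GLM and FDR (`glm.py`)

Each outcome (per-vertex RD, per-vertex logJD, or structure volume) is
regressed by OLS on the tested predictor plus age, sex and ICV, with an
intercept; cognitive predictors add the group main effect and an
interaction term, and disease-marker models are fitted in cases only.
Missing covariates/outcomes are dropped listwise; rank-deficient designs
raise with the offending column named. The solver is validated against a
normal-equations oracle to 1e-8 relative and recovers noiseless
coefficients to 1e-9.

Multiplicity is controlled with Benjamini–Hochberg step-up FDR at
q = 0.05, applied *per family*: each surface × measure (e.g. left
thalamus RD, 642 tests) is its own family, and all structure volumes are
pooled into one family. q-values are the standard monotone
min_{j≥i} m·p_(j)/j. Volume effects are reported as percent difference,
100·β / (adjusted control mean), where the adjusted control mean is the
model prediction at the fitted sample's covariate means with the tested
predictor at its control level.

On 20 effect-free simulated cohorts the mean per-family false-rejection
proportion is ≈ 2e-4, well under q = 0.05. With the −8% thalamic patch
and −10.7% callosal deficit at n = 63 + 31, median patch-vertex
sensitivity is ≈ 0.60 and the volume effect is recovered with correct
sign and q < 0.05 in 20/20 cohorts.

## Random forest (`forest.py`)

Implemented from first principles:

- **Gini impurity** Σ_c p_c(1−p_c); split gain is the impurity decrease
  weighted by child sizes. Child impurities are computed as 1 − Σp²
  from prefix counts (vectorized over candidate thresholds, which are
  midpoints between consecutive distinct sorted values). Ties break
  toward the lower feature index, then the lower threshold; both the
  split and the resulting single-tree importances match exhaustive
  brute-force enumeration exactly.
- **Trees** are unpruned CART grown to purity; `mtry` features (default
  ⌊√P⌋) are drawn without replacement at every node; leaf ties go to the
  lower class label.
- **Forests** (default 5000 trees) train each tree on a bootstrap sample
  of n rows with replacement (≈ 63.4% unique rows, checked empirically);
  scores are the fraction of trees voting class 1.
- **Importance** is the per-feature Gini gain summed over all nodes of
  all trees, divided by the tree count; per-vertex importances map back
  onto template surfaces as overlays.
- **Evaluation**: AUC by the Mann–Whitney rank formula (ties counted
  half); significance from a permutation null that shuffles held-out
  labels over the fixed score vector, p = #(null > observed)/B with
  B = 1000 by default (a smoothed (k+1)/(B+1) variant is available).
  Validation schemes: class-stratified 2-fold (train on one half, score
  the held-out half; odd counts give training the extra subject) and
  leave-one-out (one aggregated AUC over all held-out scores). Under
  the null the permutation p-values are uniform (KS-checked) and
  held-out AUC concentrates around 0.5; with a d ≈ 1.2 patch on 10% of
  one structure's vertices at n = 60, AUC ≳ 0.95 and the top-5%
  importance vertices overlap the true patch with Dice ≈ 0.6.

## Spherical registration (`register.py`)

For subjects without shared vertex indexing, correspondence is estimated
on the unit sphere:

1. **Spherical map** — centred radial projection (exact for star-shaped
   surfaces), followed by tangential-smoothing/reprojection passes until
   no spherical triangle is flipped (bijectivity is asserted).
2. **Rigid alignment** — the rotation maximizing the correlation of
   mean-curvature maps resampled on a shared icosphere grid. Raw
   curvature maps can have a correlation peak only ~10° wide, so the
   search is hierarchical: both maps are graph-smoothed (20 averaging
   iterations, widening the basin to ~45°), a fixed deterministic set of
   1200 coarse rotations is scored, Nelder–Mead refinement runs from the
   top 8 candidates, and the winner is refined through a smoothing
   pyramid (20 → 5 → 0 iterations), each stage accepted only if it does
   not worsen that stage's objective. Known rotations of smooth
   synthetic subjects are recovered well within 5° (typically < 0.5°).
   With constant curvature every rotation is optimal and the identity is
   returned deterministically.
3. **Demons refinement** — a curvature-driven tangential displacement
   field, graph-smoothed each iteration and reprojected to the sphere,
   with step halving whenever an update would flip a spherical triangle
   or increase the RMS curvature mismatch (the mismatch history is
   non-increasing by construction; an unresolvable flip sets a warning
   flag and stops).

The final correspondence samples the subject surface (barycentric
interpolation on the spherical triangulation) at the warped template
parameter locations. RD computed from estimated correspondence
correlates ≥ 0.9 with given-correspondence RD on smooth synthetics.

## Pipeline (`pipeline.py`, `cli.py`)

Stages `simulate → extract → stats → classify` each read only the
previous stage's persisted outputs inside the work directory and write
their own outputs plus a manifest entry. The manifest records a SHA-256
checksum of every output file (excluding the manifest itself and the
run log, which carry timestamps), so identical config + seed give
byte-identical checksums — verified end to end. Configs are YAML or
JSON, validated against a closed schema (unknown fields are named in the
error).

## Limitations

- The generator's templates are idealized ellipsoids/tubes; the medial
  curve construction assumes a dominant principal axis and would
  misorder sections on strongly C-shaped anatomy.
- Thickness effects displace along normals, so measured RD change is
  attenuated by the normal/radial angle (≈ 0.7 on the thalamus
  template); amplitudes are nominal, not calibrated to measured RD.
- The spherical registration is a deliberately lightweight stand-in for
  full curvature + medial registration frameworks: single-channel
  (mean curvature), rotation-only rigid stage, and a first-order demons
  loop. It is validated on smooth synthetics, not real segmentations.
- Classifier feature vectors concatenate raw per-vertex features; no
  spatial regularization or feature selection is applied beyond the
  forest's own randomization.
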