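# Methods

This note records the models implemented in `dinomorph`, the assumptions
behind them, the defaults that matter, and what the synthetic test data can
and cannot demonstrate.

## Coordinate and unit conventions

Right-handed frame, +x cranial, +y dorsal, +z right-lateral; origin at the
right hip joint centre.  All lengths in metres, masses in kilograms,
densities in kg m⁻³.  Meshes are ASCII OBJ/PLY in metres.

## Polyhedral mass properties

Volume, COM and inertia of a closed triangle mesh are accumulated over
signed tetrahedra spanned by each face and the origin (divergence theorem).
For a watertight, consistently wound polyhedron the result is exact; there
is no voxel or quadrature error.  Watertightness is checked on vertex
indices (every directed edge matched by exactly one reverse edge), because
the lofting stage always emits indexed closed meshes; meshes from other
sources must be welded before validation.  Faces below 1e−12 m² are dropped
with a warning (loft caps can emit slivers).  Point containment, used for
cavity checks and the voxel test oracle, is a generalized winding number
(summed solid angles), which is robust where ray casting can graze edges.

Composites sum masses and volumes, mass-weight the COM (zero-mass air
spaces contribute volume only) and combine inertia via the parallel-axis
theorem.  Segments with internal cavities keep their external volume, so
mass/volume is the bulk density — the quantity compared across
reconstructions.

## Hoops and lofting

A hoop is an elliptical (two semi-axes) or octagonal (eight radii, dorsal
first, proceeding right-lateral) cross-section at a station along a segment
axis.  Between hoops the surface is ruled (linear interpolation): with
sparse, manually placed sections, a spline would invent curvature the data
do not constrain.  End caps are centroid fans, guaranteeing watertightness.

Rings are discretized **area-preservingly**: the profile is sampled at
`ring_n` angles (default 32) and the sampled radii are inflated by
√(true area / polygon area), so every ring polygon carries exactly the
profile's cross-sectional area.  Consequences worth knowing:

- lofted cylinders, cones/frusta and octagonal prisms match their
  closed-form volumes to machine precision at any ring resolution
  (for octagons the 32-point ring includes the 8 control vertices and the
  correction factor is exactly 1);
- between hoops whose profiles are *similar* (proportional radii) the loft
  is an oblique pyramidal frustum and its volume is exactly
  (h/3)(A₀ + A₁ + √(A₀A₁)) — this is the analytic ground truth the
  synthetic bodies are tested against;
- shape-dependent quantities (COM off-axis, inertia) still converge at
  O(ring_n⁻²) or better.

Hoop fitting takes the per-direction outermost bone points of a section:
each octagon radius starts at the largest extreme distance assigned to its
direction, then edges are inflated minimally until every section point is
contained (verified against the exact polygon with shapely).  An
`offset_fraction` then scales all radii by (1 + offset); 0 is bone-hugging.
The synthetic initial ("preferred") torso uses offset 0.15, a mid-range
flesh allowance between the tight minimal fit and the ×1.2 maximal rule.

## Sensitivity variants

Per-segment rules, applied to hoop radii only (stations, centres and hence
all lengths are bit-identical across variants):

| variant | neck/tail/hindlimb | torso | head, forelimb | airspaces |
|---|---|---|---|---|
| minimal | ×0.80 then diagonal ×0.853 | refit tight to bone (+ diamond) | unchanged | largest (×1.2) |
| maximal | ×1.2 | ×1.2 | unchanged | smallest (×0.8) |

The four COM-extreme models compose these: most-cranial = maximal
neck+torso with minimal tail+hindlimbs; most-caudal the reverse;
most-dorsal = maximal axial segments with minimal hindlimbs; most-ventral
the reverse.  Each composed segment inherits the airspace treatment of the
rule it takes.  Head and forelimb are never varied (well-constrained by
landmarks; negligible mass, respectively).

Two genuinely open readings were decided as follows.  Diamondization in
the minimal model is applied to the torso hoops as well as to
neck/limbs/tail (switchable via `VariantSpec.diamondize_torso`); and
"largest/smallest airspaces" reuse the flesh radial factors ×1.2/×0.8,
the least arbitrary symmetric treatment since no separate airspace factors
are stated anywhere.

Mechanically applied, these rules fix every varied segment's max/min volume
ratio at 1.44/0.64 = 2.25 (2.64 with diamondization).  Published per-segment
ratios from comparable studies scatter more widely (≈1.4–3.0), reflecting
manual per-hoop editing; whole-body max/min ratios near 1.9 therefore
cannot emerge from the uniform rules, and the package asserts the exact
mechanical factors rather than any whole-body ratio band.

## Segment roster and the bilateral convention

The roster is head, neck, body (torso), tail, forelimb, thigh, shank,
foot.  Whole-body mass is the sum of these eight entries, each counted
once — the convention under which published segment tables sum exactly to
their published whole-body masses, and under which one femur volume is
subtracted from the tabulated thigh mass in the extensor method.  In the
synthetic bodies the limb segments are accordingly placed in the
midsagittal plane as merged bilateral units; a consequence is that the COM
lies exactly on z = 0 for these symmetric bodies.

## Muscle reconstruction

**CFL.**  For each caudal vertebra from the sacrum to the tail's transition
point, the muscle boundary loop runs from the lateral tip of the transverse
process along the smooth outer contour to the ventral tip of the chevron,
then back along the chevron, centrum-ventral and centrum-lateral bone
borders.  The "smooth curve" is a periodic cubic spline through the ordered
landmark points (chord-length parametrized): it passes *through* the
transverse-process tip, so the small volume immediately below the tip is
included rather than truncated, and the region dorsolateral to the
centrum-lateral border (M. caudofemoralis brevis territory) is left
unfilled and is not reconstructed.  Loops are resampled to a common point
count, lofted, capped and integrated at a configurable density (default
1000 kg m⁻³, the homogeneous model density; mass is linear in density, so
a muscle-tissue value of 1060 is a pure rescale).  The tendon to the
femur's fourth trochanter is a thin tube (default radius 1% of the
proximal loop's mean radius) whose small volume is reported separately.

**Extensor coefficients.**  Bone volumes are subtracted from segment masses
at the homogeneous model density of 1000 kg m⁻³ — the only convention
internally consistent with the homogeneous segment masses — and the
non-bony remainder is multiplied by dissection-derived fractions: hip 0.54
(plus the CFL mass), knee 0.34, ankle 0.47.  These fractions assume
extensor muscle is a constant share of non-bone segment mass across
saurians; the method is deliberately generous (all non-bone volume is
treated as potential muscle), so results are upper-end estimates.

## Growth model

mass(age) = max_mass / (1 + e^{a(age−b)}) + 5, with the 5 kg hatchling
mass anchoring age 0 and the asymptote fixed at the apex specimen's mass
(9502 kg for the packaged dataset — the apex individual's minimal-model
mass, imposed rather than fitted, following the DME protocol).  Only
(a, b) are estimated.  The printed form of this equation is typographically
ambiguous about the denominator grouping; the implemented reading
1 + e^{a(age−b)} is the only one under which b is the age at 50% of
maximum mass, which is how b is defined.

Least squares uses a deterministic multi-start grid (a ∈ [−2, −0.01] × 40,
b ∈ [1, 30] × 59) with Levenberg–Marquardt refinement from the best nodes:
five-point datasets are multimodal-prone and a fixed start set makes the
fit reproducible; the grid SSR is monotone non-increasing under refinement.
a is unconstrained in the refinement (growth corresponds to a < 0; |a| is
reported alongside).  Standard errors and pointwise confidence bands come
from the delta method, s²(JᵀJ)⁻¹ with t quantiles on n−2 degrees of
freedom; on n = 8 the 95% band's empirical coverage is ≈0.93 (delta-method
bands are mildly anti-conservative at these sample sizes).

Model comparison: common fit (k = 2) on the pooled series vs separate fits
(k = 4), AICc = n·ln(SS/n) + 2k + 2k(k+1)/(n−k−1) on pooled n with Akaike
weights, and F = ((SS_c − SS_s)/2)/(SS_s/(n−4)).  A perfect fit (SS = 0)
is floored at 1e−12 inside the log; identical series give F = 0 and a
common-model preference by penalty alone.

DME: mass_i = apex_mass × (FL_i / FL_apex)³, scale-equivariant in FL.

**External ages.**  The packaged growth dataset prints ages only for the
juvenile (12 yr) and one adult (14 or 16 yr, two published alternatives).
Ages for the remaining three adults ship in
`data/trex_growth_ages_external.csv`, clearly labelled as external
estimates (one from independent histology literature, two approximate).
Any quantity derived from that file — notably the headline peak growth
rate — is an optional, flagged check, not a validated reproduction, and no
test asserts its value.

## Synthetic data: what it shows and what it does not

The generators define the package's study conditions:

- **Skeletons** are unions of cylinders/frusta with proportional octagonal
  section tapers, so every bone, segment and muscle-territory volume has a
  closed form, and all oracles are analytic.  The tyrannosaur preset uses
  femur 1.28 m, body length 11.8 m, GAD 2.5 m, leg length 3.07 m, tail
  6.8 m — adult-grade proportions — and air cavities sized so the minimal
  model's cavity fraction is ~14% of body volume, the middle of the
  plausible 11–16% range for archosaur reconstructions (its bulk density
  then falls in the expected 840–890 kg m⁻³ band; the maximal model lands
  near 970).  The crocodile preset has a long shallow tail with small
  process spans for the muscle-validation harness.
- **Caudal landmarks** are placed on per-vertebra circles of tapering
  radius: a deliberate abstraction that makes the true muscle territory a
  circular frustum stack.  The landmark reconstruction recovers it within
  ~1–2%, and the validation test requires ≤5%.
- **Growth series** are the sigmoid plus seeded Gaussian noise
  (σ = 200 kg, n = 8 in the recovery simulations; 50 seeds; the median
  recovered half-max age must land within ±0.5 yr of truth).

Passing these tests demonstrates the *machinery* — exact geometry, correct
rule application, statistical behaviour under known truth.  It does not
demonstrate anatomical fidelity: real vertebrae are not circles, real
section tapers are not proportional, scan meshes carry distortion,
mounting errors and investigator bias that the synthetic bodies have no
analogue for.  Absolute specimen masses therefore cannot be reproduced
here; the printed-table fixtures carry those, and the package reproduces
every derived (arithmetic) cell of them.

## Numerical choices and degenerate inputs

- Watertightness by index matching; winding errors surface as
  `OrientationError` (non-positive signed volume).
- Hoop fitting needs ≥3 non-collinear section points; containment
  inflation iterates at most ~200 × 0.2% steps.
- Loft self-intersection is diagnosed (non-monotone ring-centroid advance)
  as a warning, not an error.
- Ties in the multi-start growth fit break by grid order (first best node
  wins); SSR improvements below 1e−12 are ignored.
- Fixture errata (a printed average that is not the mean of its printed
  bounds; a printed maximal CFL mass inconsistent with its own scaling
  recipe) are packaged bit-for-bit with flags, never silently corrected.

## Known limitations

- No boolean mesh operations: disjoint-union composition only; overlapping
  synthetic segments would double-count volume (the packaged bodies avoid
  overlap where exactness is asserted).
- Single homogeneous density per mesh; no density fields.
- The CFL loop's mediolateral extent between named landmarks is governed by
  spline curvature, not by muscle scarring or fascial evidence.
- Delta-method confidence bands understate uncertainty slightly at n ≤ 8.
- The CLI's model cards cover axis-aligned segment axes (+x and −y), which
  is sufficient for the packaged reconstructions but not for arbitrarily
  posed skeletons.
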