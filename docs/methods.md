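# Methods

`flapmetrics` estimates the outer-surface area of a skull flap removed at
decompressive craniectomy (DC) from volumetric binary bone masks, and
quantifies how well three estimators of that area agree.  This note records
the models, the numerical choices, and what the synthetic phantoms do and do
not demonstrate about real CT data.

## The measurement problem

A craniectomy removes a roughly rectangular, curved plate of bone.  Its
clinically relevant size is the area of the plate's *outer table* (the
external cortical surface).  Given a pre-operative and a post-operative CT,
the flap can be reconstructed digitally as the bone present before surgery
and absent after it, once the two scans are rigidly aligned:

    flap = pre_bone ∧ ¬ T̂(post_bone),   T̂ = argmax overlap(pre, T(post)).

Three estimators of the outer area are then compared:

- **Marching cubes (Sm).**  Triangulate the flap's boundary surface, keep
  triangles whose normals point away from the image centre (the outer face),
  sum their areas.
- **Quasi-Monte Carlo Crofton (Sq).**  Enclose the flap in a ball of known
  surface area S_b; sample lines uniformly under the rigid-motion-invariant
  (kinematic) line measure from a 4-D Sobol sequence; count flap-boundary
  crossings n and ball crossings n_b = 2 × n_lines; the total boundary area
  is S = (n/n_b)·S_b, and the outer estimate is S/2 because a plate has two
  faces.
- **AC product (Sac).**  The bedside method: greatest axial defect length A
  (between the outer-table corners, on the widest axial slice) times the
  craniectomy height C (number of axial slices showing a full-thickness
  defect × slice spacing).

Agreement over a cohort is summarized by pairwise RMSD, Pearson r,
Bland–Altman bias with 95% limits of agreement, mean percentage deviation,
and paired t-tests.  The bias ± 1.96·sd band is labelled *limits of
agreement*: it bounds individual between-method differences, not the
uncertainty of the mean difference.

## One boundary surface for both digital estimators

Both digital methods need a boundary surface for a binary voxel mask, and a
naive choice is badly biased: the raw voxel-union (staircase) surface of a
digitized ball has ~1.5× the ball's area, and Crofton line counting against
a nearest-voxel lookup measures exactly that staircase (+41% on an r = 30 mm
ball at 1 mm voxels); meshing a signed-distance field still retains the
beveled staircase (+8.9%).

Both estimators therefore share one boundary definition: the **0.5 level set
of the Gaussian-smoothed binary mask**, with σ = 1 voxel per axis.  A flat
interface is recovered exactly (the blur is symmetric across it), and the
residual bias is a curvature term O(σ²κ) plus edge rounding O(σ) along sharp
rims.  The mesh method triangulates this level set with marching cubes; the
Crofton method marches each chord at half the smallest voxel spacing and
counts crossings of the same level by trilinear interpolation.  Measured on
the digitized r = 30 mm ball: mesh +0.035%, Crofton +0.005% (20 000 lines).
Objects thin enough to blur away entirely (e.g. a single voxel) are handled
by refining the grid 2× per axis — which leaves the occupied region
unchanged but shrinks the blur with the voxel — until the level set exists.

Numerical details:

- Mesh orientation is fixed globally by requiring positive signed volume;
  triangles with normal·(centroid − centre) strictly positive are kept,
  zero-dot (and degenerate) triangles excluded.  The "image centre" is the
  pre-operative skull centroid by default; boundary-touching masks are
  rejected rather than repaired.
- The line sampler maps Sobol points (u₁…u₄) to a direction via the
  area-preserving cylinder map (z = 2u₁ − 1, azimuth 2πu₂) and an offset in
  the perpendicular disk at radius R√u₃, angle 2πu₄ — the invariant measure
  on lines meeting the ball, so crossing counts are unbiased for the Crofton
  identity.  The sequence skips its all-zeros first point; distinct skips
  give replicate line sets.  Every chord pierces the ball at exactly two
  points, so n_b = 2·n_lines holds by construction.
- The enclosing ball is centred on the flap bounding box with radius
  1.05 × (farthest voxel centre + half voxel diagonal).

Both digital estimators inherit one acknowledged bias: for a plate of
thickness t and perimeter P, the rim contributes ~P·t/2 to the outer
estimate (the mesh keeps roughly half the rim triangles; halving the Crofton
total assigns half the rim to each face), partially offset by the inner face
being smaller than the outer by ~2t/R.  The relative error is ~t/r_patch,
negligible for large flaps and worst for small ones — which is why small
craniectomies are measured less accurately by either digital method, and why
oracle validation (below) uses a thin-walled phantom.

## Registration

Registration is mask-overlap based (binary phantoms and thresholded bone
masks carry no useful intensities): negative **normalized** cross-correlation
of Gaussian-smoothed masks, optimized by Powell over a coarse-to-fine
pyramid (4 mm, 2 mm, plus a full-resolution polish for grids up to 4M
voxels), bounded to ±25° / ±25 mm.  Three choices matter and were each
forced by a failure mode:

1. **Normalization.**  Trilinear resampling blurs the moving image for any
   off-grid transform; a raw inner product therefore rewards the blur-free
   identity over genuinely better alignments.  Dividing by the resampled
   field's norm removes that artifact.
2. **Translation-only pre-alignment** (heavy 3-voxel smoothing): the missing
   flap displaces the post-operative centroid by up to ~1 cm, so a centroid
   initialization alone can start outside the rotation basin.
3. **A coarse 3°-step rotation scan** (±12° per axis): a thin shell
   decorrelates within a few degrees of rotation, so the basin is too narrow
   for a purely local optimizer to find from a cold start.

Subtraction is pre ∧ ¬post followed by cleanup standing in for the manual
slice-by-slice review: when the aligned post mask was actually resampled, a
single binary opening strips the one-voxel sheets that sub-voxel residue
leaves along the skull surface (they attach to the flap and stretch its
measured extent); 26-connected components under 0.5 cm³ are then dropped.

## The AC measurement

A is automated as the maximum pairwise in-plane distance among the radially
outermost flap voxels (one per 0.5° angular bin around the skull centroid)
over axial slices — the automated surrogate for "between the corners of the
outer table".  C counts slices in which some angular sector of the
pre-operative bone annulus is entirely inside the flap, i.e. the defect goes
through the full skull thickness there, and multiplies by the slice spacing.

On an idealized spherical skull the continuum AC product satisfies
A·C / S_patch = sin(θ)·sinφ* / θ for a patch of azimuthal half-angle θ whose
widest ring has polar angle φ*: a pure deficit that reaches 15% at θ ≈ 0.96
rad.  The AC method is thus meaningful only for moderately curved defects —
consistent with its clinical use on the relatively flat lateral skull — and
the phantom cohort's sampler keeps θ ≤ 0.8.

## Phantoms

The phantom skull is a spherical shell digitized by the voxel-centre rule,
with a full-thickness angular patch (azimuth 2θ, polar band [lo, hi])
removed; the patch's outer area R²·2θ·(cos lo − cos hi) is the exact ground
truth every estimator is validated against.  Three optional skull-base bumps
(mastoid/occipital stand-ins, differing in position and size) break the
sphere's rotational symmetry: without them a pose between two scans is
fundamentally unrecoverable from bone overlap.  Misaligned post-operative
masks are digitized from the rigidly moved analytic geometry — a genuine
second acquisition in a new head pose, not a resampled copy.

Phantom configurations (fixed by design, with the grid sizes chosen so the
full suite runs comfortably on one CPU):

| purpose                  | R (mm) | wall (mm) | spacing (mm)  | fiducials |
|--------------------------|--------|-----------|---------------|-----------|
| digital-estimator oracle | 80     | 1.0       | 0.5 iso       | none      |
| AC / cohort (clinical)   | 110    | 10        | 1.5×1.5×5     | cohort only |
| extraction pairs         | 80     | 6         | 1.0 iso       | 8 mm      |

Rationale: the oracle shell is thin so the rim term — a bias of the method,
not of the implementation — stays within the validation tolerance at the
small-area end (1 mm is the watertightness floor of twice the spacing); the
clinical shell uses 5 mm axial slices (typical head CT) with the wall at the
corresponding watertightness floor, and R = 110 mm approximates the flatter
lateral skull over which real flaps of up to ~200 cm² span only moderate
angles; cohort ground-truth areas are drawn uniformly over the configured
range (default 9.46–205.32 cm²) and realized exactly by construction.
Artifact damage is modelled as seeded salt noise on the boundary layers
(budget: severity × 10% of mask volume) — it exercises graceful degradation
only, not metal-streak physics.

What the phantoms do **not** emulate: real cranial anatomy (sutures,
foramina, variable thickness, tables + diploë), intensity-based segmentation
ambiguity, posterior-fossa defect geometry, and real metal artifacts.
Passing the suite shows the estimators and the pipeline are correct and
robust on ideal geometry at clinical voxel sizes; it does not certify
accuracy on patient scans.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `n_lines` | 20 000 (4 000 in cohort sweeps) | Crofton lines; a few thousand already suffice |
| `skip` | 1 | Sobol fast-forward; replicate runs use distinct skips |
| `margin_factor` | 1.05 | enclosing-ball inflation |
| `sigma_vox` | 1.0 | level-set blur, voxels per axis |
| bone `threshold` | 300 | pseudo-CT bone intensity cut |
| `min_component_cm3` | 0.5 | flap fragment filter |
| mean-deviation denominator | pairwise mean | `reference` selects the hematoma-literature convention |

## Known limitations

- Both digital estimators overestimate small flaps by ~t/r_patch (rim term);
  tests assert the bias sign rather than pretending it away.
- The AC height C uses slice spacing; if spacing and thickness differ on a
  real scanner the choice matters and is not resolved here.
- Registration is rigid and mask-based; it assumes the same skull in two
  poses and has no defence against deformation or segmentation disagreement.
- Whether a grazing line should count 0 or 2 crossings is decided by the
  digitized level set; this is an irreducible digitization ambiguity.
- The cohort phantom reuses one shell geometry per cohort (patch, pose and
  noise vary per case); between-patient anatomical variability is not
  represented.
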