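# Methods

`shapereg` builds statistical shape models (SSMs) of bone-like surfaces
from triangulated meshes. The pipeline has four stages: geometry
preparation, groupwise non-rigid registration, PCA shape modelling, and
deviation/cross-section analysis. A synthetic-population generator with
known ground truth is the package's test instrument.

## Geometry preparation

Meshes are read from binary or ASCII STL. STL stores one float32 vertex
triple per facet corner; on read the triangle soup is deduplicated by
exact coordinate equality (no tolerance welding), so topology is
deterministic and closedness/volume are well defined. Left-side bones
are mirrored across a configurable axis (default x, the sagittal
direction) with face winding flipped so volumes are preserved. Enclosed
volume uses the signed-tetrahedron (divergence-theorem) sum; volume
matching scales uniformly about the vertex centroid by
(V_target/V)^{1/3}.

Point clouds are produced by voxel **grid-average subsampling**: space
is split into cubic cells anchored at the cloud's minimum corner and
each occupied cell is replaced by its points' centroid. Cell sizes are
bisected to approximate a configured point count, since counts — not
cell sizes — are the natural control. The input is lexicographically
pre-sorted so results are independent of point order.

Rigid pre-alignment is plain point-to-point ICP (Kabsch updates on
nearest-neighbour matches, best pose retained), with no scaling:
overall size must survive into the shape model, where it is expected to
dominate the first mode. Each subject is aligned **before** final
subsampling so the sampling grid sits consistently on every aligned
geometry.

## Groupwise registration

Each cloud T with points p_j is modelled as a Gaussian mixture
D(x) = (1/n) Σ_j G(x | p_j, σ) with a shared kernel covariance σ
(default: identity, i.e. 1 mm isotropic kernels). The dissimilarity
between a deformed reference and a target is the L2 divergence

    f_L2 = ∫ (D_i − D_j)² dx,

which is closed-form for Gaussian mixtures through
∫ G(x|u₁,s₁) G(x|u₂,s₂) dx = G(0 | u₁−u₂, s₁+s₂). The reference is
deformed by a 3D thin-plate-spline map T′ = T + φθ, where
φ(m,n) = ‖T_m − c_n‖ is the radial basis over control points c_n (the
3D fundamental solution U(r) = r; no affine block — rigid pre-alignment
absorbs pose) and the bending energy tr(θᵀφᵀφθ) = ‖φθ‖²_F with weight
λ (default 1e-11) keeps the warp smooth. Control points default to a
coarser grid-average subsample of the reference (~300 points); the
registration error proved insensitive to this count over 150–1360.

The objective f_L2 + λ‖φθ‖²_F is minimized with L-BFGS-B from θ = 0
using analytic gradients: ∂/∂θ = φᵀ(∂L2/∂x) + 2λφᵀφθ, where the
point-wise L2 gradient follows from the Gaussian closed form. The
target-only D_j² term is constant in θ and is excluded from the
gradient. For speed, cross and squared sums are truncated to each
point's k nearest neighbours (default k = 6) in the relevant cloud,
keeping the full 1/(n_i n_j) double-sum weights; the neighbour lists
are frozen within one optimizer run (keeping the objective smooth) and
refreshed between passes. The truncated value is an approximation of
the exact divergence and may dip marginally negative on sparse clouds;
the exact (untruncated) mode is available and is what the quadrature
tests exercise.

Two kernel normalisations exist. The default `standard` mode uses the
properly normalised Gaussian, for which the closed form is exact. A
`printed` mode reproduces a legacy kernel with constant
1/((2π)^{3/2}|σ|) and exponent −rᵀσ⁻¹r; it equals a normalised Gaussian
of covariance σ/2 times |σ/2|^{1/2}/|σ| and is handled exactly through
that equivalence. λ is calibrated for the standard mode; switching
modes rescales the L2 term and would require recalibrating λ.

**Convergence loop.** After the initial solve, the mean distance from
each deformed reference point to its closest target point is compared
with the tolerance (default 0.4 mm). The target here is represented by
*all* its known points — the subsampled cloud plus the full vertex set
— which approximates surface distance far better than the sparse cloud
alone and makes the error of a perfectly registered identical shape
vanish. Points above tolerance are re-minimized separately: the L2 term
is restricted to the offending points (stress term unchanged), warm
started from the current θ. A refinement that fails to improve the
overall error is discarded, so the error sequence is non-increasing;
the loop stops at tolerance or after `max_outer_iter` (default 10),
flagging — not dropping — unconverged subjects. The group problem
decouples across subjects (each θ_j appears only in its own terms), so
subjects are registered independently against one fixed reference; the
deformed reference clouds all share the reference point ordering, which
is the dense correspondence used downstream. The reference is not
re-registered to an evolving mean (single-pass design; a flag exists
for the iterative variant but defaults off).

## Shape model

Registered subjects flatten to 3n-vectors. The mean shape is the
coordinate-wise average; eigenmodes come from the sample covariance
(divisor N−1) via the thin SVD of the centred N×3n data matrix
(equivalent to the Gram-matrix trick for 3n ≫ N). PCA runs on raw
millimetre coordinates — deliberately no Procrustes scaling and no size
normalisation — so size variation is free to dominate PC1, as it does
in bone populations. Eigenvector signs are fixed by making each mode's
largest-magnitude component positive. Shapes are synthesized as
mean + Σ_k s_k √λ_k v_k with scores s in σ-units; a mesh for any
corresponded cloud is obtained by transferring the reference
connectivity through the correspondence.

## Deviation and cross-section analysis

Distances from test points to a reference mesh are point-to-surface
(exact distance to the nearest triangle, computed by barycentric
projection with edge clamping against every triangle), signed by the
generalized winding number of the closed reference: positive outside,
negative inside. Reports carry the signed mean, absolute mean, extreme
positive/negative deviations and the fraction of points beyond a
threshold (default 1 mm — the displacement at which substantial
articular contact loss is reported in the ankle literature; the
fraction uses a strict comparison on absolute distance). Volume-matched
comparison scales both meshes to a common volume, ICP-aligns, and
reports B-against-A deviations; cross sections intersect a mesh with an
axis-aligned plane (through the pair's shared centroid by default),
chain the crossing segments into closed loops, and compare total loop
lengths.

## Synthetic populations

The generator emulates a cohort of ankle-bone-like shapes. The base
shape is a subdivided icosphere stretched to a (24, 18, 17) mm
semi-axis ellipsoid with one smooth 6 mm radial protrusion (a stylized
talar head/neck); its enclosed volume (~3.4·10⁴ mm³) matches reported
average talus volumes. Default resolution is 5 subdivisions (10 242
vertices), emulating the density of CT-segmented meshes, which is far
above the ~2000-point working clouds — the reason subsampling exists at
all. A population of N subjects (default 30 per cohort) varies by:

* a multiplicative size factor about the centroid, SD 5% — the
  dominant, PC1-like mode;
* smooth localized modes: Gaussian-bump displacement fields along the
  vertex direction (default one bump of 1.5 mm peak-amplitude SD,
  width 0.5 rad), emulating articular-curvature variation;
  fields are Gram–Schmidt-orthogonalized against the size direction
  and each other as 3n-vectors, then peak-normalized so a score of
  1 mm produces a 1 mm peak displacement;
* iid per-vertex noise (default SD 0.1 mm, a CT-segmentation-like
  residual);
* random rigid jitter (rotation SD 5°, translation SD 2 mm) and an
  optional mirrored (left-side) fraction.

Ground truth records every factor, so recovery is measurable. What the
generator does **not** emulate: real articular-surface geometry,
spatially correlated segmentation noise, and non-smooth local defects;
passing recovery tests therefore demonstrates the pipeline's mechanics,
not clinical validity on real tali.

**Mode SNR.** For recovery experiments the signal-to-noise ratio of a
planted mode is defined as the energy ratio
SNR_k = (amp_k‖F_k‖)² / (3n·noise_sd²) — the mode's population
displacement variance over the total per-shape noise variance, the
quantity that governs whether PCA can separate the mode from the noise
floor. The generator defaults give SNR ≈ 3.5 for the bump mode;
`noise_for_snr` derives the noise level for a prescribed SNR.

**Recovery metrics.** `evaluate_recovery` reports |Pearson r| between
each PC's subject scores and each planted score vector, and principal
angles between planted and recovered subspaces computed in
subject-score space (the N×k score matrices). Score space is used
because after registration the model lives on the registered reference
points, not the base-mesh vertices, so 3n-space vectors are not
comparable across supports; score-space angles are support-independent
and centred consistently with PC scores. When the supports do match
(models built from ground-truth correspondences) spatial angles are
reported as well.

## Numerical choices and limitations

* L-BFGS-B runs with gtol 1e-12 and ftol 1e-18 (the objective is of
  order 1e-5 at talus scale); up to 3 passes with refreshed neighbour
  lists, stopping early when the closest-point error stops improving.
* The closest-point error of a registered subject has a floor set by
  the target's point density; at the default synthetic mesh density the
  floor is ≈0.3 mm, safely under the 0.4 mm tolerance. Coarser meshes
  raise the floor above the tolerance no matter how good the warp is.
* Mode-subspace recovery through the full pipeline is limited by the
  warp's legitimate absorption of target noise: with ≈900 deformation
  degrees of freedom the absorbed noise concentrates into a few PCA
  directions. Empirically the top-2 score-subspace angle is ≈4° for
  noiseless populations and 8–10° at bump-mode SNR 10–14, insensitive
  to solver effort, control-point and working-point counts, λ over
  1e-11–1e-9, and rigid pose normalization before PCA. PC1-score
  recovery of the size factors is unaffected (|r| > 0.999).
* Degenerate inputs are rejected explicitly: collinear clouds for ICP,
  open meshes for signed distance and volume, singular kernels, empty
  solids. Truncated L2 values can be marginally negative (see above).
* Experiment sizes in the tests and the acceptance script (20-subject
  populations, ~1360/~2000-point clouds) were chosen as the smallest
  sizes that exercise the method at its reference operating point.
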