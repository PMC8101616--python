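# Methods

## Scope and model

`osteoadapt` implements the computational arm of an axial tibial-loading
study in the mouse: given a density-calibrated microCT-like volume of a
tibia, it (i) segments cortical and cancellous bone, (ii) computes standard
structural outcome measures, (iii) solves linear-elastic axial compression
on a voxel mesh, (iv) reduces the strain field to per-VOI peak/mean
principal strains and strain-volume distributions, and (v) combines those
summaries with paired loaded-vs-control outcome tests to identify adaptive
strain thresholds (ASTs) for the cortical and cancellous compartments.

The central scientific object is the AST: the 95th-percentile ("peak")
tensile or compressive principal strain in a VOI at the lowest applied load
that produces a statistically significant anabolic response. Because load
levels are discrete, an identified AST is an *upper bound* on the true
threshold — the exact threshold lies between the peak strains of the highest
non-responding and lowest responding loads. The package always carries this
upper-bound semantics in its reports.

## Image model and segmentation

Volumes are isotropic 3D grids in g HA/cm^3 with an affine grayscale →
density calibration (slope > 0) recorded alongside the data. The z axis is
the bone's long axis, proximal (slice 0) to distal. Segmentation is a fixed
inclusive threshold (value ≥ t): 0.34 g HA/cm^3 for cortical, 0.41 for
cancellous analyses. Thresold comparison direction and inclusivity are a
package decision; they matter only for voxels exactly at threshold.

VOIs are z-slabs in fractions of *bone length* (first to last occupied
slice), never image extent: the midshaft VOI spans 2.5% of bone length
centered at the length midpoint (an extra slice of an even-count slab goes
distal); the proximal VOIs span 10% of bone length starting one slice
distal to the growth-plate reference slice. Slice counts round half away
from zero; all ranges are 0-based and half-open.

The cancellous VOI additionally removes the cortical shell per slice: the
slice is eroded by one voxel so thin in-plane bridges between trabeculae and
shell break, the eroded component adjacent to the outside background is
dilated back and removed as cortex, and a one-voxel margin around the cortex
is excluded. The remaining interior defines both the trabecular bone set and
the total-volume (TV) reference region used for BV/TV and Tb.Sp. Real
studies typically separate compartments by manual contouring, for which no
algorithmic definition exists; this peel is the package's deterministic
substitute, and it slightly under-counts trabecular bone attached to the
endocortical surface (the one-voxel margin).

## Morphometry

Cortical indices are computed per slice and averaged over the VOI: Tt.Ar is
the hole-filled (periosteally enclosed) area, Ct.Ar the bone area, Ma.Ar the
difference; Imax/Imin are the eigenvalues of the second-moment-of-area
tensor of the bone pixels about the slice centroid (each pixel carries its
h^4/12 self-moment). Per-slice computation (rather than a pooled 3D moment)
avoids mixing slices with different centroids.

Thickness measures (Ct.Th, Tb.Th, Tb.Sp) share one engine: the local
thickness transform, the diameter of the largest sphere fully inside the
structure containing each voxel. It is implemented by painting spheres from
distance-transform maxima downward in half-voxel radius bins, which is
accurate to about one voxel — the intrinsic resolution of sphere-fitting
definitions. Tb.Th averages the map over the bone phase, Tb.Sp over the
background phase restricted to the endocortical interior; both are
volume-weighted means, which for equal-size voxels equal plain voxel means.

## Micro-FE

One 8-node hexahedral element per bone voxel, trilinear shape functions,
2×2×2 Gauss quadrature, isotropic linear elasticity. Voxel meshes are the
micro-FE standard and make verification exact (patch test, lattice node
counts); this package uses them rather than tetrahedra. Only the largest
face-connected component is meshed; dropped voxels are counted and
reported.

Defaults: homogeneous E = 17 GPa, ν = 0.3 — conventional cortical-bone
values; a density power law E = a·ρ^b (a = 15 GPa·(cm^3/g HA)^b, b = 2,
floor E_min = 1 MPa) is available for heterogeneous models. Since all
elements are identical cubes and ν is global, every element stiffness is
E_e times one unit-modulus reference matrix.

Boundary conditions replicate axial compression: the distal end face is
fully clamped and the applied load is distributed over proximal-face nodes
(uniform per-node by default; trilinear-consistent weights and a
roller+3-2-1 variant exist for verification problems requiring an exact
uniform stress state). The load is signed — negative is compression — and
acts along the outward normal of the proximal face, so a negative load
pushes that face toward the fixed distal end. In-plane translation of the
loaded face is unconstrained.

The system is solved matrix-free by element-by-element Jacobi-preconditioned
conjugate gradients (gather → per-element 24×24 multiply → scatter), with
Dirichlet elimination supporting prescribed non-zero displacements (used by
the patch test). Default relative residual tolerance is 1e-8; the
whole-tibia study runs at 1e-6, which changes VOI summary statistics well
below a microstrain. Peak memory scales with node count, not matrix fill.
Element strain is evaluated at the centroid (the mean of the Gauss points
for trilinear hexahedra), one tensor per element.

## Strain statistics

Principal strains are eigenvalues of the symmetric strain tensor, sorted
descending; the absolute principal strain is the larger magnitude of the
extremes. Per-VOI summaries use element-count weighting (identical voxel
volumes make this identical to volume weighting — the package's answer to
the weighting convention question):

- peak tensile = 95th percentile of ε1; peak compressive = the negative of
  the 95th percentile of |ε3| (reported negative). The percentile
  interpolates linearly between closest order statistics; the percentile
  cutoff (rather than the maximum) discards anomalous high-strain elements.
- strain-volume histogram: percent of VOI bone volume per 150-με bin of
  absolute principal strain from 0 to 3000 με, plus an overflow bin so the
  histogram always sums to 100%.
- supra-threshold fraction: percent of VOI volume above 1500 με absolute
  principal strain.

`scale_summary` multiplies all strain quantities by a load ratio — exact
under linear elasticity — and recomputes histogram/fraction from retained
raw per-element values. Summaries built from printed peak/mean values alone
scale their scalars and mark distribution quantities as missing. The study
pipeline solves once at the lowest load and scales to the others by
default; per-load solves agree within solver tolerance.

VOI voxels whose elements were dropped as disconnected floaters are
excluded from summaries and counted (`n_unmeshed`); more than 5% missing is
an error. This relaxation of the strict one-to-one voxel↔element assumption
is needed because segmentation of blurred/noisy images can produce floating
voxels that a valid mesh cannot contain.

## Outcome analysis

Histomorphometry follows ASBMR nomenclature: MS/BS = (dL.Pm + sL.Pm/2)/BS ×
100; MAR = Ir.L.Wi / label interval (6 days: calcein at 10 and 4 days before
euthanasia); BFR/BS = MAR × MS/BS / 100.

qPCR cycle thresholds become relative expression 2^−ΔCt with ΔCt = Ct_gene −
Ct_housekeeping per sample (the only reading consistent with expression
"relative to the housekeeping gene"); loaded-vs-control comparisons use the
Wilcoxon signed-rank test, RANKL/OPG ratios the Mann–Whitney U test.

The signed-rank test drops zero differences and midranks ties; for n ≤ 25
nonzero differences the two-sided p-value is exact, computed by a
generating-function convolution over doubled midranks that enumerates the
2^n equiprobable sign assignments in polynomial time; above n = 25 a normal
approximation with the squared-midrank variance is used. Two-sided p is
twice the smaller tail, capped at 1. Paired t and Mann–Whitney U delegate
to scipy.

AST identification takes per-load VOI summaries and per-load paired-test
outcomes for a designated primary structural measure (a config choice,
because μCT and histomorphometry can disagree at a load level): the lowest
responding load's peak strains become the AST (upper bound); if nothing
responds, the highest load's peaks are reported as lower bounds only;
non-monotone response patterns (responding low but not high) are flagged
rather than silently accepted.

## Synthetic data

The phantom module provides every input the pipeline needs:

- verification shapes (hollow/solid circular and elliptical tubes, parallel
  plates) with closed-form areas, moments, and thicknesses;
- a trabecular cube: a seeded Gaussian random field smoothed to a feature
  size, thresholded so the solid phase connected to the bounding shell
  matches a target BV/TV to 0.25 percentage points (bisection on the
  post-cleanup structure); one parameter controls the thickness scale —
  standard practice for bone phantoms and fully seedable;
- a reduced synthetic tibia at the study's 10 μm voxel size: a dense
  growth-plate cap (the anatomical landmark is returned as an explicit slice
  index — auto-detection is out of scope), a flared metaphyseal shell with
  trabecular interior (25% BV/TV, 40 μm feature size ≈ murine trabecular
  thickness), and a hollow diaphysis; optional Gaussian blur plus additive
  Gaussian noise emulate partial-volume and detector effects.

The default tibia is 1.2 mm long with sub-millimetre radii — roughly a
fifteenth of a real mouse tibia — chosen so a full study (≈80k elements,
one CG solve) completes in about two minutes on one CPU. Consequences to
keep in mind: cross-sections are smaller, so absolute strains at the
in vivo loads are several-fold higher than published whole-bone values, and
tests built on this phantom assert *relative* structure (load-ratio
identities, compartment orderings, analytic shapes) rather than absolute
strain magnitudes. The phantom is straight and axisymmetric: it produces a
nearly uniform midshaft strain field, without the bending gradient of a real
curved tibia, and its trabecular architecture is an isotropic random field,
not a load-adapted anisotropic lattice. Passing tests therefore demonstrate
correctness of the measurement and solver machinery, not anatomical realism.

## Numerical choices and edge cases

- Determinism throughout: all randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); CG is deterministic given inputs; rerunning
  a study config reproduces byte-identical outputs.
- Empty segmentations warn (valid degenerate input); empty VOIs, empty
  meshes, zero-variance paired differences, and all-zero sign-rank
  differences raise.
- Midshaft slab centering, round-half-away-from-zero slice counts, and the
  inclusive threshold are stated conventions; alternatives would shift
  results by at most one voxel layer.
- The elastic reaction at the clamped face balances the applied load to
  solver tolerance; tests verify this rather than the solver asserting it.

## Limitations

- The AST is only as fine-grained as the tested load levels; the package
  reports bounds, never interpolated thresholds.
- No geometric/material nonlinearity, no dynamic (cyclic) transients — the
  analysis is of peak static load, with cycle counts carried only as
  protocol metadata (4 cycles × 54 bursts = 216 events/session).
- No beam-hardening or scanner-specific artifacts in the imaging model; no
  anisotropy/connectivity morphometrics; no mixed-model repeated-measures
  statistics (paired per-load tests only).
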