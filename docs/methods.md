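# Methods

This note documents the models, numerical choices and limitations behind
`clrt`, in the order the pipeline runs them.

## Beam model

The physical CLRT beam is produced by a focusing lens that converges a
hollow cone of ~60 keV photons onto a small focal volume. `clrt` models the
per-unit-weight dose of one beam as the sum of two analytic components:

* **Focal component.** An anisotropic Gaussian centered at the focal point
  and aligned with the beam axis, with the lens's nominal FWHMs as measured
  in water (Lens A: 3.4 mm lateral / 22.5 mm longitudinal; Lens B: 1.3 /
  10.8 mm), peak normalized to 1.0 per unit weight, truncated at 5σ for
  sparsity. The nominal widths are *not* rescaled for heterogeneity: the
  focal spot is treated as a property of the lens optics measured in water.
* **Cone component.** Voxels upstream of the focus inside the hollow shell
  between the inner and outer half-angles (defaults 20° / 25°; the true
  angles of the physical head are unpublished, so they are configurable)
  receive an entrance-level dose `1/peak_to_entrance_ratio` (default ratio
  20, configurable) scaled by a geometric convergence factor and attenuated
  exponentially with the water-equivalent depth from the body entry at
  `mu_water = 0.0206 /mm` (the ~60 keV water value; overridable).

The **geometric convergence factor** models the concentration of photon
fluence as the annular cross-section of the cone shrinks toward the focus:
it scales as `r_entry / r`, where `r` is the distance to the focus and
`r_entry` the distance from the focus to the upstream grid-box entry of the
voxel's ray. Normalizing at the grid-box entry (rather than the body
surface) keeps the factor exact and analytically reproducible; with the
thin air margins of the synthetic phantoms the difference is a few percent
of an already-configurable entrance level. The factor is capped below
`r = (FWHM_lat/2) / tan(θ_inner)`, the radius at which the shell meets the
focal Gaussian laterally, so the 1/r growth hands over smoothly to the
focal spot instead of diverging.

This parametric kernel deliberately replaces a transport calculation. It
reproduces the quantitative properties stated for the physical beam —
energy scale, focal FWHMs in water, hollow convergent geometry, a
pronounced focal peak over a low entrance dose — but not photoelectric dose
enhancement in bone, scatter tails, or spectral effects.

## Radiological path

Water-equivalent path length is computed by exact Siddon-style voxel
traversal: all crossings of the segment with the grid planes are
enumerated, and each traversed voxel contributes its geometric intersection
length times its density. Mass density (g/cc) stands in for the relative
attenuation coefficient — a reasonable approximation near 60 keV for soft
tissue and lung that intentionally ignores the Z-dependence of the
photoelectric cross-section in bone. A vectorized batch variant traces one
ray per cone voxel with identical arithmetic; exactness is what makes the
additivity and log-linear attenuation tests meaningful at 1e-6 tolerances
rather than at sampling accuracy.

`depth_to_point` finds the body-surface entry voxel along the reversed
beam direction and integrates density from there to the point; the entry
search and the integral both use the exact traversal.

## Plan setup

* **Target sampling.** Focal points lie on a cubic lattice anchored at the
  PTV centroid with pitch `spacing_factor × FWHM_lat` (default factor 1.2 —
  slightly wider than the focal width, covering the target with minimal
  overlap). A target smaller than the pitch falls back to its centroid.
* **Approach regions.** Candidate directions are a deterministic Fibonacci
  lattice (default 256 candidates). A candidate is feasible iff the
  water-equivalent depth from the body surface to the point is at most the
  lens's `max_depth` (default 80 mm — the stated penetration limit of the
  delivery system). Head clearance beyond the depth criterion is not
  modeled; the physical clearance geometry is unpublished.
* **Angle assignment.** The feasible set is partitioned into `n_segments`
  near-equal groups by seeded k-means on the unit sphere (chordal metric,
  ties to the lowest index), and the member nearest each group centroid is
  assigned. The default is 8 segments per point: with the narrow Lens B and
  the 1.2×FWHM lattice pitch, fewer directions leave a lateral dose ripple
  of ~±9% between lattice points, while 8 directions interleave the ripple
  patterns of different incidence angles and flatten the target dose; the
  segment count is explicitly a computing-power trade-off. A small
  self-contained k-means keeps the partition byte-deterministic for a fixed
  seed.

## Optimization

The dose-influence matrix stores each beam's unit-weight dose as a sparse
column (entries below 1e-6 of the column maximum dropped). The objective is
the penalty-weighted sum of per-structure mean squared one-sided deviations
from the prescribed dose; the Heaviside gates are taken strict, so a voxel
exactly at prescription contributes nothing from either side (the objective
is continuous; the convention only pins down determinism). Minimization
uses L-BFGS-B under `w ≥ 0` with analytic gradients, started from uniform
weights scaled so the mean PTV dose equals the prescription. Hard max/mean
dose constraints become quadratic penalty terms on a fixed escalating
multiplier schedule (10×, 100×, 1000×, warm-started); residual violations
are reported on the plan rather than silently absorbed. Defaults:
`max_iter` 500 per stage, `tol` 1e-6 relative objective change.

The default objective set (`PlanningConfig.default`) is the standard
small-target recipe: under- and over-dose at the prescription on the PTV
(penalty 1000 each) and over-dose at 50% prescription on the auto-derived
`NORMAL = BODY ∖ PTV` structure (penalty 100) to confine the prescription
isodose to the target.

## Evaluation

DVHs are cumulative ("volume receiving at least"), threshold inclusive,
default bin width 0.1% of prescription. `V_x` counts voxels at or above
`x%` of prescription times the voxel volume; for the conformity denominator
`V100` the count runs over the whole grid (the standard conformity-index
definition, not body-restricted). Effective radii are those of equal-volume
spheres; `GI = 50 / (R50,eff − R100,eff)` in %/cm, reported as +∞ if the
two radii coincide. `CN = CI × TCI` holds by construction to machine
precision.

## Synthetic phantoms

The phantom factory emulates the *planning problem* — a deep-seated sub-cc
spherical target near a spherical OAR inside water, optionally with a
1.85 g/cc bone shell (cranial), a 0.26 g/cc lung block (thorax), or mild
seeded density texture (2% multiplicative noise on soft tissue) standing in
for CT heterogeneity. It does not emulate anatomy, contouring uncertainty,
CT artifacts, or motion; passing tests demonstrate the correctness and
internal consistency of the planning chain on controlled geometry, not
clinical plan quality. Masks are voxel-center-in-structure binary rasters;
at 1–2 mm spacing the voxelized volume of a 4.4 mm sphere deviates from the
analytic 0.36 cc by a few percent (discretization scales with surface area
× spacing).

## Problem sizes and determinism

The shipped end-to-end example uses a 48³ grid at 1 mm with 81 target
points × 8 directions (648 beams), which runs in about a minute on one CPU;
the profile-measurement checks use 0.25 mm grids of ~0.4M voxels. All
stages are deterministic for a fixed config: the only stochastic element is
the k-means seeding of angle segmentation, which is driven by the config
seed (offset per target point), and plan files re-serialize byte-identically.

## Known limitations

* The dose kernel is parametric, not transport-based: no scatter, no
  spectral hardening, no bone photoelectric enhancement.
* Density ≈ attenuation equivalence overestimates bone penetration
  slightly at 60 keV.
* Constraint handling is penalty-based; infeasible constraint sets degrade
  gracefully (logged violation) instead of failing.
* Robot kinematics, collision avoidance and couch modeling are out of
  scope; feasibility is purely the depth criterion.
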