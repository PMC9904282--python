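# Methods

This note records the models, numerical choices and their rationale, what
the synthetic fixtures do and do not emulate, and known limitations.

## Volume conductor

**Meshes.** Labeled volumetric meshes carry vertices (meters), elements
(tetra4 or hexa8), and one tissue id per element.  Tetrahedra must have
positive signed volume (reading code repairs inverted elements by swapping
two vertices rather than rejecting the file, since MSH writers disagree on
ordering); hexahedra must have positive trilinear Jacobians at all eight
corners.  The internal length unit is the meter everywhere; mm-based
formats (MSH, NIfTI) are converted at the I/O boundary.

**Nested-sphere generator.** The standard validation conductor is a ball
of concentric shells.  Points are seeded on every shell surface with a
golden-angle spiral at roughly the target edge spacing, plus an interior
body-centered-cubic lattice (lightly jittered, and kept clear of the shell
surfaces), and tetrahedralized with Delaunay — for a convex point set this
tiles the ball.  BCC was chosen because its Delaunay triangulation consists
of well-shaped tetrahedra; a plain cubic lattice produces slivers that
visibly degrade dipole right-hand sides.  Each element is labeled by the
innermost sphere containing its barycenter.  With the 92/86/80 mm
three-shell geometry, a 9 mm target edge yields ≈50k elements.  Boundary
faceting biases the total volume low by ≈0.3–0.6% at the resolutions used.

**Voxels to hexahedra.** One hexa8 per nonzero voxel, corners merged via
the corner lattice, NIfTI affine applied to half-integer corner indices
(0-based voxel centers, RAS mm).  A negative-determinant affine flips the
corner ordering so Jacobians stay positive.  Optional interface node
shifting (default fraction 0.33, allowed up to 0.49) pulls each vertex that
touches ≥2 distinct nonzero tissues toward the centroid of the adjacent
voxel centers of the locally dominant tissue (majority count, ties to the
smaller id).  Vertices adjacent to a single tissue — including the outer
staircase against background — do not move; the mechanism smooths
*tissue* interfaces, and the allowed range keeps all corner Jacobians
positive.  The displacement rule is one admissible reading of the named
geometry-adaptation technique; the magnitude and rule are configurable.

**Resection** keeps elements whose barycenter lies on the normal side of a
cut plane, compacts vertex indices, and is idempotent by construction.

## Conductivity

Isotropic defaults (S/m): scalp 0.43, skull 0.01, CSF 1.79, GM 0.33,
WM 0.14; all overridable per tissue.

**Effective medium mapping.**  Direct variant: σ = 1000 · s · d with
s = 0.736 S·s/mm³ and d in mm²/s; the factor 1000 is the only
dimensionally consistent bridge from S/mm to S/m, and the
volume-constrained variant is independent of it since its scale is
calibrated: s_vc = σ_iso · N_wm / D_wm, with D_wm the sum over white-matter
voxels of the cube root of the diffusion-eigenvalue product.  This makes
EMA+VC exactly recover σ_iso for isotropic diffusivity and invariant under
global diffusivity rescaling — both are tested identities.

**Constraints.**  Per tensor, eigenvalues are first clipped to
≤ 2 S/m, then raised to ≥ (largest eigenvalue)/10.  This order guarantees
both bounds hold after one pass; clipping acts on eigenvalues (not on the
whole tensor) so eigenvectors are untouched, and the operation is
idempotent.  Invalid (non-SPD or non-finite) masked voxels are replaced by
the isotropic WM default and *counted* — silent NaN propagation into the
stiffness matrix is the worst failure mode, and the substitution count
surfaces in logs.

**Voxel→element transfer** samples the voxel containing each element
barycenter (nearest voxel through the inverse affine, no interpolation —
interpolating across tissue boundaries would mix tissues).  Elements whose
barycenter falls outside the grid keep their isotropic default and are
counted.  Realistic tensors are intended for white matter; gray matter can
be targeted explicitly but dipole sources inside anisotropic tissue are
not recommended.

**Simulated anisotropy** builds eigenvalues (λ_l, λ_t, λ_t) with
λ_l/λ_t = ratio and geometric mean equal to the tissue scalar
(λ_l = σ·ratio^{2/3}), with the longitudinal axis radial or fixed.

## FEM core

Stiffness: K_ij = ∫ ∇φᵢ·σ∇φⱼ dV, assembled vectorized over elements; P1
tetra gradients are constant (exact integration), hexa8 uses 2×2×2 Gauss
on the trilinear isoparametric map.  The matrix is symmetrized exactly
after assembly; constants span its nullspace (row sums ≈ 1e-16 relative).

The pure-Neumann system is singular; it is solved with conjugate gradients
on the mean-zero subspace (rhs, iterates and preconditioned residuals all
projected), avoiding the bias of pinning a reference node.  Jacobi is the
default preconditioner; an algebraic-multigrid preconditioner is used when
the optional pyamg package is importable.  Default relative residual
1e-8 with 10 000 iteration cap — chosen so that transfer-vs-direct
leadfield agreement at 1e-6 has headroom; the route-equivalence test
itself tightens both routes to 1e-11 so the comparison measures the
algebraic identity rather than solver noise.

Electrodes map to the nearest outer-boundary vertex (boundary = faces used
by exactly one element); electrodes farther than 2 cm from the surface are
rejected.  The EEG transfer matrix solves K tᵀ = rᵢ − r_ref (first
electrode as internal reference, one solve per remaining channel); emitted
leadfields are re-referenced to the average, making the internal choice
invisible.  Columns are unit dipoles of 1 A·m; EEG units are volts.

## Source models

Sign convention: rhs_i = +q·∇φᵢ(x₀); with K u = rhs this reproduces the
physical potential — the global sign is pinned by the analytic sphere
oracle, which also fixes the MEG secondary-field sign (B = B_primary −
(μ0/4π)∫(σ∇u)×(r−r′)/|r−r′|³ dV).

**Partial integration** places q·∇φᵢ on the containing element's vertices
(constant per tetra; trilinear gradient evaluated at the point for hexa).
Its loads reproduce the dipole's first moment exactly; the leading error
is quadrupolar, of order the element size.

**Saint-Venant** distributes monopole loads on the vertex star of the
vertex nearest the dipole.  Loads minimize a moment-matching objective
with offsets scaled by a reference length (default 20 mm), a Tikhonov term
(default 1e-6) weighted by scaled distance to the power 2·exponent
(default exponent 1), and the zeroth moment (total charge) enforced as a
hard constraint via a nullspace parametrization — charge conservation
holds to machine precision, which the singular Neumann solver requires.
Matched moments: first moments equal the dipole moment; second moments
(including the mixed terms, on by default) equal those of a point dipole
at x₀ expanded about the star vertex.  Matching the *full* second-moment
tensor suppresses the quadrupolar discretization error: on the ≈50k-element
three-shell mesh it reduces the worst deep-dipole RDM against the analytic
oracle from ≈0.05 to ≈0.005.  The classical Venant placement condition —
the star must not cross a tissue interface — is enforced by the source
validator, which reports (rather than aborts on) invalid sources; invalid
sources yield zero leadfield columns with a warning so batch runs survive.

## MEG

The field splits into the analytic primary dipole term and the secondary
field of volume currents.  The secondary field is linear in the node
potentials, captured by a channels×nodes integration matrix using
**one-point barycenter quadrature** per element — the accuracy-limiting
choice, acceptable because fixture coils sit ≥20% outside the conductor
where the integrand is smooth (measured: RDM ≤ 1e-3 against the Sarvas
oracle; radial-dipole leakage ≤ 0.1% of a matched tangential dipole).
Element subdivision would be the natural extension if coils ever approach
the scalp.  Coils are weighted oriented point sets: magnetometers (one
point, weight 1) and planar gradiometers (two points, weights ±1/baseline,
default baseline 16.8 mm for fixtures only — the coil file fully overrides
geometry).  μ0 = 4π×10⁻⁷ T·m/A exactly.  The MEG transfer matrix solves
one system per channel against the (mean-projected) integration rows.

## Analytic references

**Multilayer EEG.**  In each layer the per-degree radial solution is
A r^n + B r^{-(n+1)}; interface continuity of potential and normal current
plus the outer no-flux condition give a small linear system per degree n,
solved with per-layer normalized basis functions ((ρ/x_top)^n,
(x_bot/ρ)^{n+1}) so the system stays well conditioned at n ≈ 200.  The
series is truncated adaptively when the term falls below 1e-12 of the
running maximum (hard cap 200 terms).  The n-th term scales as
(b/R_outer)^n, so truncation error rises steeply with eccentricity;
oracle-based tests stay at eccentricity ≤ 0.95, and the homogeneous
special case is cross-checked against an independent closed form obtained
by generating-function summation of the series.

**MEG.**  The Sarvas closed form is exact for any spherically symmetric
conductor, independent of the layer profile — on sphere fixtures it
coincides with per-sensor fitted-sphere variants, which are therefore not
implemented separately.

## Metrics and dipole scan

RDM(a,b) = ‖a/‖a‖ − b/‖b‖‖ ∈ [0,2] measures topography shape error; MAG =
‖a‖/‖b‖ measures amplitude.  The dipole scan projects the (optionally
whitened) data onto each source's 3-column subspace via SVD,
GOF = ‖projection‖²/‖data‖², ties broken toward the lowest source index,
with a configurable GOF acceptance threshold (default 0.9 — the method's
named filter threshold is not standardized, so it is a surfaced
parameter).  Singular blocks are skipped with a warning.  Whitening uses
the symmetric inverse square root of the noise covariance; whitened
least-squares projection is the generalized-least-squares reading of the
scan.

## Synthetic fixtures and what passing tests show

The synthetic DTI generator produces uniform-isotropic, radially aligned,
or fixed-axis tensor fields with typical brain-water diffusivities (mean
1e-3 mm²/s; anisotropic eigenvalues 1.4/0.35 ×10⁻³ mm²/s, a ~4:1 ratio
typical of coherent white matter), with optional relative eigenvalue
jitter clipped so tensors stay SPD.  Random dipole samplers draw uniform
elements of one tissue (all vertices within the eccentricity bound) with
unit random moments.  Everything is seed-deterministic.

These fixtures emulate geometry, conductivity structure and source
placement — not real anatomy: no cortical folding, no real skull
inhomogeneity, no sensor noise or coregistration error, and the sphere's
analytic solvability is exactly what makes it a usable oracle.  Passing
the oracle tests demonstrates correctness of the discretization and
implementation at realistic head scales and contrasts (skull:brain
≈ 1:80), not accuracy on any individual head.

## Problem sizes and defaults used in validation

The standard validation runs use the 92/86/80 mm three-shell sphere at a
9 mm target edge (≈50k tetrahedra, ≈9k vertices), 60 surface electrodes,
40 magnetometers at 1.2× the outer radius, dipole eccentricities up to
0.8 (sources), 0.95 (oracle series), a 600-point volumetric scan grid and
20 noisy scan trials (1% amplitude Gaussian noise).  Mesh-refinement
convergence is demonstrated across 12 / 10.5 / 9 mm nested resolutions.
These sizes were chosen as the smallest at which skull contrast and
eccentricity stress the discretization meaningfully.

## Known limitations

* Continuous Galerkin only; no discontinuous-Galerkin or unfitted variants.
* Tetra meshes use exact P1 integration; hexa secondary-field MEG uses the
  center-point gradient (adequate for gently deformed voxel hexes).
* The Venant model requires single-compartment vertex stars; sources
  violating the condition are excluded, not approximated.
* Electrode model is nearest-vertex restriction; barycentric-on-face
  interpolation would be the next refinement.
* The analytic EEG series degrades beyond eccentricity ≈0.95 by design of
  the truncation; the FEM itself has no such restriction.
* Mesh generation covers the nested-sphere fixture and voxel conversion;
  meshing arbitrary anatomical surfaces is out of scope.
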