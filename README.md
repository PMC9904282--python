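# ephysfem

Finite-element forward modeling of electromagnetic brain signals (EEG and
MEG), for researchers who need realistic volume-conductor head models:
labeled tetrahedral/hexahedral meshes, isotropic or DTI-derived anisotropic
conductivity tensors, continuous-Galerkin FEM leadfields computed through
transfer matrices, closed-form sphere oracles for validation, and
dipole-scan source localization.

## The forward problem

A current dipole with moment **q** at position **x**₀ drives a quasi-static
potential *u* in the head volume conductor Ω:

    ∇·(σ ∇u) = ∇·(q δ(x − x₀))   in Ω,      σ ∇u · n = 0   on ∂Ω,

where σ(x) is the (possibly tensor-valued) tissue conductivity.  The scalp
potential gives the EEG; the magnetic field at sensor coils is the sum of
the primary (infinite-medium) dipole field and the secondary field of the
volume return currents −σ∇u (Biot–Savart).  The **leadfield** L maps
elementary dipoles (3 orientations per source position) to sensor channels;
rows = channels, columns = 3 × sources.

Key pieces implemented here:

* **CG-FEM discretization** on labeled tetra4 (exact P1 integration) or
  hexa8 (trilinear, 2×2×2 Gauss) meshes; the singular pure-Neumann system
  is solved by preconditioned CG on the mean-zero subspace.
* **Transfer matrices**: for E electrodes (or M coils) only E−1 (or M)
  sparse-system solves are needed; leadfields for thousands of sources then
  reduce to sparse dot products, exploiting symmetry of the stiffness matrix.
* **Dipole models**: Saint-Venant (regularized monopole loads on the vertex
  star of the nearest vertex, matched to the dipole's multipole moments up
  to full second order) and partial integration (q·∇φᵢ at the source).
* **Conductivity from diffusion MRI** (effective medium approach): σ = s·d
  with s = 0.736 S·s/mm³, or the volume-constrained variant where s is
  calibrated so the geometric-mean white-matter conductivity equals a
  target isotropic value (default 0.14 S/m); eigenvalues are capped at
  2 S/m and the longitudinal/transversal ratio at 10.
* **Analytic oracles**: multilayer concentric-sphere EEG potential
  (Legendre series with per-layer radial transfer coefficients) and the
  Sarvas closed-form MEG field.
* **Dipole scanning**: single-dipole localization by (optionally whitened)
  least-squares projection with a goodness-of-fit threshold.

Default tissue conductivities (S/m): scalp 0.43, skull 0.01, CSF 1.79,
gray matter 0.33, white matter 0.14.

## Worked example

Three-shell sphere (radii 92/86/80 mm, conductivities 0.33/0.0042/0.33 S/m),
60 scalp electrodes, one tangential 10 nA·m dipole at 70% eccentricity,
validated against the analytic 3-shell solution:

```python
import numpy as np
from ephysfem.mesh import build_nested_sphere_mesh, SCALP, SKULL, GM, _fibonacci_sphere
from ephysfem.conductivity import default_isotropic
from ephysfem.fem import assemble_stiffness, attach_electrodes, eeg_transfer, eeg_leadfield
from ephysfem.sources import Dipole, rhs_venant
from ephysfem.analytic import SphereModel, eeg_sphere_potential
from ephysfem.metrics import rdm, mag

mesh = build_nested_sphere_mesh(
    radii=[0.092, 0.086, 0.080], tissue_ids=[SCALP, SKULL, GM],
    target_edge_length=0.009, seed=7)
print(f"mesh: {mesh.n_elements} tetrahedra, {mesh.n_vertices} vertices")

cond = default_isotropic(mesh, overrides={SCALP: 0.33, SKULL: 0.0042, GM: 0.33})
K = assemble_stiffness(mesh, cond)
electrodes = _fibonacci_sphere(60) * 0.092
R = attach_electrodes(mesh, electrodes)
T = eeg_transfer(K, R)

dip = Dipole(position=[0, 0, 0.056], moment=[0, 1e-8, 0])
lf = eeg_leadfield(T, rhs_venant(mesh, dip).toarray())
v = lf.matrix[:, 0]
print(f"scalp potential range: {v.min()*1e6:.3f} .. {v.max()*1e6:.3f} uV")

sphere = SphereModel(center=[0, 0, 0], radii=[0.092, 0.086, 0.080],
                     conductivities=[0.33, 0.0042, 0.33])
ref = eeg_sphere_potential(sphere, dip, np.asarray(R @ mesh.vertices))
ref -= ref.mean()
print(f"RDM vs analytic 3-shell: {rdm(v, ref):.4f}")
print(f"MAG vs analytic 3-shell: {mag(v, ref):.4f}")
```

Output:

    mesh: 50024 tetrahedra, 9031 vertices
    scalp potential range: -0.744 .. 0.688 uV
    RDM vs analytic 3-shell: 0.0060
    MAG vs analytic 3-shell: 1.0097

An RDM of 0.006 means the FEM and analytic topographies are nearly
identical in shape; MAG 1.01 means amplitudes agree to 1%.

The same pipeline is scriptable from the shell:

    ephysfem mesh sphere --radii 92,86,80 --ids 1,2,4 --edge 9 --seed 7 --out head.msh
    ephysfem forward eeg --mesh head.msh --dipoles dipoles.txt \
        --electrodes electrodes.txt --out results/
    ephysfem scan --leadfield results/leadfield_eeg.txt --data data.txt

See `ephysfem --help` for mesh editing (resection, voxel conversion with
interface node shifting), conductivity mapping (`cond ema`, `cond ema-vc`,
`cond simulated`), MEG forward runs, analytic references, leadfield
comparison and full INI-driven pipelines (`ephysfem run --config`).

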