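"""Synthetic fixtures: DTI volumes and random dipole samples.

These generators stand in for subject data in tests and validation runs:
a synthetic diffusion tensor image with a prescribed eigenstructure
(uniform isotropic, radially aligned, or fixed-axis) plus optional
eigenvalue jitter, and uniformly sampled dipoles inside a chosen tissue
of a mesh.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conductivity import ConductivityError, DiffusionTensorImage
from .mesh import FEMesh, element_barycenters
from .sources import SourceSpace


@dataclass(frozen=True)
class SyntheticDtiSpec:
    """Recipe for a synthetic diffusion tensor volume.

    ``pattern`` is one of ``uniform-isotropic`` (d = mean_diffusivity * I),
    ``radial`` (principal eigenvector toward/away from the grid center) or
    ``fixed-axis``; anisotropic patterns use eigenvalues
    (lambda_long, lambda_trans, lambda_trans) in mm^2/s.  ``noise`` is a
    relative eigenvalue jitter fraction (clipped so eigenvalues stay above
    10% of nominal).
    """

    shape: tuple = (16, 16, 16)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    pattern: str = "uniform-isotropic"
    mean_diffusivity: float = 1e-3  # mm^2/s, typical brain water
    lambda_long: float = 1.4e-3
    lambda_trans: float = 0.35e-3
    axis: tuple = (0.0, 0.0, 1.0)
    noise: float = 0.0
    seed: int = 0


def generate_synthetic_dti(spec: SyntheticDtiSpec) -> DiffusionTensorImage:
    """Deterministic synthetic DTI honoring the requested pattern."""
    nx, ny, nz = spec.shape
    rng = np.random.default_rng(spec.seed)
    if spec.pattern == "uniform-isotropic":
        lam = np.full((nx, ny, nz, 3), spec.mean_diffusivity)
        vecs = np.broadcast_to(np.eye(3), (nx, ny, nz, 3, 3)).copy()
    elif spec.pattern in ("radial", "fixed-axis"):
        lam = np.empty((nx, ny, nz, 3))
        lam[..., 0] = spec.lambda_long
        lam[..., 1] = spec.lambda_trans
        lam[..., 2] = spec.lambda_trans
        if spec.pattern == "fixed-axis":
            v = np.asarray(spec.axis, dtype=float)
            v = v / np.linalg.norm(v)
            d = np.broadcast_to(v, (nx, ny, nz, 3)).copy()
        else:
            idx = np.stack(np.meshgrid(*(np.arange(s) for s in spec.shape),
                                       indexing="ij"), axis=-1).astype(float)
            ctr = (np.array(spec.shape) - 1) / 2.0
            d = idx - ctr
            nrm = np.linalg.norm(d, axis=-1, keepdims=True)
            center = nrm[..., 0] < 1e-12
            d[center] = [0.0, 0.0, 1.0]
            nrm[center] = 1.0
            d = d / nrm
        vecs = _frames_from_axis(d)
    else:
        raise ConductivityError(f"unknown DTI pattern {spec.pattern!r}")

    if spec.noise > 0:
        jitter = 1.0 + spec.noise * rng.standard_normal(lam.shape)
        lam = np.maximum(lam * jitter, 0.1 * lam)

    tensors = np.einsum("...ij,...j,...kj->...ik", vecs, lam, vecs)
    return DiffusionTensorImage(
        tensors=tensors, affine=np.asarray(spec.affine, dtype=float),
        brain_mask=np.ones(spec.shape, dtype=bool),
    )


def _frames_from_axis(d: np.ndarray) -> np.ndarray:
    """Orthonormal frames (columns) with first column along d."""
    ref = np.where(np.abs(d[..., :1]) < 0.9,
                   np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
    e2 = np.cross(d, ref)
    e2 = e2 / np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = np.cross(d, e2)
    return np.stack([d, e2, e3], axis=-1)


def generate_random_dipoles(mesh: FEMesh, tissue: int, n: int,
                            eccentricity_max: float = 1.0,
                            seed: int = 0) -> SourceSpace:
    """Uniformly sample n dipoles over elements of a tissue, restricted to
    |r - centroid| / R_outer <= eccentricity_max, with unit random moments."""
    rng = np.random.default_rng(seed)
    ctr = mesh.centroid()
    R = mesh.outer_radius()
    # an element qualifies only if ALL its vertices satisfy the bound, so
    # every interior sample point does too
    vert_ecc = np.linalg.norm(mesh.vertices - ctr, axis=1) / R
    ecc = vert_ecc[mesh.elements].max(axis=1)
    eligible = np.flatnonzero((mesh.labels == int(tissue)) & (ecc <= eccentricity_max))
    if len(eligible) == 0:
        raise ValueError("no eligible elements for the requested tissue/eccentricity")
    chosen = rng.choice(eligible, size=n, replace=True)
    # random interior point per element via Dirichlet barycentric weights
    k = mesh.elements.shape[1]
    w = rng.dirichlet(np.ones(k), size=n)
    positions = np.einsum("sk,ski->si", w, mesh.vertices[mesh.elements[chosen]])
    moments = rng.standard_normal((n, 3))
    moments /= np.linalg.norm(moments, axis=1)[:, None]
    return SourceSpace(positions=positions, moments=moments)
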