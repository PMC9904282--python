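"""MEG forward computation.

The magnetic field splits into the primary field of the impressed dipole
(infinite-medium Biot-Savart term, computed analytically) and the secondary
field of the volume return currents J = -sigma grad(u), computed from the
FEM potential.  The secondary field is linear in the node potentials, so it
is captured by a channels x nodes integration matrix (one-point barycenter
quadrature per element); combined with the symmetric stiffness matrix this
yields an MEG transfer matrix with one solve per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .analytic import MU0
from .conductivity import ConductivityModel
from .fem import (FemError, Leadfield, SolverOptions, StiffnessMatrix,
                  TransferMatrix, solve_potential, tetra_gradients)
from .mesh import FEMesh, element_barycenters, element_volumes


class MegError(RuntimeError):
    pass


@dataclass
class Coil:
    """One MEG channel: weighted, oriented field integration points."""

    name: str
    points: np.ndarray  # (P,3) m
    orientations: np.ndarray  # (P,3) unit
    weights: np.ndarray  # (P,)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        nrm = np.linalg.norm(self.orientations, axis=1)
        if np.abs(nrm - 1).max() > 1e-9:
            raise MegError(f"coil {self.name}: orientations must be unit vectors")
        if not (len(self.points) == len(self.orientations) == len(self.weights)):
            raise MegError(f"coil {self.name}: inconsistent point counts")


@dataclass
class CoilModel:
    channels: list[Coil]

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @classmethod
    def magnetometers(cls, positions, orientations, names=None) -> "CoilModel":
        """Single-point unit-weight coils."""
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        orientations = np.asarray(orientations, dtype=float).reshape(-1, 3)
        orientations = orientations / np.linalg.norm(orientations, axis=1)[:, None]
        names = names or [f"MAG{i:03d}" for i in range(len(positions))]
        return cls(channels=[
            Coil(name=n, points=p[None], orientations=o[None], weights=np.array([1.0]))
            for n, p, o in zip(names, positions, orientations)
        ])

    @classmethod
    def planar_gradiometers(cls, centers, orientations, baseline_axes,
                            baseline: float = 0.0168, names=None) -> "CoilModel":
        """Two-point coils with weights +-1/baseline along the baseline axis
        (default baseline 16.8 mm, a typical hardware geometry for fixtures)."""
        centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        orientations = np.asarray(orientations, dtype=float).reshape(-1, 3)
        axes = np.asarray(baseline_axes, dtype=float).reshape(-1, 3)
        axes = axes / np.linalg.norm(axes, axis=1)[:, None]
        names = names or [f"GRAD{i:03d}" for i in range(len(centers))]
        chans = []
        for n, c, o, a in zip(names, centers, orientations, axes):
            o = o / np.linalg.norm(o)
            pts = np.array([c + a * baseline / 2, c - a * baseline / 2])
            chans.append(Coil(
                name=n, points=pts, orientations=np.array([o, o]),
                weights=np.array([1.0, -1.0]) / baseline,
            ))
        return cls(channels=chans)


@dataclass
class MegIntegrationMatrix:
    """channels x nodes map from node potentials to the secondary-field term
    (mu0/4pi) integral (sigma grad u) x (r_c - r')/|r_c - r'|^3 dV per channel;
    the physical secondary field is MINUS this reading."""

    matrix: np.ndarray
    channel_names: list[str]
    mesh_fingerprint: str


# ---------------------------------------------------------------------------
# primary field
# ---------------------------------------------------------------------------

def primary_bfield_points(dipole, points: np.ndarray) -> np.ndarray:
    """Infinite-medium dipole field B = (mu0/4pi) q x (r-r0)/|r-r0|^3 (T)."""
    r0 = np.asarray(dipole.position, dtype=float)
    q = np.asarray(dipole.moment, dtype=float)
    d = np.asarray(points, dtype=float).reshape(-1, 3) - r0
    dist = np.linalg.norm(d, axis=1)
    if (dist < 1e-3).any():
        raise MegError("integration point within 1 mm of the dipole")
    return (MU0 / (4 * np.pi)) * np.cross(q, d) / dist[:, None] ** 3


def primary_bfield(dipole, coils: CoilModel) -> np.ndarray:
    """Per-channel primary readings (T)."""
    out = np.zeros(len(coils))
    for i, ch in enumerate(coils.channels):
        B = primary_bfield_points(dipole, ch.points)
        out[i] = float(np.sum(ch.weights * np.einsum("ij,ij->i", B, ch.orientations)))
    return out


# ---------------------------------------------------------------------------
# secondary field integration matrix
# ---------------------------------------------------------------------------

def _element_sigma_gradients(mesh: FEMesh, cond: ConductivityModel):
    """(M,k,3) sigma_e grad(phi_n)|_e at element centers, volumes (M,)."""
    S = cond.element_tensors(mesh)
    if mesh.element_kind == "tetra4":
        G, vol = tetra_gradients(mesh)
    else:
        from .mesh import _trilinear_dshape

        X = mesh.vertices[mesh.elements]
        dN = _trilinear_dshape(np.zeros(3))  # center of the reference cube
        J = np.einsum("na,enb->eab", dN, X)
        invJ = np.linalg.inv(J)
        G = np.einsum("eab,nb->ena", invJ, dN)
        vol = element_volumes(mesh)
    sg = np.einsum("eij,enj->eni", S, G)
    return sg, vol


def build_meg_integration(mesh: FEMesh, cond: ConductivityModel,
                          coils: CoilModel) -> MegIntegrationMatrix:
    """One-point (barycenter) quadrature of the secondary-field volume
    integral, accumulated per node into a channels x nodes matrix."""
    bc = element_barycenters(mesh)
    sg, vol = _element_sigma_gradients(mesh, cond)  # (M,k,3), (M,)
    el = mesh.elements
    N = mesh.n_vertices
    outer_r = mesh.outer_radius()
    ctr = mesh.centroid()
    rows = np.zeros((len(coils), N))
    for ci, ch in enumerate(coils.channels):
        for p, o, w in zip(ch.points, ch.orientations, ch.weights):
            if np.linalg.norm(p - ctr) <= outer_r:
                raise MegError(
                    f"coil point of channel {ch.name} lies inside the mesh"
                )
            rvec = p - bc  # (M,3)
            rn3 = np.linalg.norm(rvec, axis=1) ** 3
            f = rvec / rn3[:, None]
            # (sigma grad phi_n) x f . o, per element and local node
            contrib = np.einsum(
                "enk,ek->en", np.cross(sg, f[:, None, :]), np.broadcast_to(o, (len(bc), 3))
            ) * vol[:, None] * (MU0 / (4 * np.pi)) * w
            np.add.at(rows[ci], el.ravel(), contrib.ravel())
    return MegIntegrationMatrix(
        matrix=rows, channel_names=coils.names,
        mesh_fingerprint=mesh.fingerprint(),
    )


# ---------------------------------------------------------------------------
# transfer and leadfield
# ---------------------------------------------------------------------------

def meg_transfer(K: StiffnessMatrix, integration: MegIntegrationMatrix,
                 opts: SolverOptions = SolverOptions()) -> TransferMatrix:
    """Per-channel solves K t = s_c (K symmetric): t . b gives the channel's
    secondary reading for any source rhs b."""
    if K.mesh_fingerprint != integration.mesh_fingerprint:
        raise FemError("stiffness and MEG integration built on different meshes")
    S = integration.matrix
    # integration rows are not zero-sum; project (secondary reading is
    # invariant under adding constants to u, so only the mean-free part acts)
    S0 = S - S.mean(axis=1, keepdims=True)
    try:
        T = solve_potential(K, S0.T, opts).T
    except FemError as e:
        raise FemError(f"MEG transfer solve failed: {e}") from e
    return TransferMatrix(
        matrix=T, modality="meg", channel_names=list(integration.channel_names),
        mesh_fingerprint=K.mesh_fingerprint, reference=None,
    )


def meg_secondary_direct(K: StiffnessMatrix, integration: MegIntegrationMatrix,
                         rhs_matrix, opts: SolverOptions = SolverOptions()) -> np.ndarray:
    """Reference route: solve potentials per source, then integrate."""
    B = rhs_matrix.toarray() if sp.issparse(rhs_matrix) else np.asarray(rhs_matrix)
    U = solve_potential(K, B, opts)
    return integration.matrix @ U


def meg_leadfield(mesh: FEMesh, cond: ConductivityModel, coils: CoilModel,
                  space, model: str = "venant", params=None,
                  opts: SolverOptions = SolverOptions(),
                  K: StiffnessMatrix | None = None,
                  transfer: TransferMatrix | None = None) -> Leadfield:
    """Total MEG leadfield: primary minus integrated secondary reading,
    channels x (3*n_sources), T per (A*m)."""
    from .fem import assemble_stiffness
    from .sources import Dipole, build_rhs_matrix

    if K is None:
        K = assemble_stiffness(mesh, cond)
    if transfer is None:
        integ = build_meg_integration(mesh, cond, coils)
        transfer = meg_transfer(K, integ, opts)
    B = build_rhs_matrix(mesh, space, model=model, params=params)
    secondary = np.asarray(transfer.matrix @ B)
    primary = np.zeros_like(secondary)
    unit = np.eye(3)
    for j, pos in enumerate(space.positions):
        if not space.valid[j]:
            continue
        for k in range(3):
            primary[:, 3 * j + k] = primary_bfield(Dipole(pos, unit[k]), coils)
    return Leadfield(
        matrix=primary - secondary, modality="meg",
        channel_names=coils.names, source_positions=space.positions,
    )
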