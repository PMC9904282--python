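"""Continuous-Galerkin FEM core for the EEG forward problem.

Assembles the anisotropic stiffness matrix K_ij = integral grad(phi_i) .
sigma grad(phi_j) dV over labeled tetra4 (exact P1 integration) or hexa8
(isoparametric trilinear, 2x2x2 Gauss) elements, solves the singular
pure-Neumann system on the mean-zero subspace with preconditioned conjugate
gradients, and builds EEG transfer matrices and leadfields.

The transfer-matrix route exploits symmetry of K: one solve per electrode
pair replaces one solve per source, so leadfields for thousands of dipoles
reduce to sparse dot products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .conductivity import ConductivityModel
from .mesh import FEMesh, _GAUSS_PTS, _trilinear_dshape, boundary_vertices


class FemError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverOptions:
    relative_tolerance: float = 1e-8
    max_iterations: int = 10000
    preconditioner: str = "auto"  # "auto" | "diagonal" | "algebraic-multigrid"

    def __post_init__(self):
        if not (0 < self.relative_tolerance < 1):
            raise ValueError("relative_tolerance must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class StiffnessMatrix:
    """Sparse symmetric stiffness matrix (S) with its mesh fingerprint."""

    matrix: sp.csr_matrix
    mesh_fingerprint: str

    @property
    def shape(self):
        return self.matrix.shape


@dataclass
class TransferMatrix:
    """Dense channels x nodes operator mapping FEM right-hand sides to
    channel readings (EEG rows are potential differences to the reference)."""

    matrix: np.ndarray
    modality: str  # "eeg" | "meg"
    channel_names: list[str]
    mesh_fingerprint: str
    reference: int | None = None  # EEG reference channel index


@dataclass
class Leadfield:
    """channels x (3*n_sources) forward operator, unit dipoles of 1 A*m.

    Column triplets are x/y/z unit-moment dipoles per source.  EEG columns
    are average-referenced (V); MEG columns are coil readings (T).
    """

    matrix: np.ndarray
    modality: str
    channel_names: list[str]
    source_positions: np.ndarray

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1] // 3

    def source_block(self, j: int) -> np.ndarray:
        return self.matrix[:, 3 * j:3 * j + 3]


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def tetra_gradients(mesh: FEMesh) -> tuple[np.ndarray, np.ndarray]:
    """P1 basis gradients (M,4,3), constant per tetra, and volumes (M,)."""
    v, el = mesh.vertices, mesh.elements
    T = np.stack([v[el[:, i]] - v[el[:, 0]] for i in (1, 2, 3)], axis=1)  # rows
    vol = np.linalg.det(T) / 6.0
    Tinv = np.linalg.inv(T)  # columns of Tinv are gradients of lambda_1..3
    G = np.empty((len(el), 4, 3))
    G[:, 1:, :] = np.swapaxes(Tinv, 1, 2)
    G[:, 0, :] = -G[:, 1:, :].sum(axis=1)
    return G, vol


def assemble_stiffness(mesh: FEMesh, cond: ConductivityModel) -> StiffnessMatrix:
    """Assemble the global conductivity stiffness matrix."""
    if cond.mesh_fingerprint is not None and cond.mesh_fingerprint != mesh.fingerprint():
        raise FemError("conductivity model does not match this mesh")
    S = cond.element_tensors(mesh)
    lam = np.linalg.eigvalsh(0.5 * (S + np.swapaxes(S, 1, 2)))
    if (lam[:, 0] <= 0).any():
        bad = int(np.argmax(lam[:, 0] <= 0))
        raise FemError(f"non-SPD conductivity tensor at element {bad}")

    el = mesh.elements
    N = mesh.n_vertices
    if mesh.element_kind == "tetra4":
        G, vol = tetra_gradients(mesh)
        Ke = np.einsum("eik,ekl,ejl->eij", G, S, G) * vol[:, None, None]
        nn = 4
    else:
        X = mesh.vertices[el]
        nn = 8
        Ke = np.zeros((len(el), 8, 8))
        for g in range(8):
            dN = _trilinear_dshape(_GAUSS_PTS[g])  # (8,3)
            J = np.einsum("na,enb->eab", dN, X)
            detJ = np.linalg.det(J)
            invJ = np.linalg.inv(J)
            gx = np.einsum("eab,nb->ena", invJ, dN)
            Ke += np.einsum("eik,ekl,ejl->eij", gx, S, gx) * detJ[:, None, None]

    rows = np.repeat(el, nn, axis=1).ravel()
    cols = np.tile(el, (1, nn)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(N, N)).tocsr()
    K = 0.5 * (K + K.T)  # enforce exact symmetry
    return StiffnessMatrix(matrix=K, mesh_fingerprint=mesh.fingerprint())


# ---------------------------------------------------------------------------
# singular-Neumann solver
# ---------------------------------------------------------------------------

def _make_preconditioner(K: sp.csr_matrix, opts: SolverOptions):
    choice = opts.preconditioner
    if choice in ("auto", "algebraic-multigrid"):
        try:  # pragma: no cover - optional dependency
            import pyamg

            ml = pyamg.smoothed_aggregation_solver(K.tocsr())
            M = ml.aspreconditioner()
            return lambda r: M @ r
        except ImportError:
            if choice == "algebraic-multigrid":
                warn("pyamg unavailable; falling back to diagonal preconditioner")
    d = K.diagonal()
    d = np.where(d > 0, d, 1.0)
    return lambda r: r / d


def solve_potential(K: StiffnessMatrix, rhs: np.ndarray,
                    opts: SolverOptions = SolverOptions()) -> np.ndarray:
    """Solve K u = rhs on the mean-zero subspace (pure-Neumann problem).

    ``rhs`` may be a vector or a matrix of columns; each column must be
    compatible (zero sum).  Returned potentials have zero mean and relative
    residual below the requested tolerance.
    """
    A = K.matrix
    N = A.shape[0]
    b = np.asarray(rhs, dtype=float)
    single = b.ndim == 1
    B = b.reshape(N, -1) if not single else b.reshape(N, 1)

    sums = np.abs(B.sum(axis=0))
    scale = np.abs(B).sum(axis=0)
    bad = sums > 1e-8 * np.maximum(scale, 1e-300)
    if bad.any() and scale[bad].max() > 0:
        raise FemError(
            f"rhs column {int(np.flatnonzero(bad)[0])} violates the "
            "zero-sum compatibility condition of the Neumann problem"
        )

    prec = _make_preconditioner(A, opts)

    def project(x):
        return x - x.mean()

    Aop = spla.LinearOperator((N, N), matvec=lambda x: project(A @ project(x)))
    Mop = spla.LinearOperator((N, N), matvec=lambda r: project(prec(project(r))))

    U = np.empty_like(B)
    for j in range(B.shape[1]):
        bj = project(B[:, j])
        if np.abs(bj).max() == 0:
            U[:, j] = 0.0
            continue
        x, info = spla.cg(Aop, bj, rtol=opts.relative_tolerance, atol=0.0,
                          maxiter=opts.max_iterations, M=Mop)
        if info != 0:
            res = np.linalg.norm(A @ project(x) - bj) / np.linalg.norm(bj)
            raise FemError(
                f"CG failed to converge for rhs column {j} "
                f"(final relative residual {res:.2e})"
            )
        U[:, j] = project(x)
    return U[:, 0] if single else U


# ---------------------------------------------------------------------------
# electrodes and EEG transfer
# ---------------------------------------------------------------------------

def attach_electrodes(mesh: FEMesh, positions: np.ndarray,
                      max_distance: float = 0.02) -> sp.csr_matrix:
    """Map electrodes to their nearest scalp-boundary vertex.

    Returns the E x N restriction operator (one unit entry per row).
    Electrodes farther than ``max_distance`` (default 2 cm) from the outer
    surface are rejected; duplicate vertex assignments are warned about.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    bidx = boundary_vertices(mesh)
    tree = cKDTree(mesh.vertices[bidx])
    dist, which = tree.query(pos)
    if (dist > max_distance).any():
        far = int(np.argmax(dist))
        raise FemError(
            f"electrode {far} is {dist[far] * 100:.1f} cm from the scalp "
            f"surface (limit {max_distance * 100:.0f} cm)"
        )
    nodes = bidx[which]
    if len(np.unique(nodes)) < len(nodes):
        warn("multiple electrodes mapped to the same scalp vertex")
    E, N = len(pos), mesh.n_vertices
    R = sp.csr_matrix((np.ones(E), (np.arange(E), nodes)), shape=(E, N))
    return R


def eeg_transfer(K: StiffnessMatrix, electrodes: sp.csr_matrix,
                 opts: SolverOptions = SolverOptions(),
                 channel_names: list[str] | None = None,
                 reference: int = 0) -> TransferMatrix:
    """EEG transfer matrix: rows reproduce (electrode - reference) potential
    differences for any compatible source vector, via one solve per channel."""
    E = electrodes.shape[0]
    if E < 2:
        raise FemError("EEG transfer needs at least two electrodes")
    R = electrodes.toarray()
    others = [i for i in range(E) if i != reference]
    rhs = (R[others] - R[reference]).T  # N x (E-1)
    try:
        T = solve_potential(K, rhs, opts).T  # (E-1) x N
    except FemError as e:
        raise FemError(f"EEG transfer solve failed: {e}") from e
    names = channel_names or [f"EEG{i:03d}" for i in range(E)]
    return TransferMatrix(
        matrix=T, modality="eeg", channel_names=list(names),
        mesh_fingerprint=K.mesh_fingerprint, reference=reference,
    )


def _average_reference(L: np.ndarray) -> np.ndarray:
    return L - L.mean(axis=0, keepdims=True)


def eeg_leadfield(transfer: TransferMatrix, rhs_matrix,
                  source_positions: np.ndarray | None = None) -> Leadfield:
    """Average-referenced EEG leadfield from transfer rows and source RHS."""
    B = rhs_matrix
    if transfer.matrix.shape[1] != B.shape[0]:
        raise FemError("transfer matrix and rhs matrix shapes do not match")
    diffs = np.asarray(transfer.matrix @ B)
    E = diffs.shape[0] + 1
    ref = transfer.reference if transfer.reference is not None else 0
    full = np.zeros((E, diffs.shape[1]))
    rows = [i for i in range(E) if i != ref]
    full[rows] = diffs
    full = _average_reference(full)
    if source_positions is None:
        source_positions = np.zeros((diffs.shape[1] // 3, 3))
    return Leadfield(
        matrix=full, modality="eeg",
        channel_names=transfer.channel_names,
        source_positions=np.asarray(source_positions),
    )


def eeg_leadfield_direct(K: StiffnessMatrix, electrodes: sp.csr_matrix,
                         rhs_matrix, opts: SolverOptions = SolverOptions(),
                         source_positions: np.ndarray | None = None) -> Leadfield:
    """Reference route: one full FEM solve per source column, then electrode
    restriction and average reference.  Used to validate the transfer route."""
    B = rhs_matrix.toarray() if sp.issparse(rhs_matrix) else np.asarray(rhs_matrix)
    U = solve_potential(K, B, opts)
    L = _average_reference(electrodes @ U)
    if source_positions is None:
        source_positions = np.zeros((B.shape[1] // 3, 3))
    E = electrodes.shape[0]
    return Leadfield(
        matrix=np.asarray(L), modality="eeg",
        channel_names=[f"EEG{i:03d}" for i in range(E)],
        source_positions=np.asarray(source_positions),
    )
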