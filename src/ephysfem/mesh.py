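"""Volumetric finite-element meshes for head volume conductors.

Provides the labeled-mesh data model (:class:`FEMesh`), a nested-sphere
tetrahedral mesh generator used as the standard validation fixture, a
voxel-to-hexahedron converter (with optional interface node shifting to
smooth the voxel staircase), geometric queries, and mesh editing
(plane resection, e.g. for cutting away neck/shoulders or defacing).

All coordinates are stored in meters; file readers that consume mm-based
formats convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree


class MeshError(ValueError):
    """Invalid mesh construction or query argument."""


# ---------------------------------------------------------------------------
# tissue table
# ---------------------------------------------------------------------------

SCALP, SKULL, CSF, GM, WM = 1, 2, 3, 4, 5


@dataclass(frozen=True)
class TissueTable:
    """Ordered map tissue_id -> (name, default conductivity in S/m)."""

    entries: tuple[tuple[int, str, float], ...]

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise MeshError("duplicate tissue ids in table")
        if any(i <= 0 for i in ids):
            raise MeshError("tissue ids must be strictly positive")

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(e[0] for e in self.entries)

    def __contains__(self, tissue_id: int) -> bool:
        return tissue_id in self.ids

    def name(self, tissue_id: int) -> str:
        for tid, nm, _ in self.entries:
            if tid == tissue_id:
                return nm
        raise KeyError(tissue_id)

    def conductivity(self, tissue_id: int) -> float:
        for tid, _, sig in self.entries:
            if tid == tissue_id:
                return sig
        raise KeyError(tissue_id)

    def conductivities(self) -> dict[int, float]:
        return {tid: sig for tid, _, sig in self.entries}


#: Standard five-compartment head tissue defaults (S/m).
DEFAULT_TISSUES = TissueTable(
    entries=(
        (SCALP, "scalp", 0.43),
        (SKULL, "skull", 0.01),
        (CSF, "csf", 1.79),
        (GM, "gm", 0.33),
        (WM, "wm", 0.14),
    )
)


@dataclass(frozen=True)
class CutPlane:
    """Oriented plane; resection keeps the half-space the normal points into."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        nrm = np.linalg.norm(n)
        if abs(nrm - 1.0) > 1e-12:
            if nrm == 0:
                raise MeshError("cut plane normal must be nonzero")
            n = n / nrm
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

# gmsh/VTK hexahedron corner ordering relative to the unit voxel
_HEX_OFFSETS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=np.int64,
)

# 2x2x2 Gauss points on [-1,1]^3 and trilinear shape-function derivatives
_G = 1.0 / np.sqrt(3.0)
_GAUSS_PTS = np.array(
    [[sx * _G, sy * _G, sz * _G] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)
_HEX_CORNERS_REF = 2.0 * _HEX_OFFSETS - 1.0  # reference corners in [-1,1]^3


def _trilinear_shape(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_i(xi) for the 8 hex corners, shape (...,8)."""
    xi = np.asarray(xi, dtype=float)
    c = _HEX_CORNERS_REF  # (8,3)
    return (
        (1 + xi[..., None, 0] * c[:, 0])
        * (1 + xi[..., None, 1] * c[:, 1])
        * (1 + xi[..., None, 2] * c[:, 2])
        / 8.0
    )


def _trilinear_dshape(xi: np.ndarray) -> np.ndarray:
    """d N_i / d xi_a at points xi, shape (...,8,3)."""
    xi = np.asarray(xi, dtype=float)
    c = _HEX_CORNERS_REF
    out = np.empty(xi.shape[:-1] + (8, 3))
    t0 = 1 + xi[..., None, 0] * c[:, 0]
    t1 = 1 + xi[..., None, 1] * c[:, 1]
    t2 = 1 + xi[..., None, 2] * c[:, 2]
    out[..., 0] = c[:, 0] * t1 * t2 / 8.0
    out[..., 1] = c[:, 1] * t0 * t2 / 8.0
    out[..., 2] = c[:, 2] * t0 * t1 / 8.0
    return out


@dataclass
class FEMesh:
    """Labeled volumetric FE mesh (tetra4 or hexa8), coordinates in meters."""

    vertices: np.ndarray
    elements: np.ndarray
    element_kind: str  # "tetra4" | "hexa8"
    labels: np.ndarray
    tissue_table: TissueTable = DEFAULT_TISSUES
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int64)
        if self.element_kind not in ("tetra4", "hexa8"):
            raise MeshError(f"unknown element kind {self.element_kind!r}")
        k = 4 if self.element_kind == "tetra4" else 8
        if self.elements.ndim != 2 or self.elements.shape[1] != k:
            raise MeshError(f"{self.element_kind} elements must be Mx{k}")
        if self.labels.shape != (self.elements.shape[0],):
            raise MeshError("labels must be one per element")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.vertices)
        ):
            raise MeshError("element vertex index out of range")
        srt = np.sort(self.elements, axis=1)
        if self.elements.size and np.any(srt[:, 1:] == srt[:, :-1]):
            raise MeshError("duplicate vertex within an element")
        for lab in np.unique(self.labels):
            if int(lab) not in self.tissue_table:
                raise MeshError(f"label {lab} not in tissue table")
        if self.element_kind == "tetra4":
            if self.elements.size and element_volumes(self).min() <= 0:
                raise MeshError("tetra with nonpositive signed volume")
        else:
            if self.elements.size and hex_corner_jacobians(self).min() <= 0:
                raise MeshError("hexa with nonpositive corner Jacobian")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def fingerprint(self) -> str:
        """Content hash used for mesh/operator consistency checks."""
        if "fingerprint" not in self._cache:
            import hashlib

            h = hashlib.sha256()
            h.update(self.element_kind.encode())
            h.update(np.ascontiguousarray(self.vertices).tobytes())
            h.update(np.ascontiguousarray(self.elements).tobytes())
            h.update(np.ascontiguousarray(self.labels).tobytes())
            self._cache["fingerprint"] = h.hexdigest()[:16]
        return self._cache["fingerprint"]

    def centroid(self) -> np.ndarray:
        """Volume-weighted barycenter of the whole mesh."""
        v = element_volumes(self)
        b = element_barycenters(self)
        return (v[:, None] * b).sum(axis=0) / v.sum()

    def outer_radius(self) -> float:
        return float(np.linalg.norm(self.vertices - self.centroid(), axis=1).max())


def fix_tetra_orientation(elements: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Swap two vertices of negatively oriented tetrahedra (repair on load)."""
    el = np.array(elements, dtype=np.int64, copy=True)
    v = np.asarray(vertices, dtype=float)
    a = v[el[:, 1]] - v[el[:, 0]]
    b = v[el[:, 2]] - v[el[:, 0]]
    c = v[el[:, 3]] - v[el[:, 0]]
    vol6 = np.einsum("ij,ij->i", np.cross(a, b), c)
    bad = vol6 < 0
    el[bad, 1], el[bad, 2] = el[bad, 2].copy(), el[bad, 1].copy()
    return el


def element_volumes(mesh: FEMesh) -> np.ndarray:
    """Signed (tetra) / quadrature (hexa) element volumes in m^3."""
    v, el = mesh.vertices, mesh.elements
    if mesh.element_kind == "tetra4":
        a = v[el[:, 1]] - v[el[:, 0]]
        b = v[el[:, 2]] - v[el[:, 0]]
        c = v[el[:, 3]] - v[el[:, 0]]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0
    X = v[el]  # (M,8,3)
    vol = np.zeros(len(el))
    for g in range(8):
        dN = _trilinear_dshape(_GAUSS_PTS[g])  # (8,3)
        J = np.einsum("na,enb->eab", dN, X)
        vol += np.linalg.det(J)
    return vol


def hex_corner_jacobians(mesh: FEMesh) -> np.ndarray:
    """det J of the trilinear map at every hexa corner, shape (M,8)."""
    X = mesh.vertices[mesh.elements]
    out = np.empty((len(X), 8))
    for c in range(8):
        dN = _trilinear_dshape(_HEX_CORNERS_REF[c])
        J = np.einsum("na,enb->eab", dN, X)
        out[:, c] = np.linalg.det(J)
    return out


def element_barycenters(mesh: FEMesh) -> np.ndarray:
    return mesh.vertices[mesh.elements].mean(axis=1)


def mean_edge_length(mesh: FEMesh) -> float:
    el = mesh.elements
    if mesh.element_kind == "tetra4":
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    else:
        pairs = [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7), (7, 4),
                 (0, 4), (1, 5), (2, 6), (3, 7)]
    e = np.concatenate([el[:, [i, j]] for i, j in pairs])
    e = np.unique(np.sort(e, axis=1), axis=0)
    d = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    return float(d.mean())


# ---------------------------------------------------------------------------
# nested-sphere fixture generator
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = (1 + np.sqrt(5.0)) / 2
    theta = 2 * np.pi * i / phi
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def build_nested_sphere_mesh(
    radii,
    tissue_ids,
    target_edge_length: float,
    seed: int = 0,
    tissue_table: TissueTable = DEFAULT_TISSUES,
) -> FEMesh:
    """Tetrahedral mesh of a ball made of concentric shells.

    ``radii`` are strictly decreasing shell radii in meters, outermost first;
    ``tissue_ids[i]`` labels the shell between ``radii[i]`` and ``radii[i+1]``
    (the last id fills the innermost ball).  Points are seeded on each shell
    surface plus a jittered interior grid, then tetrahedralized (Delaunay of a
    convex point set covers the ball); each element is labeled by the tissue
    of the innermost sphere containing its barycenter.
    """
    radii = [float(r) for r in radii]
    tissue_ids = [int(t) for t in tissue_ids]
    if len(radii) != len(tissue_ids):
        raise MeshError("radii and tissue_ids must have equal length")
    if any(r2 >= r1 for r1, r2 in zip(radii, radii[1:])) or radii[-1] <= 0:
        raise MeshError("radii must be strictly decreasing and positive")
    h = float(target_edge_length)
    gaps = [r1 - r2 for r1, r2 in zip(radii, radii[1:])] + [radii[-1]]
    if h > min(gaps) * 2.5:
        raise MeshError(
            f"target edge length {h} too coarse to resolve a shell "
            f"(min gap {min(gaps)})"
        )
    R = radii[0]
    rng = np.random.default_rng(seed)

    pts = []
    # shell surface points, spacing ~ h (hex-packing area per point)
    for r in radii:
        n = max(14, int(round(4 * np.pi * r * r / (0.866 * h * h))))
        pts.append(_fibonacci_sphere(n) * r)
    # interior body-centered-cubic lattice (Delaunay of BCC points gives
    # well-shaped tetrahedra), lightly jittered, kept clear of the shells
    ax = np.arange(-R, R + 0.5 * h, h)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    cubic = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    grid = np.concatenate([cubic, cubic + 0.5 * h])
    grid = grid + rng.uniform(-0.03 * h, 0.03 * h, size=grid.shape)
    rad = np.linalg.norm(grid, axis=1)
    keep = rad <= R - 0.45 * h
    for r in radii[1:]:
        keep &= np.abs(rad - r) >= 0.45 * h
    pts.append(grid[keep])
    pts = np.concatenate(pts)

    tri = Delaunay(pts)
    el = fix_tetra_orientation(tri.simplices, pts)
    # drop slivers (flat boundary tets contribute ~nothing)
    a = pts[el[:, 1]] - pts[el[:, 0]]
    b = pts[el[:, 2]] - pts[el[:, 0]]
    c = pts[el[:, 3]] - pts[el[:, 0]]
    vol = np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0
    el = el[vol > 1e-6 * h**3]

    bc = pts[el].mean(axis=1)
    br = np.linalg.norm(bc, axis=1)
    labels = np.full(len(el), tissue_ids[0], dtype=np.int64)
    for r, tid in zip(radii, tissue_ids):
        labels[br <= r] = tid  # innermost containing sphere wins

    # compact unused vertices (sliver removal may orphan none/few)
    used, inv = np.unique(el, return_inverse=True)
    mesh = FEMesh(
        vertices=pts[used],
        elements=inv.reshape(el.shape),
        element_kind="tetra4",
        labels=labels,
        tissue_table=tissue_table,
    )
    return mesh


# ---------------------------------------------------------------------------
# voxels -> hexahedra
# ---------------------------------------------------------------------------

def voxels_to_hex(
    labels: np.ndarray,
    affine: np.ndarray,
    node_shift: float = 0.0,
    tissue_table: TissueTable = DEFAULT_TISSUES,
) -> FEMesh:
    """One hexahedron per nonzero voxel; shared corners merged.

    ``affine`` maps 0-based voxel indices to world mm (NIfTI/RAS convention);
    output coordinates are meters.  With ``node_shift`` > 0, vertices lying on
    an interface between two different nonzero tissues are pulled toward the
    centroid of the adjacent voxel centers of the locally dominant tissue by
    that fraction, smoothing the voxel staircase while keeping all trilinear
    Jacobians positive for shifts <= 0.49.
    """
    labels = np.asarray(labels)
    affine = np.asarray(affine, dtype=float)
    if labels.ndim != 3 or labels.min() < 0:
        raise MeshError("labels must be a nonnegative 3-D integer volume")
    if not (0.0 <= node_shift <= 0.49):
        raise MeshError("node_shift must lie in [0, 0.49]")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-30:
        raise MeshError("affine is singular")

    vox = np.argwhere(labels > 0)
    if len(vox) == 0:
        raise MeshError("no nonzero voxels")
    # corner lattice ids
    shape = labels.shape
    dims = (shape[0] + 1, shape[1] + 1, shape[2] + 1)
    corners = vox[:, None, :] + _HEX_OFFSETS[None, :, :]  # (M,8,3)
    keys = np.ravel_multi_index(
        (corners[..., 0], corners[..., 1], corners[..., 2]), dims
    )
    uniq, inv = np.unique(keys, return_inverse=True)
    el = inv.reshape(-1, 8)
    ci, cj, ck = np.unravel_index(uniq, dims)
    ijk = np.column_stack([ci, cj, ck]).astype(float) - 0.5  # voxel corners
    verts_mm = ijk @ affine[:3, :3].T + affine[:3, 3]
    verts = verts_mm / 1000.0

    if np.linalg.det(affine[:3, :3]) < 0:
        # mirror-flip node order to keep positive Jacobians
        el = el[:, [3, 2, 1, 0, 7, 6, 5, 4]]

    if node_shift > 0:
        verts = _apply_node_shift(verts, uniq, dims, labels, affine, node_shift)

    return FEMesh(
        vertices=verts,
        elements=el,
        element_kind="hexa8",
        labels=labels[vox[:, 0], vox[:, 1], vox[:, 2]].astype(np.int64),
        tissue_table=tissue_table,
    )


def _apply_node_shift(verts, corner_keys, dims, labels, affine, shift):
    verts = verts.copy()
    shape = labels.shape
    ci, cj, ck = np.unravel_index(corner_keys, dims)
    for idx in range(len(corner_keys)):
        i, j, k = int(ci[idx]), int(cj[idx]), int(ck[idx])
        adj = []
        for di, dj, dk in _HEX_OFFSETS - 1:
            ii, jj, kk = i + di, j + dj, k + dk
            if 0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]:
                lab = int(labels[ii, jj, kk])
                if lab > 0:
                    adj.append((lab, ii, jj, kk))
        labs = [a[0] for a in adj]
        if len(set(labs)) < 2:
            continue  # interior of one tissue (or boundary with background)
        # dominant tissue: most adjacent voxels, ties -> smallest id
        counts = {}
        for lab in labs:
            counts[lab] = counts.get(lab, 0) + 1
        dom = min(counts, key=lambda t: (-counts[t], t))
        centers = np.array(
            [(ii, jj, kk) for lab, ii, jj, kk in adj if lab == dom], dtype=float
        )
        cent_mm = centers @ affine[:3, :3].T + affine[:3, 3]
        target = cent_mm.mean(axis=0) / 1000.0
        verts[idx] = verts[idx] + shift * (target - verts[idx])
    return verts


# ---------------------------------------------------------------------------
# point location
# ---------------------------------------------------------------------------

def _tet_bary_setup(mesh: FEMesh):
    if "tet_inv" not in mesh._cache:
        v, el = mesh.vertices, mesh.elements
        T = np.stack(
            [v[el[:, i]] - v[el[:, 0]] for i in (1, 2, 3)], axis=2
        )  # (M,3,3) columns = edge vectors
        mesh._cache["tet_inv"] = np.linalg.inv(T)
        mesh._cache["tet_v0"] = v[el[:, 0]]
    return mesh._cache["tet_inv"], mesh._cache["tet_v0"]


def _bary_coords(mesh: FEMesh, point: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of point w.r.t. tetra subset idx, shape (len(idx),4)."""
    inv, v0 = _tet_bary_setup(mesh)
    lam = np.einsum("eij,ej->ei", inv[idx], point - v0[idx])
    return np.column_stack([1 - lam.sum(axis=1), lam])


_INSIDE_TOL = -1e-12  # barycentric tolerance: face-adjacent points stay inside


def _element_tree(mesh: FEMesh) -> cKDTree:
    if "bc_tree" not in mesh._cache:
        mesh._cache["bc_tree"] = cKDTree(element_barycenters(mesh))
    return mesh._cache["bc_tree"]


def _point_in_hex(mesh: FEMesh, point: np.ndarray, e: int) -> bool:
    X = mesh.vertices[mesh.elements[e]]
    xi = np.zeros(3)
    for _ in range(30):
        r = _trilinear_shape(xi) @ X - point
        if np.linalg.norm(r) < 1e-14:
            break
        J = np.einsum("na,nb->ab", _trilinear_dshape(xi), X)
        try:
            xi = xi - np.linalg.solve(J.T, r)
        except np.linalg.LinAlgError:
            return False
        if np.abs(xi).max() > 3:
            return False
    return bool(np.abs(xi).max() <= 1 + 1e-9)


def locate_point(mesh: FEMesh, point) -> int | None:
    """Index of an element whose closed hull contains ``point`` (lowest index
    on shared faces), or ``None`` if the point is outside the mesh."""
    point = np.asarray(point, dtype=float).reshape(3)
    tree = _element_tree(mesh)
    k = min(32, mesh.n_elements)
    _, cand = tree.query(point, k=k)
    cand = np.atleast_1d(cand)
    if mesh.element_kind == "tetra4":
        lam = _bary_coords(mesh, point, cand)
        ok = cand[(lam >= _INSIDE_TOL).all(axis=1)]
        if len(ok):
            return int(ok.min())
        # exhaustive fallback (vectorized over all elements)
        all_idx = np.arange(mesh.n_elements)
        lam = _bary_coords(mesh, point, all_idx)
        ok = all_idx[(lam >= _INSIDE_TOL).all(axis=1)]
        return int(ok.min()) if len(ok) else None
    for e in sorted(int(c) for c in cand):
        if _point_in_hex(mesh, point, e):
            return e
    for e in range(mesh.n_elements):
        if _point_in_hex(mesh, point, e):
            return e
    return None


# ---------------------------------------------------------------------------
# resection
# ---------------------------------------------------------------------------

def resect_mesh(mesh: FEMesh, plane: CutPlane) -> FEMesh:
    """Keep elements whose barycenter lies on the normal side of the plane."""
    bc = element_barycenters(mesh)
    keep = (bc - plane.point) @ plane.normal >= 0
    if not keep.any():
        raise MeshError("resection removed every element")
    el = mesh.elements[keep]
    used, inv = np.unique(el, return_inverse=True)
    return FEMesh(
        vertices=mesh.vertices[used],
        elements=inv.reshape(el.shape),
        element_kind=mesh.element_kind,
        labels=mesh.labels[keep],
        tissue_table=mesh.tissue_table,
    )


# ---------------------------------------------------------------------------
# quality
# ---------------------------------------------------------------------------

_TET_FACES = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]  # face i opposite vertex i
_TET_EDGE_FACES = {  # edge (i,j) shared by the two faces opposite its other vertices
    (0, 1): (2, 3), (0, 2): (1, 3), (0, 3): (1, 2),
    (1, 2): (0, 3), (1, 3): (0, 2), (2, 3): (0, 1),
}


def mesh_quality(mesh: FEMesh) -> dict[str, np.ndarray]:
    """Per-element quality: volume (m^3), min dihedral angle (deg),
    radius-edge ratio (circumradius / shortest edge)."""
    v, el = mesh.vertices, mesh.elements
    vol = element_volumes(mesh)
    if mesh.element_kind == "tetra4":
        X = v[el]  # (M,4,3)
        normals = np.empty((len(el), 4, 3))
        for f, (a, b, c) in enumerate(_TET_FACES):
            n = np.cross(X[:, b] - X[:, a], X[:, c] - X[:, a])
            normals[:, f] = n / np.maximum(
                np.linalg.norm(n, axis=1, keepdims=True), 1e-300
            )
        min_dih = np.full(len(el), np.inf)
        for (fa, fb) in _TET_EDGE_FACES.values():
            # outward face normals -> dihedral = pi - angle(normals)
            cosang = np.einsum("ij,ij->i", normals[:, fa], normals[:, fb])
            ang = np.pi - np.arccos(np.clip(cosang, -1, 1))
            min_dih = np.minimum(min_dih, ang)
        # circumradius via |x-v0|^2 = |x-vi|^2
        A = 2 * (X[:, 1:] - X[:, :1])  # (M,3,3)
        rhs = (X[:, 1:] ** 2).sum(axis=2) - (X[:, :1] ** 2).sum(axis=2)
        center = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
        circ = np.linalg.norm(center - X[:, 0], axis=1)
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    else:
        X = v[el]  # (M,8,3)
        # planar-approximation face normals via corner averaging
        faces = [(0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
                 (2, 3, 7, 6), (1, 2, 6, 5), (0, 4, 7, 3)]
        normals = np.empty((len(el), 6, 3))
        for f, (a, b, c, d) in enumerate(faces):
            n = np.cross(X[:, c] - X[:, a], X[:, d] - X[:, b])
            normals[:, f] = n / np.maximum(
                np.linalg.norm(n, axis=1, keepdims=True), 1e-300
            )
        adj = [(0, 2), (0, 3), (0, 4), (0, 5), (1, 2), (1, 3),
               (1, 4), (1, 5), (2, 4), (2, 5), (3, 4), (3, 5)]
        min_dih = np.full(len(el), np.inf)
        for fa, fb in adj:
            cosang = np.einsum("ij,ij->i", normals[:, fa], normals[:, fb])
            ang = np.pi - np.arccos(np.clip(cosang, -1, 1))
            min_dih = np.minimum(min_dih, ang)
        ctr = X.mean(axis=1)
        circ = np.linalg.norm(X - ctr[:, None, :], axis=2).max(axis=1)
        edges = [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7), (7, 4),
                 (0, 4), (1, 5), (2, 6), (3, 7)]
    elen = np.stack(
        [np.linalg.norm(v[el[:, i]] - v[el[:, j]], axis=1) for i, j in edges]
    )
    min_edge = elen.min(axis=0)
    return {
        "volume": vol,
        "min_dihedral_deg": np.degrees(min_dih),
        "radius_edge_ratio": circ / np.maximum(min_edge, 1e-300),
    }


# ---------------------------------------------------------------------------
# boundary extraction
# ---------------------------------------------------------------------------

def boundary_vertices(mesh: FEMesh) -> np.ndarray:
    """Indices of vertices on the outer boundary (faces used exactly once)."""
    if "boundary_vertices" in mesh._cache:
        return mesh._cache["boundary_vertices"]
    el = mesh.elements
    if mesh.element_kind == "tetra4":
        face_sets = _TET_FACES
    else:
        face_sets = [(0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
                     (2, 3, 7, 6), (1, 2, 6, 5), (0, 4, 7, 3)]
    faces = np.concatenate([el[:, list(f)] for f in face_sets])
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    bidx = np.unique(faces[counts[inv] == 1])
    mesh._cache["boundary_vertices"] = bidx
    return bidx
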