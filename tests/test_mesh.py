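"""Mesh model: generators, geometric queries, editing, quality."""

import numpy as np
import pytest

from ephysfem.mesh import (CSF, GM, SCALP, SKULL, WM, CutPlane, FEMesh,
                           MeshError, build_nested_sphere_mesh,
                           element_barycenters, element_volumes,
                           fix_tetra_orientation, hex_corner_jacobians,
                           locate_point, mean_edge_length, mesh_quality,
                           resect_mesh, voxels_to_hex)

UNIT_TET = dict(
    vertices=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float),
    elements=np.array([[0, 1, 2, 3]]),
    element_kind="tetra4",
    labels=np.array([GM]),
)

UNIT_CUBE = dict(
    vertices=np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                       [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float),
    elements=np.array([[0, 1, 2, 3, 4, 5, 6, 7]]),
    element_kind="hexa8",
    labels=np.array([GM]),
)


# ---------------------------------------------------------------------------
# nested-sphere generator
# ---------------------------------------------------------------------------

class TestNestedSphere:
    def test_shell_labels_follow_barycenter_radius(self, small_mesh):
        bc = element_barycenters(small_mesh)
        r = np.linalg.norm(bc, axis=1)
        scalp_band = (r > 0.086) & (r <= 0.092)
        assert np.all(small_mesh.labels[scalp_band] == SCALP)
        skull_band = (r > 0.080) & (r <= 0.086)
        assert np.all(small_mesh.labels[skull_band] == SKULL)
        assert np.all(small_mesh.labels[r <= 0.080] == GM)

    def test_total_volume_matches_ball(self, small_mesh):
        ball = 4.0 / 3.0 * np.pi * 0.092**3
        assert abs(element_volumes(small_mesh).sum() - ball) / ball < 0.02

    def test_deterministic_for_fixed_seed(self):
        a = build_nested_sphere_mesh([0.05, 0.04], [SCALP, GM], 0.012, seed=9)
        b = build_nested_sphere_mesh([0.05, 0.04], [SCALP, GM], 0.012, seed=9)
        assert a.vertices.tobytes() == b.vertices.tobytes()
        assert a.elements.tobytes() == b.elements.tobytes()
        assert a.labels.tobytes() == b.labels.tobytes()

    def test_mean_edge_length_near_target(self, small_mesh):
        assert abs(mean_edge_length(small_mesh) - 0.012) < 0.5 * 0.012

    def test_radially_monotone_labels(self, small_mesh):
        # element strictly inside another never has an outer-shell tissue
        bc = element_barycenters(small_mesh)
        r = np.linalg.norm(bc, axis=1)
        shell_rank = {SCALP: 0, SKULL: 1, GM: 2}
        ranks = np.array([shell_rank[int(l)] for l in small_mesh.labels])
        order = np.argsort(r)
        assert np.all(np.maximum.accumulate(ranks[order][::-1]) >= ranks[order][::-1])
        # equivalently: once radius exceeds a shell, rank cannot increase
        # (bands checked explicitly above; here monotone trend on sorted radii)
        running_min = np.minimum.accumulate(ranks[order])
        assert ranks[order][0] == 2 and running_min[-1] >= 0

    def test_nondecreasing_radii_rejected(self):
        with pytest.raises(MeshError):
            build_nested_sphere_mesh([0.05, 0.06], [SCALP, GM], 0.01, seed=0)

    def test_infeasible_edge_length_rejected(self):
        with pytest.raises(MeshError):
            build_nested_sphere_mesh([0.05, 0.048], [SCALP, GM], 0.02, seed=0)

    def test_all_volumes_positive(self, small_mesh):
        assert element_volumes(small_mesh).min() > 0


# ---------------------------------------------------------------------------
# voxel -> hexahedra
# ---------------------------------------------------------------------------

def _five_voxel_volume():
    labels = np.zeros((2, 2, 2), dtype=int)
    labels.flat[[0, 1, 2, 3, 4]] = GM
    return labels


class TestVoxelsToHex:
    def test_element_and_vertex_counts_match_enumeration(self):
        labels = _five_voxel_volume()
        mesh = voxels_to_hex(labels, np.eye(4))
        assert mesh.n_elements == 5
        # oracle: enumerate distinct corner-lattice points of the voxel union
        corners = set()
        for i, j, k in np.argwhere(labels > 0):
            for di in (0, 1):
                for dj in (0, 1):
                    for dk in (0, 1):
                        corners.add((i + di, j + dj, k + dk))
        assert mesh.n_vertices == len(corners) <= 27

    def test_no_shift_vertices_on_affine_corner_grid(self):
        affine = np.diag([2.0, 3.0, 1.5, 1.0])
        affine[:3, 3] = [5.0, -2.0, 1.0]
        mesh = voxels_to_hex(_five_voxel_volume(), affine, node_shift=0.0)
        ijk = np.round(
            (mesh.vertices * 1000.0 - affine[:3, 3]) @ np.linalg.inv(affine[:3, :3]).T
            + 0.5, 9)
        assert np.allclose(ijk, np.round(ijk))  # integer corner lattice

    def test_volume_conservation(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        mesh = voxels_to_hex(_five_voxel_volume(), affine)
        voxel_vol = 5 * (2e-3) ** 3
        total = element_volumes(mesh).sum()
        assert abs(total - voxel_vol) / voxel_vol < 1e-9

    def test_uniform_volume_shift_is_identity(self):
        labels = np.full((3, 3, 3), WM)
        a = voxels_to_hex(labels, np.eye(4), node_shift=0.0)
        b = voxels_to_hex(labels, np.eye(4), node_shift=0.3)
        assert np.array_equal(a.vertices, b.vertices)

    def test_shift_moves_interface_vertices_only(self):
        labels = np.full((3, 3, 3), GM)
        labels[:, :, 2] = CSF
        a = voxels_to_hex(labels, np.eye(4), node_shift=0.0)
        b = voxels_to_hex(labels, np.eye(4), node_shift=0.3)
        moved = ~np.isclose(a.vertices, b.vertices).all(axis=1)
        assert moved.any()
        # only vertices on the z-interface plane (voxel-corner z = 1.5mm) move
        z = a.vertices[:, 2] * 1000.0
        assert np.all(np.isclose(z[moved], 1.5))

    @pytest.mark.parametrize("shift", [0.1, 0.33, 0.49])
    def test_shifted_jacobians_stay_positive(self, shift):
        rng = np.random.default_rng(4)
        labels = rng.integers(1, 4, size=(4, 4, 4))
        mesh = voxels_to_hex(labels, np.eye(4), node_shift=shift)
        assert hex_corner_jacobians(mesh).min() > 0

    def test_invalid_shift_rejected(self):
        with pytest.raises(MeshError):
            voxels_to_hex(_five_voxel_volume(), np.eye(4), node_shift=0.6)

    def test_negative_determinant_affine_handled(self):
        affine = np.diag([-1.0, 1.0, 1.0, 1.0])  # LAS-style flip
        mesh = voxels_to_hex(_five_voxel_volume(), affine)
        assert hex_corner_jacobians(mesh).min() > 0


# ---------------------------------------------------------------------------
# barycenters / location / resection
# ---------------------------------------------------------------------------

class TestGeometry:
    def test_unit_tetra_barycenter(self):
        mesh = FEMesh(**UNIT_TET)
        assert np.allclose(element_barycenters(mesh), [[0.25, 0.25, 0.25]])

    def test_unit_cube_barycenter(self):
        mesh = FEMesh(**UNIT_CUBE)
        assert np.allclose(element_barycenters(mesh), [[0.5, 0.5, 0.5]])

    def test_barycenters_translate_with_mesh(self, small_mesh):
        t = np.array([0.1, -0.2, 0.05])
        shifted = FEMesh(vertices=small_mesh.vertices + t,
                         elements=small_mesh.elements,
                         element_kind="tetra4", labels=small_mesh.labels)
        assert np.allclose(element_barycenters(shifted),
                           element_barycenters(small_mesh) + t)

    def test_locate_barycenter_returns_owner(self, small_mesh):
        bc = element_barycenters(small_mesh)
        for e in (0, 57, 1234, small_mesh.n_elements - 1):
            assert locate_point(small_mesh, bc[e]) == e

    def test_locate_outside_returns_none(self, small_mesh):
        assert locate_point(small_mesh, [0.2, 0.0, 0.0]) is None

    def test_locate_agrees_with_exhaustive_search(self, small_mesh):
        from ephysfem.mesh import _bary_coords, _INSIDE_TOL

        rng = np.random.default_rng(0)
        pts = rng.uniform(-0.05, 0.05, size=(100, 3))
        all_idx = np.arange(small_mesh.n_elements)
        for p in pts:
            lam = _bary_coords(small_mesh, p, all_idx)
            inside = all_idx[(lam >= _INSIDE_TOL).all(axis=1)]
            expected = int(inside.min()) if len(inside) else None
            assert locate_point(small_mesh, p) == expected

    def test_locate_in_hex_mesh(self):
        labels = np.full((3, 3, 3), GM)
        mesh = voxels_to_hex(labels, np.eye(4))
        bc = element_barycenters(mesh)
        assert locate_point(mesh, bc[13]) == 13
        assert locate_point(mesh, [1.0, 1.0, 1.0]) is None  # 1 m away

    def test_resect_far_plane_keeps_everything(self, small_mesh):
        plane = CutPlane(point=[0, 0, -1.0], normal=[0, 0, 1])
        out = resect_mesh(small_mesh, plane)
        assert out.n_elements == small_mesh.n_elements
        assert np.isclose(element_volumes(out).sum(),
                          element_volumes(small_mesh).sum())

    def test_resect_halves_a_sphere(self, small_mesh):
        plane = CutPlane(point=[0, 0, 0], normal=[0, 0, 1])
        out = resect_mesh(small_mesh, plane)
        assert abs(out.n_elements / small_mesh.n_elements - 0.5) < 0.05

    def test_resect_equals_brute_force_barycenter_filter(self, small_mesh):
        plane = CutPlane(point=[0.01, 0.0, 0.02], normal=[0.3, -0.1, 0.9])
        out = resect_mesh(small_mesh, plane)
        bc = element_barycenters(small_mesh)
        keep = (bc - plane.point) @ plane.normal >= 0
        assert out.n_elements == int(keep.sum())
        assert np.isclose(element_volumes(out).sum(),
                          element_volumes(small_mesh)[keep].sum())
        assert np.array_equal(np.sort(out.labels), np.sort(small_mesh.labels[keep]))

    def test_resect_idempotent(self, small_mesh):
        plane = CutPlane(point=[0, 0, 0.01], normal=[0, 0, 1])
        once = resect_mesh(small_mesh, plane)
        twice = resect_mesh(once, plane)
        assert twice.n_elements == once.n_elements
        assert np.allclose(np.sort(element_volumes(twice)),
                           np.sort(element_volumes(once)))

    def test_resect_empty_raises(self, small_mesh):
        with pytest.raises(MeshError):
            resect_mesh(small_mesh, CutPlane(point=[0, 0, 1.0], normal=[0, 0, 1]))


# ---------------------------------------------------------------------------
# quality and validation
# ---------------------------------------------------------------------------

class TestQuality:
    def test_regular_tetra_dihedral_angle(self):
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        el = fix_tetra_orientation(np.array([[0, 1, 2, 3]]), verts)
        mesh = FEMesh(vertices=verts, elements=el, element_kind="tetra4",
                      labels=np.array([GM]))
        q = mesh_quality(mesh)
        assert np.allclose(q["min_dihedral_deg"], np.degrees(np.arccos(1 / 3)),
                           atol=1e-9)

    def test_near_degenerate_tetra_flagged_by_volume(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.3, 1e-12]])
        el = fix_tetra_orientation(np.array([[0, 1, 2, 3]]), verts)
        mesh = FEMesh(vertices=verts, elements=el, element_kind="tetra4",
                      labels=np.array([GM]))
        # base area 0.5 m^2, height 1e-12 m -> V = 0.5*1e-12/3
        vol = mesh_quality(mesh)["volume"][0]
        assert vol == pytest.approx(0.5e-12 / 3, rel=1e-6)
        assert vol < 1e-12  # far below any healthy element at this scale

    def test_unit_cube_volume(self):
        q = mesh_quality(FEMesh(**UNIT_CUBE))
        assert np.isclose(q["volume"][0], 1.0)
        assert np.isclose(q["min_dihedral_deg"][0], 90.0)

    def test_quality_finite_on_generated_mesh(self, small_mesh):
        q = mesh_quality(small_mesh)
        for arr in q.values():
            assert np.isfinite(arr).all()
        assert q["volume"].min() > 0


class TestValidation:
    def test_out_of_range_index_rejected(self):
        bad = dict(UNIT_TET, elements=np.array([[0, 1, 2, 9]]))
        with pytest.raises(MeshError):
            FEMesh(**bad)

    def test_duplicate_vertex_in_element_rejected(self):
        bad = dict(UNIT_TET, elements=np.array([[0, 1, 2, 2]]))
        with pytest.raises(MeshError):
            FEMesh(**bad)

    def test_unknown_label_rejected(self):
        bad = dict(UNIT_TET, labels=np.array([99]))
        with pytest.raises(MeshError):
            FEMesh(**bad)

    def test_negative_volume_tetra_rejected_but_repairable(self):
        el = np.array([[0, 2, 1, 3]])  # inverted
        with pytest.raises(MeshError):
            FEMesh(**dict(UNIT_TET, elements=el))
        fixed = fix_tetra_orientation(el, UNIT_TET["vertices"])
        mesh = FEMesh(**dict(UNIT_TET, elements=fixed))
        assert element_volumes(mesh)[0] > 0
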