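"""Conductivity assignment: defaults, EMA / EMA+VC, constraints, mapping."""

import numpy as np
import pytest

from ephysfem.conductivity import (ConductivityError, DiffusionTensorImage,
                                   EmaParameters, compute_vc_scaling,
                                   constrain_tensors, default_isotropic,
                                   eigendecompose_dti, ema_direct, ema_vc,
                                   map_voxels_to_elements, simulated_tensor)
from ephysfem.mesh import CSF, GM, SCALP, SKULL, WM, element_barycenters
from ephysfem.synthetic import SyntheticDtiSpec, generate_synthetic_dti


def _uniform_dti(a=1e-3, shape=(6, 6, 6)):
    return generate_synthetic_dti(
        SyntheticDtiSpec(shape=shape, pattern="uniform-isotropic",
                         mean_diffusivity=a))


def _random_spd(n, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, 3, 3))
    return scale * (np.einsum("eij,ekj->eik", A, A) + 1e-3 * np.eye(3))


class TestDefaults:
    def test_standard_tissue_conductivities(self, small_mesh):
        model = default_isotropic(small_mesh)
        assert model.per_tissue[SCALP] == 0.43
        assert model.per_tissue[SKULL] == 0.01
        assert model.per_tissue[CSF] == 1.79
        assert model.per_tissue[GM] == 0.33
        assert model.per_tissue[WM] == 0.14

    def test_override_changes_only_that_tissue(self, small_mesh):
        model = default_isotropic(small_mesh, overrides={SKULL: 0.025})
        assert model.per_tissue[SKULL] == 0.025
        assert model.per_tissue[SCALP] == 0.43

    def test_unknown_override_rejected(self, small_mesh):
        with pytest.raises(ConductivityError):
            default_isotropic(small_mesh, overrides={99: 1.0})

    def test_tensor_expansion_is_scaled_identity(self, small_mesh):
        model = default_isotropic(small_mesh)
        T = model.element_tensors(small_mesh)
        sig = model.element_scalars(small_mesh)
        assert np.allclose(T, sig[:, None, None] * np.eye(3))


class TestEigendecomposition:
    def test_diagonal_tensor(self):
        dti = DiffusionTensorImage(
            tensors=np.diag([3e-3, 2e-3, 1e-3])[None, None, None],
            affine=np.eye(4), brain_mask=np.ones((1, 1, 1), bool))
        lam, vec = eigendecompose_dti(dti)
        assert np.allclose(lam[0, 0, 0], [3e-3, 2e-3, 1e-3])
        assert np.allclose(np.abs(vec[0, 0, 0]), np.eye(3), atol=1e-12)

    def test_rotated_tensor_recovers_rotation(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((3, 3))
        R, _ = np.linalg.qr(A)
        lam_true = np.array([2.0e-3, 1.0e-3, 0.5e-3])
        t = R @ np.diag(lam_true) @ R.T
        dti = DiffusionTensorImage(tensors=t[None, None, None],
                                   affine=np.eye(4),
                                   brain_mask=np.ones((1, 1, 1), bool))
        lam, vec = eigendecompose_dti(dti)
        assert np.allclose(lam[0, 0, 0], lam_true)
        for k in range(3):
            c = abs(vec[0, 0, 0][:, k] @ R[:, k])
            assert c == pytest.approx(1.0, abs=1e-10)

    def test_reconstruction(self):
        t = _random_spd(20, seed=5, scale=1e-3).reshape(2, 2, 5, 3, 3)
        dti = DiffusionTensorImage(tensors=t, affine=np.eye(4),
                                   brain_mask=np.ones((2, 2, 5), bool))
        lam, vec = eigendecompose_dti(dti)
        rec = np.einsum("...ij,...j,...kj->...ik", vec, lam, vec)
        assert np.allclose(rec, t, rtol=1e-10, atol=1e-18)


class TestEmaDirect:
    def test_unit_conversion_of_isotropic_voxel(self):
        sigma, substituted = ema_direct(_uniform_dti(1e-3))
        assert np.allclose(sigma, 0.736 * np.eye(3))
        assert substituted.sum() == 0

    def test_invalid_voxel_replaced_by_wm_default(self):
        dti = _uniform_dti(1e-3, shape=(3, 3, 3))
        dti.tensors[1, 1, 1] = 0.0
        sigma, substituted = ema_direct(dti)
        assert substituted.sum() == 1
        assert np.allclose(sigma[1, 1, 1], 0.14 * np.eye(3))

    def test_eigenvectors_preserved(self):
        t = _random_spd(100, seed=2, scale=1e-3).reshape(4, 5, 5, 3, 3)
        dti = DiffusionTensorImage(tensors=t, affine=np.eye(4),
                                   brain_mask=np.ones((4, 5, 5), bool))
        sigma, _ = ema_direct(dti)
        lam_d, vec_d = np.linalg.eigh(t)
        lam_s, vec_s = np.linalg.eigh(sigma)
        # same eigenvectors (up to sign), eigenvalues scaled by 736
        assert np.allclose(np.abs(np.einsum("...ij,...ij->...j", vec_d, vec_s)),
                           1.0, atol=1e-8)
        assert np.allclose(lam_s, 736.0 * lam_d)

    def test_linearity_in_diffusivity(self):
        d1 = _uniform_dti(1e-3)
        d2 = _uniform_dti(2e-3)
        s1, _ = ema_direct(d1)
        s2, _ = ema_direct(d2)
        assert np.allclose(s2, 2 * s1)


class TestEmaVc:
    def test_isotropic_input_recovers_target_exactly(self):
        a = 1e-3
        dti = _uniform_dti(a, shape=(2, 1, 1))
        wm = np.ones((2, 1, 1), bool)
        scaling = compute_vc_scaling(dti, wm, sigma_iso_wm=0.14)
        assert scaling.D_wm == pytest.approx(2 * a, rel=1e-12)
        assert scaling.s_vc == pytest.approx(0.14 / a, rel=1e-12)
        sigma, _, _ = ema_vc(dti, wm)
        assert np.allclose(sigma, 0.14 * np.eye(3), atol=1e-10)

    def test_global_rescaling_invariance(self):
        dti = generate_synthetic_dti(SyntheticDtiSpec(
            shape=(5, 5, 5), pattern="radial", noise=0.05, seed=3))
        wm = np.ones((5, 5, 5), bool)
        s1, _, _ = ema_vc(dti, wm)
        scaled = DiffusionTensorImage(tensors=dti.tensors * 10.0,
                                      affine=dti.affine,
                                      brain_mask=dti.brain_mask)
        s2, _, _ = ema_vc(scaled, wm)
        assert np.allclose(s1, s2, rtol=1e-12, atol=1e-15)

    def test_dwm_matches_loop_summed_oracle(self):
        dti = generate_synthetic_dti(SyntheticDtiSpec(
            shape=(4, 4, 4), pattern="fixed-axis", noise=0.1, seed=8))
        wm = np.zeros((4, 4, 4), bool)
        wm[1:3, :, :] = True
        scaling = compute_vc_scaling(dti, wm)
        total = 0.0
        for idx in np.argwhere(wm):
            lam = np.linalg.eigvalsh(dti.tensors[tuple(idx)])
            total += np.cbrt(lam[0] * lam[1] * lam[2])
        assert scaling.D_wm == pytest.approx(total, rel=1e-12)

    def test_empty_wm_mask_rejected(self):
        dti = _uniform_dti()
        with pytest.raises(ConductivityError):
            compute_vc_scaling(dti, np.zeros(dti.shape, bool))

    def test_all_invalid_wm_rejected(self):
        dti = _uniform_dti(shape=(2, 2, 2))
        dti.tensors[...] = 0.0
        with pytest.raises(ConductivityError):
            compute_vc_scaling(dti, np.ones((2, 2, 2), bool))


class TestConstraints:
    def test_cap_applied_first(self):
        out = constrain_tensors(np.diag([4.0, 0.5, 0.5])[None])[0]
        assert np.allclose(np.linalg.eigvalsh(out), [0.5, 0.5, 2.0])

    def test_ratio_floor_after_cap(self):
        out = constrain_tensors(np.diag([2.0, 0.1, 0.1])[None])[0]
        assert np.allclose(np.linalg.eigvalsh(out), [0.2, 0.2, 2.0])

    def test_compliant_tensor_unchanged_and_idempotent(self):
        t = _random_spd(200, seed=7, scale=0.05)
        once = constrain_tensors(t)
        twice = constrain_tensors(once)
        assert np.allclose(once, twice, atol=1e-13)
        small = np.diag([0.3, 0.1, 0.05])[None]
        assert np.allclose(constrain_tensors(small), small)

    def test_constraints_hold_and_eigenvectors_unrotated(self):
        t = _random_spd(500, seed=11, scale=2.0)
        out = constrain_tensors(t)
        lam_o, vec_o = np.linalg.eigh(out)
        assert lam_o.max() <= 2.0 + 1e-9
        assert (lam_o[:, 2] / lam_o[:, 0]).max() <= 10.0 + 1e-6
        assert lam_o.min() > 0
        # input eigenbasis still diagonalizes the output (no rotation;
        # degenerate floored eigenvalues leave basis choice free)
        _, vec_i = np.linalg.eigh(t)
        D = np.einsum("eji,ejk,ekl->eil", vec_i, out, vec_i)
        off = D - D * np.eye(3)
        assert np.abs(off).max() < 1e-10 * np.abs(D).max()


class TestVoxelElementMapping:
    def test_uniform_field_reaches_every_target_element(self, small_mesh):
        tensor = np.diag([0.2, 0.15, 0.1])
        grid = np.broadcast_to(tensor, (40, 40, 40, 3, 3)).copy()
        affine = np.eye(4)
        affine[:3, :3] *= 5.0  # 5 mm voxels covering +-100 mm
        affine[:3, 3] = [-97.5, -97.5, -97.5]
        model = map_voxels_to_elements(grid, affine, small_mesh, {GM})
        sel = small_mesh.labels == GM
        assert model.fallback_count == 0
        assert np.allclose(model.per_element_tensor[sel], tensor)
        other = ~sel
        sig = model.element_scalars(small_mesh)
        assert np.allclose(model.per_element_tensor[other],
                           sig[other, None, None] * np.eye(3))

    def test_two_region_field_split_by_barycenter_sign(self, small_mesh):
        grid = np.zeros((40, 40, 40, 3, 3))
        affine = np.eye(4)
        affine[:3, :3] *= 5.0
        affine[:3, 3] = [-97.5, -97.5, -97.5]
        centers_x = affine[0, 0] * np.arange(40) + affine[0, 3]
        left = np.diag([0.1, 0.1, 0.1])
        right = np.diag([0.3, 0.3, 0.3])
        grid[centers_x < 0] = left
        grid[centers_x >= 0] = right
        model = map_voxels_to_elements(grid, affine, small_mesh, {GM})
        bc = element_barycenters(small_mesh) * 1000.0
        sel = np.flatnonzero(small_mesh.labels == GM)
        inv = np.linalg.inv(affine)
        for e in sel[::50]:
            i = int(round(bc[e] @ inv[:3, :3].T[0] + inv[0, 3]))
            expect = left if centers_x[i] < 0 else right
            assert np.allclose(model.per_element_tensor[e], expect)

    def test_fallback_count_matches_brute_force(self, small_mesh):
        # grid covering only half the sphere
        grid = np.broadcast_to(0.2 * np.eye(3), (20, 40, 40, 3, 3)).copy()
        affine = np.eye(4)
        affine[:3, :3] *= 5.0
        affine[:3, 3] = [0.0, -97.5, -97.5]  # x >= -2.5mm only
        model = map_voxels_to_elements(grid, affine, small_mesh, {GM})
        bc = element_barycenters(small_mesh) * 1000.0
        inv = np.linalg.inv(affine)
        ijk = np.rint(bc @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        outside = ((ijk < 0) | (ijk >= [20, 40, 40])).any(axis=1)
        expected = int((outside & (small_mesh.labels == GM)).sum())
        assert model.fallback_count == expected


class TestSimulatedTensor:
    def test_skull_ratio_ten_closed_form(self, small_mesh):
        model = simulated_tensor(small_mesh, SKULL, 10.0)
        sel = small_mesh.labels == SKULL
        lam = np.linalg.eigvalsh(model.per_element_tensor[sel])
        assert np.allclose(lam[:, 2], 0.01 * 10 ** (2 / 3), rtol=1e-12)
        assert np.allclose(lam[:, 0], 0.01 * 10 ** (-1 / 3), rtol=1e-12)

    def test_ratio_one_is_isotropic_default(self, small_mesh):
        model = simulated_tensor(small_mesh, SKULL, 1.0)
        sel = small_mesh.labels == SKULL
        assert np.allclose(model.per_element_tensor[sel], 0.01 * np.eye(3))

    def test_geometric_mean_preserved_everywhere(self, small_mesh):
        model = simulated_tensor(small_mesh, SKULL, 5.0)
        sel = small_mesh.labels == SKULL
        lam = np.linalg.eigvalsh(model.per_element_tensor[sel])
        gm = np.cbrt(np.prod(lam, axis=1))
        assert np.allclose(gm, 0.01, atol=1e-12)

    def test_radial_longitudinal_axis(self, small_mesh):
        model = simulated_tensor(small_mesh, SKULL, 10.0, "radial")
        sel = np.flatnonzero(small_mesh.labels == SKULL)[:25]
        bc = element_barycenters(small_mesh)
        ctr = small_mesh.centroid()
        for e in sel:
            lam, vec = np.linalg.eigh(model.per_element_tensor[e])
            r = bc[e] - ctr
            r /= np.linalg.norm(r)
            assert abs(vec[:, 2] @ r) == pytest.approx(1.0, abs=1e-9)

    def test_absent_tissue_rejected(self, small_mesh):
        with pytest.raises(ConductivityError):
            simulated_tensor(small_mesh, WM, 5.0)
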