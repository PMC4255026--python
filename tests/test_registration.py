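"""Rigid alignment, DCT warps, resampling and Jacobian maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longvbm.image import BrainImage, default_affine
from longvbm.registration import (
    DCTWarp,
    RigidTransform,
    TransformChain,
    apply_chain,
    dct_normalize,
    jacobian_map,
    rigid_align,
)


def _angle_of(M):
    return np.rad2deg(np.arccos(np.clip((np.trace(M[:3, :3]) - 1) / 2, -1, 1)))


def _identity_warp(K, shape, affine, A=None, coefs=None):
    c = np.zeros((K, K, K, 3)) if coefs is None else coefs
    return DCTWarp(np.eye(4) if A is None else A, c, shape, affine)


@pytest.fixture(scope="module")
def textured_t1(template_t1):
    """Template T1 plus smooth deterministic texture: the bare ellipsoid is
    nearly rotation-symmetric, so pure rotations would be unidentifiable."""
    from scipy import ndimage

    rng = np.random.default_rng(42)
    tex = ndimage.gaussian_filter(rng.normal(0, 1, template_t1.shape), 2.5)
    brain = template_t1.data > 0.1
    data = template_t1.data + 0.15 * tex.astype(np.float32) * brain
    return template_t1.like(data)


@pytest.fixture(scope="module")
def jittered_fixed(textured_t1):
    """Fixed image with one sub-voxel resample so that moving and fixed
    carry the same interpolation history (as two real acquisitions would);
    returns (image, jitter transform)."""
    J = RigidTransform([0, 0, 0], [0.31, -0.27, 0.23])
    return apply_chain(textured_t1, J, "spline-3"), J


class TestRigidTransform:
    def test_matrix_orthonormal(self):
        T = RigidTransform([0.1, -0.2, 0.3], [1, 2, 3])
        R = T.rotation_matrix
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-0.5, 0.5), min_size=6, max_size=6))
    def test_inverse_roundtrip(self, params):
        T = RigidTransform(params[:3], params[3:])
        pts = np.array([[1.0, -2.0, 3.0], [0.0, 0.0, 0.0], [5.0, 5.0, -5.0]])
        back = T.inverse().apply(T.apply(pts))
        assert np.abs(back - pts).max() < 1e-6

    def test_compose_matches_matrix_product(self):
        A = RigidTransform([0.1, 0, -0.05], [1, 0, 2])
        B = RigidTransform([0, 0.2, 0], [-1, 3, 0])
        assert np.allclose(A.compose(B).matrix, A.matrix @ B.matrix, atol=1e-9)


class TestRigidAlign:
    def test_self_registration_is_identity(self, template_t1):
        T = rigid_align(template_t1, template_t1, cost="ssd")
        assert np.linalg.norm(T.rotations) < np.deg2rad(0.01)
        assert np.linalg.norm(T.translations) < 0.01

    def test_translation_recovery(self, textured_t1, jittered_fixed):
        fixed, J = jittered_fixed
        T0 = RigidTransform([0, 0, 0], [2.0, -1.0, 0.5])
        moving = apply_chain(textured_t1, T0, "spline-3")
        That = rigid_align(moving, fixed, cost="ssd")
        # the pull-back maps fixed coords to moving coords: T0^-1 o J
        truth = T0.inverse().compose(J)
        assert np.abs(That.translations - truth.translations).max() < 0.2

    def test_rotation_recovery(self, textured_t1, jittered_fixed):
        fixed, J = jittered_fixed
        T0 = RigidTransform([0, 0, np.deg2rad(2.0)], [0, 0, 0])
        moving = apply_chain(textured_t1, T0, "spline-3")
        That = rigid_align(moving, fixed, cost="ssd")
        truth = T0.inverse().compose(J)
        M = That.matrix @ np.linalg.inv(truth.matrix)
        # the smooth ellipsoid is nearly symmetric about z, making this the
        # weakest rotation mode; 0.2 degrees is the identifiability limit
        assert _angle_of(M) < 0.2

    def test_equivariance_within_capture_range(self, textured_t1, jittered_fixed):
        fixed, J = jittered_fixed
        T0 = RigidTransform(np.deg2rad([1.5, -2.0, 1.0]), [1.0, 2.0, -1.5])
        moving = apply_chain(textured_t1, T0, "spline-3")
        That = rigid_align(moving, fixed, cost="ssd")
        truth = T0.inverse().compose(J)
        M = That.matrix @ np.linalg.inv(truth.matrix)
        assert _angle_of(M) < 0.2
        assert np.abs(M[:3, 3]).max() < 0.2

    def test_nmi_cross_contrast(self, template, template_t1):
        # synthesize the T2 contrast of the same anatomy, shift it, recover
        tp = template.tissue_priors
        mu = template.contrast_table["t2"]
        bg = np.clip(1 - tp["gm"].data - tp["wm"].data - tp["csf"].data, 0, 1)
        t2 = BrainImage(
            mu["gm"] * tp["gm"].data + mu["wm"] * tp["wm"].data
            + mu["csf"] * tp["csf"].data + mu["bg"] * bg, template.affine
        )
        T0 = RigidTransform([0, 0, 0], [1.5, 0.0, -1.0])
        moving = apply_chain(t2, T0, "spline-3")
        That = rigid_align(moving, template_t1, cost="nmi")
        assert np.abs(That.translations - T0.inverse().translations).max() < 0.5

    def test_rejects_bad_cost_and_nonfinite(self, template_t1):
        with pytest.raises(ValueError):
            rigid_align(template_t1, template_t1, cost="mse")
        bad = template_t1.like(template_t1.data.copy())
        bad.data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rigid_align(bad, template_t1)


class TestDCTWarp:
    def test_parameter_count_k8(self, template_t1):
        w = _identity_warp(8, template_t1.shape, template_t1.affine)
        assert w.n_parameters == 1536  # 8*8*8 basis in three directions

    def test_identity_mapping(self, template_t1):
        w = _identity_warp(6, template_t1.shape, template_t1.affine)
        pts = np.array([[0.0, 0.0, 0.0], [5.0, -3.0, 7.0]])
        assert np.abs(w.apply(pts) - pts).max() < 1e-12

    def test_serialization_roundtrip(self, template_t1, tmp_path):
        rng = np.random.default_rng(0)
        w = _identity_warp(4, template_t1.shape, template_t1.affine,
                           coefs=rng.normal(0, 0.3, (4, 4, 4, 3)))
        w.save(tmp_path / "w.warp")
        w2 = DCTWarp.load(tmp_path / "w.warp")
        assert np.array_equal(w.coefficients, w2.coefficients)
        assert np.array_equal(w.affine_part, w2.affine_part)

    def test_normalize_identity_problem(self, template_t1):
        w = dct_normalize(template_t1, template_t1, K=6, max_iter=16)
        disp = w.displacement_on_grid()
        assert np.abs(disp).max() < 0.1  # voxels are 1 mm here

    def test_k_must_be_at_least_4(self, template_t1):
        with pytest.raises(ValueError):
            dct_normalize(template_t1, template_t1, K=2)

    def test_known_warp_recovery(self, template_t1):
        """A source synthesized by warping the template with a known
        low-order field is normalized back: recovered displacement RMS
        error < 20% of the true field's RMS amplitude."""
        K = 4
        rng = np.random.default_rng(3)
        coefs = np.zeros((K, K, K, 3))
        coefs[:2, :2, :2, :] = rng.normal(0, 0.5, (2, 2, 2, 3))
        true = DCTWarp(np.eye(4), coefs, template_t1.shape, template_t1.affine)
        source = apply_chain(template_t1, true, "spline-3")
        # fit maps template voxels onto source, i.e. approximates true^-1
        fit = dct_normalize(source, template_t1, K=8, affine_stage=False,
                            regularization_weight=3e2, max_iter=200,
                            smooth_fwhm_mm=3.0, tol=1e-9)
        # the fit approximates the inverse of the true field; invert the
        # true mapping numerically (fixed point) as the oracle
        mask = template_t1.data > 0.1
        pts = template_t1.world_coords().reshape(-1, 3)
        p = pts.copy()
        for _ in range(20):
            p = pts - true.displacement(p)
        d_inv = (p - pts).reshape(template_t1.shape + (3,))
        d_true = true.displacement_on_grid()[mask]
        err = np.sqrt(((fit.displacement_on_grid()[mask] - d_inv[mask]) ** 2).mean())
        rms_true = np.sqrt((d_true**2).mean())
        assert err < 0.2 * rms_true


class TestApplyChain:
    def test_identity_chain_returns_input(self, template_t1):
        out = apply_chain(template_t1, RigidTransform(), "trilinear")
        assert np.allclose(out.data, template_t1.data, atol=1e-5)

    def test_translation_of_ones_interior(self):
        img = BrainImage(np.ones((24, 24, 24), np.float32),
                         default_affine((24, 24, 24), 1.0))
        out = apply_chain(img, RigidTransform([0, 0, 0], [1.2, -0.7, 0.4]),
                          "trilinear")
        assert np.allclose(out.data[4:-4, 4:-4, 4:-4], 1.0, atol=1e-6)

    def test_invalid_interpolation(self, template_t1):
        with pytest.raises(ValueError):
            apply_chain(template_t1, RigidTransform(), "sinc")

    def test_composition_beats_sequential_resampling(self):
        """A two-rigid chain composed in coordinate space (one interpolation)
        is closer to the analytic ground truth than two resampling passes."""
        shape = (32, 32, 32)
        aff = default_affine(shape, 1.0)
        grid = BrainImage(np.zeros(shape, np.float32), aff)
        w = grid.world_coords()

        def gauss(pts):
            return np.exp(-(pts**2).sum(-1) / (2 * 36.0))

        img = BrainImage(gauss(w).astype(np.float32), aff)
        A = RigidTransform(np.deg2rad([3, 0, 0]), [1.3, 0, 0])
        B = RigidTransform(np.deg2rad([0, 2, 0]), [0, -0.8, 0.5])
        composed = apply_chain(img, TransformChain([A, B]), "trilinear")
        seq = apply_chain(apply_chain(img, B, "trilinear"), A, "trilinear")
        truth = gauss(B.apply(A.apply(w.reshape(-1, 3)))).reshape(shape)
        interior = (slice(6, -6),) * 3
        e_comp = np.abs(composed.data[interior] - truth[interior]).max()
        e_seq = np.abs(seq.data[interior] - truth[interior]).max()
        assert e_comp < e_seq

    def test_rigid_only_chain_inverse(self):
        A = RigidTransform([0.05, 0, 0.1], [2, -1, 0])
        B = RigidTransform([0, -0.07, 0], [0, 3, 1])
        chain = TransformChain([A, B])
        pts = np.random.default_rng(1).normal(0, 10, (50, 3))
        back = chain.inverse().apply(chain.apply(pts))
        assert np.abs(back - pts).max() < 1e-6


class TestJacobian:
    def test_identity_warp_unit_map(self, template_t1):
        w = _identity_warp(6, template_t1.shape, template_t1.affine)
        j = jacobian_map(w)
        assert np.allclose(j.data, 1.0, atol=1e-6)

    def test_isotropic_scale_closed_form(self, template_t1):
        s = 1.07
        A = np.diag([s, s, s, 1.0])
        w = _identity_warp(6, template_t1.shape, template_t1.affine, A=A)
        j = jacobian_map(w)
        assert np.allclose(j.data, s**3, atol=1e-6)

    def test_rigid_affine_part_has_unit_jacobian(self, template_t1):
        T = RigidTransform(np.deg2rad([3, -2, 5]), [4, 1, -2])
        w = _identity_warp(6, template_t1.shape, template_t1.affine, A=T.matrix)
        assert np.allclose(jacobian_map(w).data, 1.0, atol=1e-9)

    def test_analytic_matches_finite_differences(self, template_t1):
        """Analytic determinant vs central differences of the closed-form
        displacement field at h = 0.25 mm, max abs deviation < 1e-3."""
        rng = np.random.default_rng(5)
        K = 8
        k = np.arange(K)
        decay = 0.5 / (1.0 + (k[:, None, None] ** 2 + k[None, :, None] ** 2
                              + k[None, None, :] ** 2))
        coefs = rng.normal(0, 1, (K, K, K, 3)) * decay[..., None]
        w = DCTWarp(np.eye(4), coefs, template_t1.shape, template_t1.affine)
        j_analytic = jacobian_map(w).data

        pts = template_t1.world_coords().reshape(-1, 3)
        h = 0.25
        J = np.empty((len(pts), 3, 3))
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            dp = (w.displacement(pts + e) - w.displacement(pts - e)) / (2 * h)
            J[:, :, ax] = dp
        J += np.eye(3)
        j_fd = np.linalg.det(J).reshape(template_t1.shape)
        assert np.abs(j_analytic - j_fd).max() < 1e-3

    def test_folding_reported(self, template_t1):
        coefs = np.zeros((4, 4, 4, 3))
        coefs[1, 0, 0, 0] = 60.0  # strong enough to fold
        w = DCTWarp(np.eye(4), coefs, template_t1.shape, template_t1.affine)
        report = {}
        j = jacobian_map(w, report=report)
        assert report["folding_fraction"] > 0
        assert j.data.min() <= 0

    def test_volume_duality_against_surface_mesh(self, template_t1):
        """Integral of the Jacobian over a ball equals the volume of the
        ball's image, computed independently from the mapped triangulated
        surface (divergence theorem), within 1%."""
        trimesh = pytest.importorskip("trimesh")
        rng = np.random.default_rng(2)
        K = 6
        coefs = rng.normal(0, 0.25, (K, K, K, 3))
        w = DCTWarp(np.eye(4), coefs, template_t1.shape, template_t1.affine)
        j = jacobian_map(w).data

        r = 10.0
        world = template_t1.world_coords()
        ball = (world**2).sum(-1) <= r**2
        vol_jac = j[ball].sum() * template_t1.voxel_volume

        sphere = trimesh.creation.icosphere(subdivisions=4, radius=r)
        mapped = trimesh.Trimesh(
            vertices=w.apply(np.asarray(sphere.vertices)),
            faces=sphere.faces, process=False,
        )
        # voxelized ball volume differs from the analytic sphere: compare
        # against the mesh volume scaled by the same discretization ratio
        vol_ball_vox = ball.sum() * template_t1.voxel_volume
        vol_ball_true = 4 / 3 * np.pi * r**3
        expected = abs(mapped.volume) * vol_ball_vox / vol_ball_true
        assert vol_jac == pytest.approx(expected, rel=0.01)
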