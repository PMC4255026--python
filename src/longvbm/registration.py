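"""Spatial transforms: rigid alignment, DCT-basis nonlinear normalization,
transform chains, and analytic Jacobian-determinant maps.

Conventions
-----------
All transforms act on world (mm) coordinates and are stored in *pull-back*
form: a transform maps target-space points to source-space points, so
resampling an image through a transform needs a single interpolation pass.
The nonlinear warp is an affine followed by a displacement field expressed
in a separable 3D discrete cosine (DCT-II) basis of order K per axis —
K = 8 gives the classic 8x8x8 basis with 8^3 x 3 = 1,536 parameters.
The basis is written in normalized grid coordinates p = (index + 1/2)/N,
so coefficients are resolution-independent and transfer unchanged across
multi-resolution levels.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .image import BrainImage

__all__ = [
    "RigidTransform",
    "DCTWarp",
    "TransformChain",
    "RegistrationError",
    "rigid_align",
    "dct_normalize",
    "apply_chain",
    "jacobian_map",
]


class RegistrationError(RuntimeError):
    """Optimization failure; carries the last cost trace."""

    def __init__(self, message: str, cost_trace=None):
        super().__init__(message)
        self.cost_trace = list(cost_trace or [])


# --------------------------------------------------------------------------
# rigid transforms
# --------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """6-parameter rigid-body transform: 3 rotations (rad) + 3 translations (mm).

    Maps world points y = R x + t with R = Rz Ry Rx (extrinsic xyz Euler).
    """

    rotations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translations: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=float).reshape(3)
        self.translations = np.asarray(self.translations, dtype=float).reshape(3)

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotations).as_matrix()

    @property
    def matrix(self) -> np.ndarray:
        """Equivalent 4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation_matrix
        M[:3, 3] = self.translations
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points, shape (..., 3)."""
        return points @ self.rotation_matrix.T + self.translations

    def inverse(self) -> "RigidTransform":
        Rm = self.rotation_matrix
        rot = Rotation.from_matrix(Rm.T).as_euler("xyz")
        return RigidTransform(rot, -Rm.T @ self.translations)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: first apply ``other``, then ``self``."""
        M = self.matrix @ other.matrix
        rot = Rotation.from_matrix(M[:3, :3]).as_euler("xyz")
        return RigidTransform(rot, M[:3, 3])


# --------------------------------------------------------------------------
# DCT warps
# --------------------------------------------------------------------------

def _dct_basis(p: np.ndarray, K: int) -> np.ndarray:
    """DCT-II basis functions cos(pi k p) at normalized positions p, (len(p), K)."""
    k = np.arange(K)
    return np.cos(np.pi * np.outer(p, k))


def _dct_basis_deriv(p: np.ndarray, K: int) -> np.ndarray:
    """d/dp of the basis: -pi k sin(pi k p)."""
    k = np.arange(K)
    return -np.pi * k * np.sin(np.pi * np.outer(p, k))


@dataclass
class DCTWarp:
    """Affine + low-frequency DCT displacement field on a reference grid.

    ``coefficients`` has shape (K, K, K, 3), units mm.  The mapping is
    phi(x) = A x + d(x) with d evaluated in the normalized coordinates of
    the reference (target) grid.  Zero coefficients with an identity affine
    give the identity mapping.
    """

    affine_part: np.ndarray  # 4x4 world-to-world
    coefficients: np.ndarray  # (K, K, K, 3) mm
    grid_shape: tuple[int, int, int]
    grid_affine: np.ndarray  # voxel-to-world of the reference grid

    def __post_init__(self):
        self.affine_part = np.asarray(self.affine_part, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        K = self.coefficients.shape[0]
        if self.coefficients.shape != (K, K, K, 3):
            raise ValueError("coefficients must have shape (K, K, K, 3)")
        self.grid_affine = np.asarray(self.grid_affine, dtype=float)

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_parameters(self) -> int:
        return int(np.prod(self.coefficients.shape))

    # -------------------------------------------------------------- mapping
    def _normalized(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.grid_affine)
        idx = points @ inv[:3, :3].T + inv[:3, 3]
        return (idx + 0.5) / np.asarray(self.grid_shape)

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Displacement d(x) (mm) at world points, shape (..., 3)."""
        flat = points.reshape(-1, 3)
        p = self._normalized(flat)
        K = self.order
        B = [_dct_basis(p[:, ax], K) for ax in range(3)]
        # d_i = sum_abc Bx[:,a] By[:,b] Bz[:,c] C[a,b,c,i]
        t = np.einsum("na,abci->nbci", B[0], self.coefficients)
        t = np.einsum("nb,nbci->nci", B[1], t)
        d = np.einsum("nc,nci->ni", B[2], t)
        return d.reshape(points.shape)

    def apply(self, points: np.ndarray) -> np.ndarray:
        A = self.affine_part
        return points @ A[:3, :3].T + A[:3, 3] + self.displacement(points)

    def displacement_on_grid(self, shape=None, affine=None) -> np.ndarray:
        """Displacement field on a voxel grid, shape (*shape, 3)."""
        shape = shape or self.grid_shape
        affine = self.grid_affine if affine is None else affine
        img = BrainImage(np.zeros(shape, np.float32), affine)
        return self.displacement(img.world_coords())

    # ------------------------------------------------------------ serialize
    def save(self, path: str | Path) -> None:
        """JSON header + little-endian float64 coefficient block."""
        path = Path(path)
        header = {
            "order": self.order,
            "grid_shape": list(self.grid_shape),
            "grid_affine": self.grid_affine.tolist(),
            "affine_part": self.affine_part.tolist(),
            "dtype": "<f8",
        }
        hdr = json.dumps(header).encode()
        with open(path, "wb") as f:
            f.write(struct.pack("<I", len(hdr)))
            f.write(hdr)
            f.write(np.ascontiguousarray(self.coefficients, "<f8").tobytes())

    @classmethod
    def load(cls, path: str | Path) -> "DCTWarp":
        with open(path, "rb") as f:
            n = struct.unpack("<I", f.read(4))[0]
            header = json.loads(f.read(n).decode())
            K = header["order"]
            coefs = np.frombuffer(f.read(), dtype="<f8").reshape(K, K, K, 3)
        return cls(
            np.array(header["affine_part"]), coefs.copy(),
            tuple(header["grid_shape"]), np.array(header["grid_affine"]),
        )


@dataclass
class TransformChain:
    """Ordered pull-back transforms: target coords -> ... -> source coords."""

    components: list

    def apply(self, points: np.ndarray) -> np.ndarray:
        for c in self.components:
            points = c.apply(points)
        return points

    def inverse(self) -> "TransformChain":
        inv = []
        for c in reversed(self.components):
            if not isinstance(c, RigidTransform):
                raise ValueError("only rigid-only chains have a stored inverse")
            inv.append(c.inverse())
        return TransformChain(inv)


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

_ORDER = {"nearest": 0, "trilinear": 1, "spline-3": 3}


def apply_chain(
    image: BrainImage,
    chain: TransformChain | RigidTransform | DCTWarp,
    interpolation: str = "trilinear",
    target: BrainImage | None = None,
) -> BrainImage:
    """Resample ``image`` onto the target grid through the whole chain.

    Transforms are composed in coordinate space first, so a single
    interpolation pass is performed regardless of chain length.
    Out-of-field voxels are 0.
    """
    if interpolation not in _ORDER:
        raise ValueError(f"interpolation must be one of {sorted(_ORDER)}")
    if not isinstance(chain, TransformChain):
        chain = TransformChain([chain])
    ref = target if target is not None else image
    pts = ref.world_coords().reshape(-1, 3)
    src_world = chain.apply(pts)
    inv = np.linalg.inv(image.affine)
    vox = src_world @ inv[:3, :3].T + inv[:3, 3]
    out = ndimage.map_coordinates(
        image.data.astype(np.float64), vox.T,
        order=_ORDER[interpolation], mode="constant", cval=0.0,
    )
    return BrainImage(out.reshape(ref.shape).astype(np.float32), ref.affine)


def _downsample(img: BrainImage, factor: int = 2) -> BrainImage:
    data = ndimage.gaussian_filter(img.data.astype(np.float64), sigma=factor / 2.0)
    data = data[::factor, ::factor, ::factor]
    aff = img.affine.copy()
    aff[:3, :3] *= factor
    return BrainImage(data.astype(np.float32), aff)


# --------------------------------------------------------------------------
# rigid registration
# --------------------------------------------------------------------------

def _resample_rigid_cost(moving, fixed_pts, inv_mov, params):
    rot, tra = params[:3], params[3:]
    T = RigidTransform(rot, tra)
    mapped = T.apply(fixed_pts)
    vox = mapped @ inv_mov[:3, :3].T + inv_mov[:3, 3]
    return ndimage.map_coordinates(moving, vox.T, order=1, mode="constant", cval=0.0)


def _nmi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    h, _, _ = np.histogram2d(a, b, bins=bins)
    p = h / h.sum()
    px, py = p.sum(1), p.sum(0)
    nz = p > 0
    hxy = -(p[nz] * np.log(p[nz])).sum()
    hx = -(px[px > 0] * np.log(px[px > 0])).sum()
    hy = -(py[py > 0] * np.log(py[py > 0])).sum()
    return (hx + hy) / max(hxy, 1e-12)


def _rot_and_derivs(angles: np.ndarray):
    R = Rotation.from_euler("xyz", angles).as_matrix()
    dR = []
    eps = 1e-7
    for i in range(3):
        a = angles.copy()
        a[i] += eps
        dR.append((Rotation.from_euler("xyz", a).as_matrix() - R) / eps)
    return R, dR


def rigid_align(
    moving: BrainImage,
    fixed: BrainImage,
    cost: str = "ssd",
    levels: int = 2,
    max_iter: int = 100,
    x0: np.ndarray | None = None,
    fine_stride: int = 2,
    bias_poly: bool = False,
) -> RigidTransform:
    """Estimate the 6-parameter transform T with moving(T(x)) ~ fixed(x).

    Multi-resolution descent: Levenberg-Marquardt on the intensity
    residuals (analytic Jacobian) for same-contrast "ssd", Powell on
    32-bin normalized mutual information for cross-contrast "nmi".  The
    finest level is subsampled by ``fine_stride`` for speed.  The returned
    transform is the pull-back used to resample ``moving`` onto the fixed
    grid; for a moving image generated as fixed seen through T0, the
    recovered transform is T0^-1.

    With ``bias_poly=True`` (ssd only) a quadratic log-intensity-ratio
    field is estimated jointly with the transform: smooth session-specific
    bias is absorbed by the polynomial instead of displacing the rigid
    optimum.  The nuisance field is discarded.
    """
    if cost not in ("ssd", "nmi"):
        raise ValueError("cost must be 'ssd' or 'nmi'")
    if bias_poly and cost != "ssd":
        raise ValueError("bias_poly is only available with the ssd cost")
    if not (np.isfinite(moving.data).all() and np.isfinite(fixed.data).all()):
        raise ValueError("images must be finite-valued")
    params = np.zeros(6) if x0 is None else np.asarray(x0, dtype=float).copy()
    trace: list[float] = []

    pyramid = [fixed]
    mov_pyr = [moving]
    for _ in range(levels - 1):
        pyramid.insert(0, _downsample(pyramid[0]))
        mov_pyr.insert(0, _downsample(mov_pyr[0]))

    for lvl, (fx, mv) in enumerate(zip(pyramid, mov_pyr)):
        stride = fine_stride if lvl == len(pyramid) - 1 and levels > 1 else 1
        sl = (slice(None, None, stride),) * 3
        grid = np.stack(
            np.meshgrid(*[np.arange(n)[s] for n, s in zip(fx.shape, sl)],
                        indexing="ij"), axis=-1
        ).reshape(-1, 3).astype(np.float64)
        fixed_pts = grid @ fx.affine[:3, :3].T + fx.affine[:3, 3]
        fixed_vals = fx.data[sl].astype(np.float64).ravel()
        inv_mov = np.linalg.inv(mv.affine)
        mov_data = mv.data.astype(np.float64)

        if cost == "ssd":
            gxyz = np.gradient(mov_data, *mv.voxel_size)
            # cubic interpolation of the moving image inside the residuals:
            # trilinear smoothing is asymmetric (applied to one side only)
            # and displaces weakly identifiable modes by ~0.1 degree
            mov_coef = ndimage.spline_filter(mov_data, order=3)
            g_coef = [ndimage.spline_filter(g, order=3) for g in gxyz]
            if bias_poly:
                ext = np.abs(fixed_pts).max(axis=0)
                ext[ext == 0] = 1.0
                xs, ys, zs = (fixed_pts[:, i] / ext[i] for i in range(3))
                P = np.stack(
                    [np.ones_like(xs), xs, ys, zs, xs * ys, xs * zs, ys * zs,
                     xs * xs, ys * ys, zs * zs], axis=1
                )
                n_nuis = P.shape[1]
            else:
                P = None
                n_nuis = 0
            if len(params) == 6 and n_nuis:
                params = np.r_[params, np.zeros(n_nuis)]

            def residuals(x):
                T = RigidTransform(x[:3], x[3:6])
                vox = T.apply(fixed_pts) @ inv_mov[:3, :3].T + inv_mov[:3, 3]
                vals = ndimage.map_coordinates(
                    mov_coef, vox.T, order=3, prefilter=False, mode="constant"
                )
                if n_nuis:
                    vals = vals * np.exp(P @ x[6:])
                r = vals - fixed_vals
                trace.append(float((r**2).mean()))
                return r

            def jac(x):
                R, dR = _rot_and_derivs(x[:3])
                mapped = fixed_pts @ R.T + x[3:6]
                vox = mapped @ inv_mov[:3, :3].T + inv_mov[:3, 3]
                scale = np.exp(P @ x[6:]) if n_nuis else 1.0
                g = np.stack(
                    [ndimage.map_coordinates(gi, vox.T, order=3,
                                             prefilter=False, mode="constant")
                     for gi in g_coef], axis=1
                )  # (N, 3) image gradient at mapped points
                J = np.empty((len(fixed_pts), 6 + n_nuis))
                for i in range(3):
                    J[:, i] = (g * (fixed_pts @ dR[i].T)).sum(axis=1)
                    J[:, 3 + i] = g[:, i]
                if n_nuis:
                    vals = ndimage.map_coordinates(
                        mov_data, vox.T, order=1, mode="constant"
                    )
                    J[:, :6] *= scale[:, None]
                    J[:, 6:] = (vals * scale)[:, None] * P
                return J

            res = optimize.least_squares(
                residuals, params, jac=jac, method="lm",
                max_nfev=max_iter, xtol=1e-10, ftol=1e-10,
            )
            params = res.x
        else:

            def fun(x):
                vals = _resample_rigid_cost(mov_data, fixed_pts, inv_mov, x)
                c = -_nmi(fixed_vals, vals)
                trace.append(c)
                return c

            res = optimize.minimize(
                fun, params, method="Powell",
                options={"maxiter": max_iter, "xtol": 1e-5, "ftol": 1e-9},
            )
            params = res.x
    if not np.isfinite(params).all():
        raise RegistrationError("rigid optimization diverged", trace)
    return RigidTransform(params[:3], params[3:6])


# --------------------------------------------------------------------------
# DCT normalization
# --------------------------------------------------------------------------

def _bending_weights(K: int, grid_shape, voxel_size) -> np.ndarray:
    """Diagonal bending-energy weight per coefficient.

    For basis cos(pi k p) the second spatial derivative scales as
    (pi k / L)^2 with L the field-of-view extent, so the bending energy is
    diagonal in coefficient space: w = (|k|^2 scaled)^2.
    """
    L = np.asarray(grid_shape) * np.asarray(voxel_size)  # mm extent
    k = [((np.pi * np.arange(K)) / L[ax]) ** 2 for ax in range(3)]
    lap = k[0][:, None, None] + k[1][None, :, None] + k[2][None, None, :]
    return (lap**2)[..., None] * np.ones((1, 1, 1, 3))


def _fit_affine(source, template, dof=12, max_iter=60):
    """Affine stage: Levenberg-Marquardt on SSD residuals at half resolution.

    Parameterized as rotations + translations + log-scales (+ shears for
    dof=12); the Jacobian uses the analytic image gradient with
    finite-difference derivatives of the 3x4 matrix in the 12 parameters.
    """
    src = _downsample(source) if min(source.shape) >= 32 else source
    tmp = _downsample(template) if min(template.shape) >= 32 else template
    pts = tmp.world_coords().reshape(-1, 3)
    tvals = tmp.data.astype(np.float64).ravel()
    inv_src = np.linalg.inv(src.affine)
    sdata = src.data.astype(np.float64)
    gxyz = np.gradient(sdata, *src.voxel_size)
    n = 12 if dof == 12 else 9

    def build(x):
        A = np.eye(4)
        R = Rotation.from_euler("xyz", x[:3]).as_matrix()
        S = np.diag(np.exp(x[6:9]))
        Sh = np.eye(3)
        if dof == 12:
            Sh[0, 1], Sh[0, 2], Sh[1, 2] = x[9:12]
        A[:3, :3] = R @ S @ Sh
        A[:3, 3] = x[3:6]
        return A

    def residuals(x):
        A = build(x)
        mapped = pts @ A[:3, :3].T + A[:3, 3]
        vox = mapped @ inv_src[:3, :3].T + inv_src[:3, 3]
        vals = ndimage.map_coordinates(sdata, vox.T, order=1, mode="constant")
        return vals - tvals

    def jac(x):
        A = build(x)
        mapped = pts @ A[:3, :3].T + A[:3, 3]
        vox = mapped @ inv_src[:3, :3].T + inv_src[:3, 3]
        g = np.stack(
            [ndimage.map_coordinates(gi, vox.T, order=1, mode="constant")
             for gi in gxyz], axis=1
        )
        J = np.empty((len(pts), n))
        eps = 1e-6
        for j in range(n):
            xe = x.copy()
            xe[j] += eps
            dA = (build(xe) - A) / eps
            J[:, j] = (g * (pts @ dA[:3, :3].T + dA[:3, 3])).sum(axis=1)
        return J

    # bounded trust-region keeps the fit in the identity basin: smooth
    # ellipsoidal brains are nearly rotation-symmetric, and an unbounded
    # optimizer can wander to a rotated near-symmetry or slide along a
    # weakly constrained scale direction
    lb = np.r_[-0.1 * np.ones(3), -10 * np.ones(3), -0.05 * np.ones(3),
               -0.05 * np.ones(n - 9)]
    ub = -lb
    res = optimize.least_squares(
        residuals, np.zeros(n), jac=jac, method="trf", bounds=(lb, ub),
        x_scale=np.r_[0.05 * np.ones(3), 2.0 * np.ones(3), 0.05 * np.ones(n - 6)],
        max_nfev=max_iter, xtol=1e-10, ftol=1e-10,
    )
    return build(res.x)


def dct_normalize(
    source: BrainImage,
    template: BrainImage,
    K: int = 8,
    regularization_weight: float = 1e4,
    seed: int = 0,
    affine_stage: bool = True,
    levels: int = 2,
    max_iter: int = 64,
    tol: float = 1e-5,
    fine_stride: int = 1,
    smooth_fwhm_mm: float = 8.0,
) -> DCTWarp:
    """Normalize ``source`` to ``template``: affine then penalized DCT fit.

    Both images are Gaussian-smoothed (``smooth_fwhm_mm``) for the fit only,
    so hard-edged segment images can be matched to soft priors; the warp is
    then applied to the unsmoothed data.  Minimizes SSD between the warped
    source and the template plus a bending-energy penalty (diagonal in the
    DCT basis), by L-BFGS with the analytic gradient, coarse-to-fine over
    ``levels`` resolutions.  The returned pull-back warp resamples the
    source onto the template grid.
    """
    if K < 4:
        raise ValueError("K must be >= 4")

    def _presmooth(img: BrainImage) -> BrainImage:
        if smooth_fwhm_mm <= 0:
            return img
        sig = smooth_fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / img.voxel_size
        return img.like(ndimage.gaussian_filter(img.data.astype(np.float64), sig))

    source_s, template_s = _presmooth(source), _presmooth(template)
    A = _fit_affine(source_s, template_s) if affine_stage else np.eye(4)

    coefs = np.zeros((K, K, K, 3))
    w = _bending_weights(K, template.shape, template.voxel_size).ravel()

    tmpls, srcs = [template_s], [source_s]
    for _ in range(levels - 1):
        tmpls.insert(0, _downsample(tmpls[0]))
        srcs.insert(0, _downsample(srcs[0]))

    for lvl, (tmp, src) in enumerate(zip(tmpls, srcs)):
        stride = fine_stride if lvl == len(tmpls) - 1 and levels > 1 else 1
        sl = (slice(None, None, stride),) * 3
        shape = tmp.data[sl].shape
        grid = np.stack(
            np.meshgrid(*[np.arange(n)[s] for n, s in zip(tmp.shape, sl)],
                        indexing="ij"), axis=-1
        ).reshape(-1, 3).astype(np.float64)
        pts = grid @ tmp.affine[:3, :3].T + tmp.affine[:3, 3]
        tvals = tmp.data[sl].astype(np.float64).ravel()
        data_w = float(stride**3)  # keep the data term on the full-grid scale
        inv_src = np.linalg.inv(src.affine)
        sdata = src.data.astype(np.float64)
        # image gradient (per mm) in source space, sampled after warping
        gxyz = np.gradient(sdata, *src.voxel_size)

        # basis matrices at this level (normalized coords of template grid)
        p = [(np.arange(n)[s] + 0.5) / n for n, s in zip(tmp.shape, sl)]
        B = [_dct_basis(p[ax], K) for ax in range(3)]
        affpts = pts @ A[:3, :3].T + A[:3, 3]

        def disp(cflat):
            C = cflat.reshape(K, K, K, 3)
            t = np.einsum("abci,xa->xbci", C, B[0], optimize=True)
            t = np.einsum("xbci,yb->xyci", t, B[1], optimize=True)
            d = np.einsum("xyci,zc->xyzi", t, B[2], optimize=True)
            return d.reshape(-1, 3)

        def fun_grad(cflat):
            d = disp(cflat)
            mapped = affpts + d
            vox = mapped @ inv_src[:3, :3].T + inv_src[:3, 3]
            vals = ndimage.map_coordinates(sdata, vox.T, order=1, mode="constant")
            res = vals - tvals
            f = 0.5 * data_w * float(res @ res) + 0.5 * regularization_weight * float(
                (w * cflat**2).sum()
            )
            grad = np.empty((K, K, K, 3))
            for i in range(3):
                gi = ndimage.map_coordinates(gxyz[i], vox.T, order=1, mode="constant")
                G = (res * gi).reshape(shape)
                t = np.tensordot(B[0], G, axes=(0, 0))  # (K, ny, nz)
                t = np.tensordot(t, B[1], axes=(1, 0))  # (K, nz, K)
                grad[..., i] = np.tensordot(t, B[2], axes=(1, 0))  # (K,K,K)
            g = data_w * grad.ravel() + regularization_weight * w * cflat
            return f, g

        res = optimize.minimize(
            fun_grad, coefs.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        coefs = res.x.reshape(K, K, K, 3)

    return DCTWarp(A, coefs, template.shape, template.affine.copy())


# --------------------------------------------------------------------------
# Jacobians
# --------------------------------------------------------------------------

def jacobian_map(warp: DCTWarp | RigidTransform, report=None) -> BrainImage:
    """Voxelwise determinant of the spatial derivative of the mapping.

    Uses the analytic derivatives of the DCT basis; rigid transforms give a
    constant unit map.  Folding (non-positive determinants) is reported via
    the optional ``report`` dict ({"folding_fraction": f}) but the map is
    still returned.
    """
    if isinstance(warp, RigidTransform):
        raise ValueError("rigid transforms have unit Jacobian; pass a DCTWarp")
    shape, affine = warp.grid_shape, warp.grid_affine
    K = warp.order
    p = [(np.arange(n) + 0.5) / n for n in shape]
    B = [_dct_basis(p[ax], K) for ax in range(3)]
    dB = [_dct_basis_deriv(p[ax], K) for ax in range(3)]
    inv = np.linalg.inv(affine)
    # dp/dx: row k of inv rotation scaled by 1/N_k
    dpdx = inv[:3, :3] / np.asarray(shape)[:, None]

    C = warp.coefficients
    # derivative of displacement wrt normalized coordinate q (3 of them)
    ddisp = np.empty(shape + (3, 3))  # [..., i (component), q (wrt p_q)]
    for q in range(3):
        mats = [dB[ax] if ax == q else B[ax] for ax in range(3)]
        t = np.einsum("abci,xa->xbci", C, mats[0], optimize=True)
        t = np.einsum("xbci,yb->xyci", t, mats[1], optimize=True)
        ddisp[..., q] = np.einsum("xyci,zc->xyzi", t, mats[2], optimize=True)
    # chain rule to world coords: dd_i/dx_j = sum_q dd_i/dp_q * dp_q/dx_j
    J = np.einsum("...iq,qj->...ij", ddisp, dpdx)
    J += warp.affine_part[:3, :3]
    det = np.linalg.det(J)
    if report is not None:
        report["folding_fraction"] = float((det <= 0).mean())
    return BrainImage(det.astype(np.float32), affine)
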