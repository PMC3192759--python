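"""Affine + B-spline free-form deformation (FFD) registration and Jacobians.

The transform convention is fixed -> moving (pull-back): a transform ``T``
maps fixed-image world coordinates to moving-image world coordinates, and
``warp`` resamples the moving image onto the fixed grid as ``I(T(x))``.
Under this convention a Jacobian determinant > 1 means the fixed template
locally expands into the subject; planted subject shrinkage therefore shows
up as J < 1 when the template is the fixed reference.

The total transform composes an affine with a cubic B-spline FFD:
``T(x) = A(x + u(x))`` where ``u`` is the B-spline displacement defined on a
control grid with spacing ``control_spacing`` mm (the grid covers the image
domain plus one boundary ring of control points).

The optimizer is plain gradient descent with step halving on an analytic
gradient, run coarse-to-fine; the similarity metric defaults to negative
normalized cross-correlation (robust to the phantom's multiplicative bias
field), with SSD available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import Image3D

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


@dataclass
class AffineTransform:
    """Affine map ``y = A x + t`` from fixed world mm to moving world mm."""

    linear: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(self.linear)) <= 1e-8:
            raise ValueError("affine linear part is singular")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.translation)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()


def _bspline_weights(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis values at fractional offsets t in [0,1); (n,4)."""
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ],
        axis=-1,
    )


def _bspline_dweights(t: np.ndarray) -> np.ndarray:
    """Derivatives of the four cubic B-spline pieces w.r.t. t; (n,4)."""
    t2 = t * t
    return np.stack(
        [
            -((1 - t) ** 2) / 2.0,
            (3 * t2 - 4 * t) / 2.0,
            (-3 * t2 + 2 * t + 1) / 2.0,
            t2 / 2.0,
        ],
        axis=-1,
    )


@dataclass
class DeformationField:
    """B-spline FFD on a control grid, composed with an optional affine.

    ``control_displacements`` has shape (n0, n1, n2, 3) in mm; control point
    (i, j, k) sits at world mm ``(i - 1) * control_spacing`` relative to the
    domain origin so that the grid covers the domain plus one boundary ring.
    ``domain`` is the fixed (reference) geometry the field is defined on.
    """

    control_spacing: tuple[float, float, float]
    control_displacements: np.ndarray
    domain_shape: tuple[int, int, int]
    domain_spacing: tuple[float, float, float]
    domain_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    affine: AffineTransform = field(default_factory=AffineTransform.identity)

    def __post_init__(self) -> None:
        self.control_spacing = tuple(float(s) for s in self.control_spacing)
        self.control_displacements = np.asarray(
            self.control_displacements, dtype=np.float64
        )
        if not np.all(np.isfinite(self.control_displacements)):
            raise ValueError("control displacements contain non-finite values")
        need = required_control_shape(
            self.domain_shape, self.domain_spacing, self.control_spacing
        )
        have = self.control_displacements.shape[:3]
        if any(h < n for h, n in zip(have, need)):
            raise ValueError(
                f"control grid {have} does not cover domain (needs >= {need})"
            )

    # -- evaluation ---------------------------------------------------------

    def _tap_setup(self, pts_mm: np.ndarray):
        cs = np.asarray(self.control_spacing)
        g = pts_mm / cs + 1.0  # +1: one-ring offset
        i = np.floor(g).astype(np.int64)
        t = g - i
        return i, t

    def displacement(self, pts_mm: np.ndarray) -> np.ndarray:
        """FFD displacement u(x) in mm at local-domain points (n,3)."""
        return self._evaluate(pts_mm, want_grad=False)[0]

    def displacement_and_gradient(self, pts_mm: np.ndarray):
        """Return (u, du/dx) with du/dx of shape (n, 3, 3), mm/mm."""
        return self._evaluate(pts_mm, want_grad=True)

    def _evaluate(self, pts_mm: np.ndarray, want_grad: bool):
        phi = self.control_displacements
        n0, n1, n2 = phi.shape[:3]
        i, t = self._tap_setup(np.atleast_2d(pts_mm))
        w = [_bspline_weights(t[:, a]) for a in range(3)]
        dw = [_bspline_dweights(t[:, a]) for a in range(3)] if want_grad else None
        phi_flat = phi.reshape(-1, 3)
        u = np.zeros((i.shape[0], 3))
        grad = np.zeros((i.shape[0], 3, 3)) if want_grad else None
        cs = np.asarray(self.control_spacing)
        base = i - 1
        for l in range(4):
            i0 = np.clip(base[:, 0] + l, 0, n0 - 1)
            for m in range(4):
                i1 = np.clip(base[:, 1] + m, 0, n1 - 1)
                for n in range(4):
                    i2 = np.clip(base[:, 2] + n, 0, n2 - 1)
                    p = phi_flat[(i0 * n1 + i1) * n2 + i2]
                    wl, wm, wn = w[0][:, l], w[1][:, m], w[2][:, n]
                    u += (wl * wm * wn)[:, None] * p
                    if want_grad:
                        grad[:, :, 0] += (dw[0][:, l] * wm * wn / cs[0])[:, None] * p
                        grad[:, :, 1] += (wl * dw[1][:, m] * wn / cs[1])[:, None] * p
                        grad[:, :, 2] += (wl * wm * dw[2][:, n] / cs[2])[:, None] * p
        return u, grad

    def transform_points(self, pts_world: np.ndarray) -> np.ndarray:
        """Total transform T(x) = A(x + u(x - origin)) at world mm points."""
        pts_world = np.atleast_2d(pts_world)
        local = pts_world - np.asarray(self.domain_origin)
        return self.affine.apply(pts_world + self.displacement(local))

    def grid_points_mm(self) -> np.ndarray:
        """All voxel-center positions of the domain, local mm, (N,3)."""
        idx = np.indices(self.domain_shape).reshape(3, -1).T
        return idx * np.asarray(self.domain_spacing)

    def grid_points_world(self) -> np.ndarray:
        return self.grid_points_mm() + np.asarray(self.domain_origin)

    def copy(self) -> "DeformationField":
        return DeformationField(
            self.control_spacing,
            self.control_displacements.copy(),
            self.domain_shape,
            self.domain_spacing,
            self.domain_origin,
            AffineTransform(self.affine.linear.copy(), self.affine.translation.copy()),
        )

    @classmethod
    def identity_for(
        cls,
        image: Image3D,
        control_spacing: float | tuple[float, float, float] = 10.0,
        affine: AffineTransform | None = None,
    ) -> "DeformationField":
        cs = (
            (control_spacing,) * 3
            if np.isscalar(control_spacing)
            else tuple(control_spacing)
        )
        nshape = required_control_shape(image.shape, image.spacing, cs)
        return cls(
            cs,
            np.zeros(nshape + (3,)),
            image.shape,
            image.spacing,
            image.origin,
            affine or AffineTransform.identity(),
        )


def required_control_shape(shape, spacing, control_spacing) -> tuple[int, int, int]:
    """Control-grid size covering the domain plus one boundary ring."""
    out = []
    for n, sp, cs in zip(shape, spacing, control_spacing):
        gmax = (n - 1) * sp / cs + 1.0
        out.append(int(np.floor(gmax)) + 3)
    return tuple(out)


def random_smooth_field(
    image: Image3D,
    control_spacing: float = 8.0,
    amplitude_mm: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> DeformationField:
    """A random smooth FFD with control displacements ~ N(0, amplitude^2).

    Displacements are mildly smoothed across the control grid and clipped to
    3*amplitude so the field stays diffeomorphic-in-practice at coarse
    control spacing.
    """
    rng = np.random.default_rng(seed)
    f = DeformationField.identity_for(image, control_spacing)
    disp = rng.normal(0.0, amplitude_mm, f.control_displacements.shape)
    disp = ndimage.gaussian_filter(disp, sigma=(0.8, 0.8, 0.8, 0.0))
    f.control_displacements = np.clip(disp, -3 * amplitude_mm, 3 * amplitude_mm)
    return f


# ---------------------------------------------------------------------------
# resampling and Jacobians
# ---------------------------------------------------------------------------


def warp(
    moving: Image3D,
    fld: DeformationField,
    interpolation: str = "linear",
    pad_value: float = 0.0,
) -> Image3D:
    """Pull-back resampling of ``moving`` onto the field's fixed domain.

    Output voxel x takes the moving-image value at T(x).  ``interpolation``
    is 'linear' (default) or 'nearest' (for label maps).
    """
    order = {"linear": 1, "nearest": 0}[interpolation]
    tgt = fld.transform_points(fld.grid_points_world())
    # moving voxel coordinates
    vox = (tgt - np.asarray(moving.origin)) / np.asarray(moving.spacing)
    out = ndimage.map_coordinates(
        moving.data, vox.T, order=order, mode="constant", cval=pad_value
    )
    return Image3D(
        out.reshape(fld.domain_shape), fld.domain_spacing, fld.domain_origin
    )


def warp_labels(labels: np.ndarray, fld: DeformationField) -> np.ndarray:
    """Nearest-neighbour pull-back of an integer label grid on the domain grid."""
    tgt = fld.transform_points(fld.grid_points_world()) - np.asarray(fld.domain_origin)
    vox = tgt / np.asarray(fld.domain_spacing)
    out = ndimage.map_coordinates(
        labels.astype(np.float64), vox.T, order=0, mode="constant", cval=0
    )
    return out.reshape(fld.domain_shape).astype(labels.dtype)


@dataclass
class JacobianMap:
    """det(dT/dx) on the fixed grid; 1 everywhere for the identity."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Jacobian map contains non-finite values")


def jacobian_map(fld: DeformationField) -> JacobianMap:
    """Analytic Jacobian determinant of the total transform A(x + u(x)).

    dT/dx = A_lin (I + du/dx); the B-spline gradient is evaluated in closed
    form at voxel centers.
    """
    pts = fld.grid_points_mm()
    _, grad = fld.displacement_and_gradient(pts)
    jac = np.eye(3)[None] + grad
    jac = fld.affine.linear[None] @ jac
    det = np.linalg.det(jac).reshape(fld.domain_shape)
    return JacobianMap(det, fld.domain_spacing)


# ---------------------------------------------------------------------------
# similarity metrics (value + gradient w.r.t. warped intensities)
# ---------------------------------------------------------------------------


def _metric_ssd(w: np.ndarray, f: np.ndarray):
    r = w - f
    return float(np.mean(r * r)), 2.0 * r / r.size


def _metric_ncc(w: np.ndarray, f: np.ndarray):
    a = w - w.mean()
    b = f - f.mean()
    na = np.linalg.norm(a) + 1e-12
    nb = np.linalg.norm(b) + 1e-12
    ncc = float(a @ b) / (na * nb)
    g = b / (na * nb) - ncc * a / (na * na)
    g -= g.mean()  # chain rule through the mean subtraction
    return -ncc, -g


_METRICS = {"ssd": _metric_ssd, "ncc": _metric_ncc}


class _MovingSampler:
    """Linear sampling of a moving image and its mm-space gradient."""

    def __init__(self, moving: Image3D):
        self.moving = moving
        self.grad = np.stack(
            np.gradient(moving.data, *moving.spacing), axis=0
        )  # (3, X, Y, Z) in intensity/mm

    def values(self, pts_world: np.ndarray) -> np.ndarray:
        vox = (pts_world - np.asarray(self.moving.origin)) / np.asarray(
            self.moving.spacing
        )
        return ndimage.map_coordinates(
            self.moving.data, vox.T, order=1, mode="nearest"
        )

    def values_and_gradient(self, pts_world: np.ndarray):
        vox = (
            (pts_world - np.asarray(self.moving.origin))
            / np.asarray(self.moving.spacing)
        ).T
        vals = ndimage.map_coordinates(self.moving.data, vox, order=1, mode="nearest")
        g = np.stack(
            [
                ndimage.map_coordinates(self.grad[a], vox, order=1, mode="nearest")
                for a in range(3)
            ],
            axis=1,
        )
        return vals, g


def _center_of_mass_mm(img: Image3D) -> np.ndarray:
    d = img.data - img.data.min()
    tot = d.sum()
    if tot <= 0:
        raise ValueError("image has no intensity mass")
    com = np.array(ndimage.center_of_mass(d))
    return com * np.asarray(img.spacing) + np.asarray(img.origin)


def _downsample(img: Image3D, factor: int) -> Image3D:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img.data, sigma=0.5 * factor)
    data = sm[::factor, ::factor, ::factor]
    sp = tuple(s * factor for s in img.spacing)
    return Image3D(data, sp, img.origin)


# ---------------------------------------------------------------------------
# affine registration
# ---------------------------------------------------------------------------


def affine_align(
    moving: Image3D,
    fixed: Image3D,
    metric: str = "ncc",
    iters: int = 60,
    levels: tuple[int, ...] = (4, 2, 1),
    translation_only: bool = False,
    return_trace: bool = False,
):
    """Affine registration by multi-resolution gradient descent.

    Initializes with the center-of-mass translation, then minimizes the
    chosen dissimilarity (default negative NCC) over the 12 affine
    parameters with analytic gradients and step halving.  The best-cost
    trace is monotone non-increasing by construction.
    """
    metric_fn = _METRICS[metric]
    t0 = _center_of_mass_mm(moving) - _center_of_mass_mm(fixed)
    A = np.eye(3)
    t = t0.copy()
    trace: list[float] = []
    # characteristic length scales linear-part gradient to mm steps
    L = 0.5 * max(n * s for n, s in zip(fixed.shape, fixed.spacing))

    for factor in levels:
        fx = _downsample(fixed, factor)
        sampler = _MovingSampler(moving)
        pts = (
            np.indices(fx.shape).reshape(3, -1).T * np.asarray(fx.spacing)
            + np.asarray(fx.origin)
        )
        fvals = fx.data.ravel()
        if not np.any(np.isfinite(fvals)):
            raise ValueError("fixed image empty at this resolution")
        step = max(fx.spacing) * 1.0
        cost = None
        for _ in range(iters):
            tgt = pts @ A.T + t
            w, g = sampler.values_and_gradient(tgt)
            cost, dcdw = metric_fn(w, fvals)
            if trace and cost > trace[-1]:
                trace.append(trace[-1])
            else:
                trace.append(cost)
            gw = dcdw[:, None] * g  # (n,3) dcost/dT(x)
            grad_t = gw.sum(axis=0)
            grad_A = np.zeros((3, 3)) if translation_only else gw.T @ pts
            # preconditioned, inf-norm-normalized step
            gnorm = max(np.abs(grad_t).max(), np.abs(grad_A).max() * L)
            if gnorm < 1e-14:
                break
            while step > 1e-3:
                A_new = A - step * grad_A * L / gnorm * (1.0 / L)
                t_new = t - step * grad_t / gnorm
                w_new = sampler.values(pts @ A_new.T + t_new)
                c_new = metric_fn(w_new, fvals)[0]
                if c_new < cost - 1e-12:
                    A, t = A_new, t_new
                    step *= 1.2
                    break
                step *= 0.5
            else:
                break
    result = AffineTransform(A, t)
    if return_trace:
        return result, trace
    return result


# ---------------------------------------------------------------------------
# FFD registration
# ---------------------------------------------------------------------------


def _bending_energy_and_grad(phi: np.ndarray):
    """Discrete bending penalty: mean squared second differences per axis."""
    e = 0.0
    grad = np.zeros_like(phi)
    n = phi[..., 0].size
    for ax in range(3):
        if phi.shape[ax] < 3:
            continue
        d2 = ndimage.correlate1d(phi, [1.0, -2.0, 1.0], axis=ax, mode="constant")
        e += float(np.sum(d2 * d2)) / n
        grad += 2.0 * ndimage.correlate1d(
            d2, [1.0, -2.0, 1.0], axis=ax, mode="constant"
        ) / n
    return e, grad


class _TapCache:
    """Precomputed B-spline tap indices/weights for a fixed sample grid."""

    def __init__(self, fld: DeformationField, pts_mm: np.ndarray):
        n0, n1, n2 = fld.control_displacements.shape[:3]
        self.ncflat = n0 * n1 * n2
        i, tt = fld._tap_setup(pts_mm)
        w = [_bspline_weights(tt[:, a]) for a in range(3)]
        base = i - 1
        self.flat_idx = []
        self.weights = []
        for l in range(4):
            i0 = np.clip(base[:, 0] + l, 0, n0 - 1)
            for m in range(4):
                i1 = np.clip(base[:, 1] + m, 0, n1 - 1)
                for n in range(4):
                    i2 = np.clip(base[:, 2] + n, 0, n2 - 1)
                    self.flat_idx.append(((i0 * n1 + i1) * n2 + i2).astype(np.int64))
                    self.weights.append(w[0][:, l] * w[1][:, m] * w[2][:, n])

    def interpolate(self, phi_flat: np.ndarray) -> np.ndarray:
        out = np.zeros((self.flat_idx[0].size, phi_flat.shape[1]))
        for idx, wt in zip(self.flat_idx, self.weights):
            out += wt[:, None] * phi_flat[idx]
        return out

    def scatter(self, g: np.ndarray) -> np.ndarray:
        out = np.zeros((self.ncflat, g.shape[1]))
        for idx, wt in zip(self.flat_idx, self.weights):
            for c in range(g.shape[1]):
                out[:, c] += np.bincount(idx, weights=wt * g[:, c], minlength=self.ncflat)
        return out


def ffd_register(
    moving: Image3D,
    fixed: Image3D,
    control_spacing_mm: float | tuple[float, float, float] = 10.0,
    metric: str = "ncc",
    levels: tuple[int, ...] = (2, 1),
    iters: int = 30,
    reg_weight: float = 0.001,
    affine: AffineTransform | None = None,
    init: DeformationField | None = None,
) -> DeformationField:
    """Cubic B-spline FFD registration, coarse-to-fine gradient descent.

    A bending-energy penalty weighted by ``reg_weight`` regularizes the
    control displacements.  The final total cost never exceeds the initial
    cost (step halving only accepts improvements); divergence (non-finite
    cost) raises with the iteration index.
    """
    cs = (
        (control_spacing_mm,) * 3
        if np.isscalar(control_spacing_mm)
        else tuple(control_spacing_mm)
    )
    if min(cs) < 2 * min(fixed.spacing):
        raise ValueError("control spacing must be >= 2 voxels")
    metric_fn = _METRICS[metric]
    fld = (
        init.copy()
        if init is not None
        else DeformationField.identity_for(fixed, cs, affine)
    )
    if affine is not None:
        fld.affine = affine
    phi = fld.control_displacements
    A_lin_T = fld.affine.linear.T

    it_global = 0
    for factor in levels:
        fx = _downsample(fixed, factor)
        sampler = _MovingSampler(moving)
        pts_local = np.indices(fx.shape).reshape(3, -1).T * np.asarray(fx.spacing)
        # restrict the metric to the (dilated) fixed-image foreground
        fg = ndimage.binary_dilation(
            fx.data > 0.02 * fx.data.max(), iterations=2
        ).ravel()
        if fg.sum() < 100:
            fg = np.ones(fx.data.size, dtype=bool)
        pts_local = pts_local[fg]
        pts_world0 = pts_local + np.asarray(fx.origin)
        fvals = fx.data.ravel()[fg]
        taps = _TapCache(fld, pts_local)
        phi_flat = phi.reshape(-1, 3)
        step = min(cs) / 8.0

        def total_cost(pf):
            u = taps.interpolate(pf)
            w = sampler.values(fld.affine.apply(pts_world0 + u))
            c, _ = metric_fn(w, fvals)
            e, _ = _bending_energy_and_grad(pf.reshape(phi.shape))
            return c + reg_weight * e

        cost = total_cost(phi_flat)
        for _ in range(iters):
            it_global += 1
            u = taps.interpolate(phi_flat)
            w, gm = sampler.values_and_gradient(fld.affine.apply(pts_world0 + u))
            c_sim, dcdw = metric_fn(w, fvals)
            if not np.isfinite(c_sim):
                raise RuntimeError(f"FFD registration diverged at iteration {it_global}")
            e_bend, g_bend = _bending_energy_and_grad(phi)
            cost = c_sim + reg_weight * e_bend
            # dC/du = dcdw * (A^T grad_moving)
            g_pts = dcdw[:, None] * (gm @ A_lin_T)
            g_phi = taps.scatter(g_pts) + reg_weight * g_bend.reshape(-1, 3)
            gmax = np.abs(g_phi).max()
            if gmax < 1e-14:
                break
            improved = False
            while step > 1e-3:
                cand = phi_flat - step * g_phi / gmax
                c_new = total_cost(cand)
                if c_new < cost - 1e-12:
                    phi_flat = cand
                    phi = phi_flat.reshape(phi.shape)
                    cost = c_new
                    step *= 1.2
                    improved = True
                    break
                step *= 0.5
            if not improved:
                break
        fld.control_displacements = phi

    return fld
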