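"""Rigid and non-rigid (demons-style) intensity-based registration.

The non-rigid stage estimates the 3D displacement of the meniscus
between the unloaded (fixed) and loaded (moving) images. It is a
multi-resolution, greedy demons-type scheme driven by a windowed
normalized cross-correlation similarity: at each iteration the local-CC
gradient force is computed, scaled by a step size, Gaussian-smoothed,
and composed into the accumulated field, which is itself smoothed by
the same Gaussian — the classic fluid/elastic regularization pair.
Parameter semantics (CC window radius, step size, smoothing sigma,
per-level iteration caps, energy tolerance) follow the registration
protocol of the loading study this pipeline implements: radius 2,
step 0.25, sigma 3, levels (1000, 500, 250, 100), tolerance 1e-6.
The sigma regularizes the UPDATE (fluid-like regularization, the
Gauss[3,0] convention); an optional second sigma smooths the total
field (elastic-like) but defaults to 0, since repeated total-field
smoothing systematically dilutes strain gradients across the thin
axial extent of a meniscus.

The returned field maps unloaded (fixed) voxel positions to their
loaded positions, so strains computed from it are material strains
relative to the unloaded state. Everything here is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .volumes import DisplacementField, ImageVolume, LabelMask

__all__ = [
    "RigidTransform",
    "RegistrationConfig",
    "local_cross_correlation",
    "rigid_register",
    "nonrigid_register",
    "invert_convention",
]

log = logging.getLogger(__name__)

_VAR_EPS = 1e-10


@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid transform: rotations (radians) about the grid
    x, y, z axes applied in that order about ``center`` (world mm),
    then translation (mm)."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform world points, shape (..., 3)."""
        R = self.matrix()
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (points - c) @ R.T + c + t

    def inverse(self) -> "RigidTransform":
        R = self.matrix()
        # inverse as a matrix+offset pair re-expressed about the same center
        t = np.asarray(self.translation)
        c = np.asarray(self.center)
        Rinv = R.T
        # p = Rinv (p' - c - t) + c  =>  offset relative to the center form
        tinv = Rinv @ (-t)
        # recover Euler angles of Rinv (Rz Ry Rx convention)
        ry = -np.arcsin(np.clip(Rinv[2, 0], -1, 1))
        rx = np.arctan2(Rinv[2, 1], Rinv[2, 2])
        rz = np.arctan2(Rinv[1, 0], Rinv[0, 0])
        return RigidTransform(rotation=(rx, ry, rz), translation=tuple(tinv), center=tuple(c))


@dataclass(frozen=True)
class RegistrationConfig:
    """Non-rigid registration parameters (defaults per the protocol)."""

    metric_window_radius: int = 2
    step_size: float = 0.25
    smoothing_sigma: float = 3.0
    iterations_per_level: tuple[int, ...] = (1000, 500, 250, 100)
    n_levels: int = 4
    tolerance: float = 1e-6
    total_field_sigma: float = 0.0
    rigid_on_mask_intensities: bool = False

    def __post_init__(self) -> None:
        if self.metric_window_radius < 1:
            raise ValueError("metric_window_radius must be >= 1")
        if self.step_size <= 0 or self.smoothing_sigma <= 0 or self.tolerance <= 0:
            raise ValueError("step_size, smoothing_sigma, tolerance must be positive")
        if len(self.iterations_per_level) != self.n_levels:
            raise ValueError("iterations_per_level length must equal n_levels")
        if any(i <= 0 for i in self.iterations_per_level):
            raise ValueError("iteration caps must be positive")


def _window_stats(f: np.ndarray, m: np.ndarray, radius: int):
    """Window means / centered covariance sums over a cubic window."""
    size = 2 * radius + 1
    uf = lambda a: ndimage.uniform_filter(a, size=size, mode="nearest")
    mu_f, mu_m = uf(f), uf(m)
    cov = uf(f * m) - mu_f * mu_m
    var_f = np.maximum(uf(f * f) - mu_f * mu_f, 0.0)
    var_m = np.maximum(uf(m * m) - mu_m * mu_m, 0.0)
    return mu_f, mu_m, cov, var_f, var_m


def local_cross_correlation(fixed: ImageVolume, moving: ImageVolume, radius: int = 2) -> ImageVolume:
    """Per-voxel normalized cross-correlation over a cubic window of the
    given radius (voxels), in [-1, 1]; 0 where either local variance
    vanishes."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if not fixed.same_grid(moving):
        raise ValueError("fixed and moving grids are not congruent")
    f = fixed.data.astype(float)
    m = moving.data.astype(float)
    _, _, cov, var_f, var_m = _window_stats(f, m, radius)
    denom = np.sqrt(var_f * var_m)
    cc = np.where(denom > _VAR_EPS, cov / np.maximum(denom, _VAR_EPS), 0.0)
    return ImageVolume(data=np.clip(cc, -1.0, 1.0),
                       spacing=fixed.spacing.copy(), origin=fixed.origin.copy())


def _resample_rigid(moving: ImageVolume, transform: RigidTransform,
                    shape, spacing, origin) -> np.ndarray:
    """Sample moving at T(x) for every voxel center x of the fixed grid."""
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    world = np.stack([origin[a] + idx[a] * spacing[a] for a in range(3)], axis=-1)
    mapped = transform.apply(world.reshape(-1, 3))
    vox = (mapped - moving.origin) / moving.spacing
    out = ndimage.map_coordinates(moving.data.astype(float), vox.T, order=1,
                                  mode="constant", cval=float(np.min(moving.data)))
    return out.reshape(shape)


def _ncc(a: np.ndarray, b: np.ndarray, w: np.ndarray | None = None) -> float:
    if w is not None:
        sel = w > 0
        a, b = a[sel], b[sel]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > _VAR_EPS else 0.0


def rigid_register(
    fixed_mask: LabelMask,
    moving: ImageVolume,
    config: RegistrationConfig = RegistrationConfig(),
    fixed_intensity: ImageVolume | None = None,
) -> tuple[RigidTransform, ImageVolume]:
    """6-parameter rigid alignment of ``moving`` to the fixed reference.

    The fixed reference is either the binary mask itself (e.g. the tibia
    segmentation; ``rigid_on_mask_intensities=False``) or a fixed
    intensity image evaluated within a dilated neighborhood of the mask
    (``rigid_on_mask_intensities=True``, requires ``fixed_intensity``).
    Multi-resolution Powell ascent on global normalized cross-correlation.
    """
    if config.rigid_on_mask_intensities:
        if fixed_intensity is None:
            raise ValueError("rigid_on_mask_intensities requires fixed_intensity")
        ref = fixed_intensity.data.astype(float)
        weight = ndimage.binary_dilation(fixed_mask.labels > 0, iterations=3).astype(float)
    else:
        ref = (fixed_mask.labels > 0).astype(float)
        weight = None
    if not (fixed_mask.labels > 0).any():
        raise ValueError("fixed mask is empty — nothing to align to")

    shape = fixed_mask.shape
    spacing = fixed_mask.spacing
    origin = fixed_mask.origin
    center = origin + (np.asarray(shape) - 1) / 2.0 * spacing

    def objective(params, factor):
        tr = RigidTransform(rotation=tuple(params[:3]), translation=tuple(params[3:]),
                            center=tuple(center))
        sub_shape = tuple(max(2, s // factor) for s in shape)
        sub_spacing = spacing * np.asarray(shape) / np.asarray(sub_shape)
        res = _resample_rigid(moving, tr, sub_shape, sub_spacing, origin)
        zoomed_ref = ndimage.zoom(ref, np.asarray(sub_shape) / np.asarray(shape), order=1) \
            if factor != 1 else ref
        zw = None
        if weight is not None:
            zw = ndimage.zoom(weight, np.asarray(sub_shape) / np.asarray(shape), order=0) \
                if factor != 1 else weight
        return -_ncc(zoomed_ref, res, zw)

    params = np.zeros(6)
    for factor in (4, 2, 1):
        result = optimize.minimize(
            objective, params, args=(factor,), method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-6, "maxiter": 200},
        )
        params = result.x
    transform = RigidTransform(rotation=tuple(params[:3]), translation=tuple(params[3:]),
                               center=tuple(center))
    resampled = ImageVolume(data=_resample_rigid(moving, transform, shape, spacing, origin),
                            spacing=spacing.copy(), origin=origin.copy())
    if -objective(params, 1) < 0.1:
        log.warning("rigid registration finished with very low similarity (%.3f); "
                    "check that the volumes overlap", -objective(params, 1))
    return transform, resampled


# ---------------------------------------------------------------------------
# non-rigid (demons-style) registration


def _warp_by_field(moving: np.ndarray, u_vox: np.ndarray) -> np.ndarray:
    """Sample moving(x + u(x)) with u in voxel units."""
    shape = moving.shape
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    coords = [idx[a] + u_vox[..., a] for a in range(3)]
    return ndimage.map_coordinates(moving, coords, order=1, mode="nearest")


def _compose(u_vox: np.ndarray, upd_vox: np.ndarray) -> np.ndarray:
    """Compositive update: (upd ∘ u)(x) = upd(x) + u(x + upd(x))."""
    out = np.empty_like(u_vox)
    shape = u_vox.shape[:3]
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    coords = [idx[a] + upd_vox[..., a] for a in range(3)]
    for a in range(3):
        out[..., a] = upd_vox[..., a] + ndimage.map_coordinates(
            u_vox[..., a], coords, order=1, mode="nearest")
    return out


def _cc_force(f: np.ndarray, m: np.ndarray, radius: int) -> tuple[np.ndarray, float]:
    """Local-CC gradient force on the (warped) moving image and the
    current energy 1 - mean CC over informative voxels.

    With window-demeaned images fc, mc and window sums A = <fc mc>,
    B = <fc^2>, C = <mc^2>, the derivative of CC^2 = A^2/(B C) with
    respect to the moving intensities is 2A/(BC) (fc - (A/C) mc) ∇m.
    """
    mu_f, mu_m, A, B, C = _window_stats(f, m, radius)
    fc = f - mu_f
    mc = m - mu_m
    good = (B > _VAR_EPS) & (C > _VAR_EPS)
    denom = np.where(good, B * C, 1.0)
    scalar = np.where(good, 2.0 * A / denom * (fc - np.where(good, A / np.maximum(C, _VAR_EPS), 0.0) * mc), 0.0)
    grads = np.gradient(m)
    force = np.stack([scalar * g for g in grads], axis=-1)
    cc = np.where(good, A / np.sqrt(np.maximum(B * C, _VAR_EPS)), 0.0)
    energy = 1.0 - float(cc[good].mean()) if good.any() else 1.0
    return force, energy


def _downsample(img: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma=1.0)[::2, ::2, ::2]


def nonrigid_register(
    fixed: ImageVolume,
    moving: ImageVolume,
    config: RegistrationConfig = RegistrationConfig(),
) -> DisplacementField:
    """Estimate the displacement field u with moving(x + u(x)) ≈ fixed(x).

    Multi-resolution (factor-2 pyramid, coarsest first): at each level,
    iterate local-CC force → scale to at most ``step_size`` voxels →
    Gaussian-smooth the update → compose with the accumulated field →
    Gaussian-smooth the field, until the relative energy change drops
    below ``tolerance`` or the level's iteration cap is reached.
    """
    if not fixed.same_grid(moving):
        raise ValueError("fixed and moving grids are not congruent")
    f0 = fixed.data.astype(float)
    m0 = moving.data.astype(float)
    if not (np.all(np.isfinite(f0)) and np.all(np.isfinite(m0))):
        raise ValueError("NaN or Inf in input images")
    scale = max(f0.std(), _VAR_EPS)
    f0, m0 = f0 / scale, m0 / scale

    pyramid = [(f0, m0)]
    for _ in range(config.n_levels - 1):
        f, m = pyramid[-1]
        if min(f.shape) < 8:
            break
        pyramid.append((_downsample(f), _downsample(m)))
    pyramid = pyramid[::-1]  # coarsest first

    u_vox: np.ndarray | None = None  # in voxels of the current level
    n_levels = len(pyramid)
    for li, (f, m) in enumerate(pyramid):
        cap = config.iterations_per_level[min(li + (config.n_levels - n_levels), config.n_levels - 1)]
        if u_vox is None:
            u_vox = np.zeros(f.shape + (3,))
        else:
            up = np.empty(f.shape + (3,))
            zoom = np.asarray(f.shape) / np.asarray(u_vox.shape[:3])
            for a in range(3):
                up[..., a] = ndimage.zoom(u_vox[..., a], zoom, order=1) * zoom[a]
            u_vox = up
        prev_energy = np.inf
        it = 0
        for it in range(1, cap + 1):
            warped = _warp_by_field(m, u_vox)
            force, energy = _cc_force(f, warped, config.metric_window_radius)
            if prev_energy < np.inf and abs(prev_energy - energy) <= config.tolerance * abs(prev_energy):
                break
            prev_energy = energy
            mag = np.sqrt((force ** 2).sum(axis=-1))
            if not (mag > _VAR_EPS).any():
                break
            # robust normalization: scale so a typical strong force moves
            # step_size voxels, then cap every voxel at step_size
            peak = np.percentile(mag[mag > _VAR_EPS], 95)
            if peak < _VAR_EPS:
                break
            upd = force * (config.step_size / peak)
            umag = np.sqrt((upd ** 2).sum(axis=-1))
            cap = np.minimum(1.0, config.step_size / np.maximum(umag, _VAR_EPS))
            upd *= cap[..., None]
            for a in range(3):
                upd[..., a] = ndimage.gaussian_filter(upd[..., a], config.smoothing_sigma)
            u_vox = _compose(u_vox, upd)
            if config.total_field_sigma > 0:
                for a in range(3):
                    u_vox[..., a] = ndimage.gaussian_filter(u_vox[..., a],
                                                            config.total_field_sigma)
        log.info("level %d/%d (%s): %d iterations, energy %.6f",
                 li + 1, n_levels, "x".join(map(str, f.shape)), it, prev_energy)

    assert u_vox is not None
    if u_vox.shape[:3] != fixed.shape:
        up = np.empty(fixed.shape + (3,))
        zoom = np.asarray(fixed.shape) / np.asarray(u_vox.shape[:3])
        for a in range(3):
            up[..., a] = ndimage.zoom(u_vox[..., a], zoom, order=1) * zoom[a]
        u_vox = up
    u_mm = u_vox * fixed.spacing
    return DisplacementField(vectors=u_mm, spacing=fixed.spacing.copy(), origin=fixed.origin.copy())


def invert_convention(fld: DisplacementField, n_iter: int = 30, tol_mm: float = 1e-4) -> DisplacementField:
    """Fixed-point inversion: find v with v(x) = -u(x + v(x)).

    Exact for constant fields; for smooth fields the composition
    residual is reported via the module logger if it stays large.
    """
    u_vox = fld.vectors / fld.spacing
    shape = fld.shape
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    v = np.zeros_like(u_vox)
    for _ in range(n_iter):
        coords = [idx[a] + v[..., a] for a in range(3)]
        u_at = np.stack([ndimage.map_coordinates(u_vox[..., a], coords, order=1, mode="nearest")
                         for a in range(3)], axis=-1)
        v_new = -u_at
        delta = np.max(np.abs(v_new - v) * fld.spacing)
        v = v_new
        if delta < tol_mm:
            break
    coords = [idx[a] + v[..., a] for a in range(3)]
    u_at = np.stack([ndimage.map_coordinates(u_vox[..., a], coords, order=1, mode="nearest")
                     for a in range(3)], axis=-1)
    residual = np.median(np.sqrt(((v + u_at) ** 2).sum(axis=-1)))
    if residual > 0.1:
        log.warning("field inversion residual median %.3f voxels — field may not be invertible", residual)
    return DisplacementField(vectors=v * fld.spacing, spacing=fld.spacing.copy(), origin=fld.origin.copy())
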