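"""Synthetic study inputs: meniscus-shaped phantoms, ground-truth
deformation fields, MRI-like volumes, and two-group strain cohorts.

The phantom emulates what the real study measured on cadaveric knees:
a C-shaped wedge of fibrocartilage (annular sector in plan view, height
tapering from the outer rim to the inner edge) imaged at
0.4 x 0.4 x 0.6 mm voxel spacing, compressed axially at load levels
expressed as fractions of donor body weight. Ground-truth displacement
fields are analytic, so every downstream stage (registration, meshing,
strain, statistics) can be validated against a known answer — something
the cadaver data could never offer.

Sign convention: compressive normal strain is negative throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import DisplacementField, ImageVolume, LabelMask

__all__ = [
    "BODY",
    "ARA",
    "PRA",
    "REGIONS",
    "DIRECTIONS",
    "PhantomGeometry",
    "DeformationSpec",
    "CohortSpec",
    "make_meniscus_mask",
    "make_displacement",
    "warp_image",
    "synthesize_specimen",
    "synthesize_cohort",
    "region_level",
]

# mask label codes
BODY, ARA, PRA = 1, 2, 3

REGIONS = ("ARA", "AH", "PI", "PH", "PRA")
DIRECTIONS = ("axial", "circumferential", "radial")


@dataclass(frozen=True)
class PhantomGeometry:
    """C-shaped wedge meniscus geometry.

    The body occupies the annular sector ``inner_radius <= r <= outer_radius``
    over ``angular_span`` degrees starting (counterclockwise) at
    ``start_angle``; each open end carries a root-attachment extension of
    ``attachment_span`` degrees. Height tapers linearly from
    ``peripheral_height`` at the outer rim to ``inner_height`` at the
    inner edge — the interposed wedge shape that converts axial
    compression into circumferential (hoop) tension.
    """

    center: tuple[float, float] = (0.0, 0.0)
    inner_radius: float = 15.0
    outer_radius: float = 30.0
    angular_span: float = 280.0
    attachment_span: float = 15.0
    peripheral_height: float = 8.0
    inner_height: float = 2.0
    start_angle: float = 40.0
    z_base: float = 2.0
    grid_shape: tuple[int, int, int] = (96, 96, 24)
    spacing: tuple[float, float, float] = (0.8, 0.8, 0.6)
    origin: tuple[float, float, float] = (-38.4, -38.4, 0.0)

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")
        if not 0 < self.angular_span <= 360:
            raise ValueError("angular_span must lie in (0, 360]")
        if self.attachment_span < 0:
            raise ValueError("attachment_span must be >= 0")
        if not 0 < self.inner_height <= self.peripheral_height:
            raise ValueError("need 0 < inner_height <= peripheral_height")

    @classmethod
    def paper_resolution(cls, **kw) -> "PhantomGeometry":
        """Geometry at the acquisition voxel size (0.4 x 0.4 x 0.6 mm)."""
        defaults = dict(
            grid_shape=(192, 192, 24),
            spacing=(0.4, 0.4, 0.6),
            origin=(-38.4, -38.4, 0.0),
        )
        defaults.update(kw)
        return cls(**defaults)


def _grid_world(shape, spacing, origin):
    """World coordinates of voxel centers, as three broadcastable arrays."""
    ax = [origin[d] + spacing[d] * np.arange(shape[d]) for d in range(3)]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angle differences into [0, 360)."""
    return np.mod(a, 360.0)


def make_meniscus_mask(geom: PhantomGeometry) -> LabelMask:
    """Rasterize the C-shaped wedge onto the voxel grid.

    Voxels whose CENTERS lie in the body sector get label ``BODY``; the
    angular extensions at the C's open ends get ``ARA`` (anterior side,
    at ``start_angle``) and ``PRA`` (posterior side, at
    ``start_angle + angular_span``).
    """
    shape, spacing, origin = geom.grid_shape, geom.spacing, geom.origin
    X, Y, Z = _grid_world(shape, spacing, origin)
    dx, dy = X - geom.center[0], Y - geom.center[1]
    r = np.sqrt(dx * dx + dy * dy)
    theta = np.degrees(np.arctan2(dy, dx))

    radial_ok = (r >= geom.inner_radius) & (r <= geom.outer_radius)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.clip((r - geom.inner_radius) / (geom.outer_radius - geom.inner_radius), 0, 1)
    height = geom.inner_height + (geom.peripheral_height - geom.inner_height) * frac
    z_ok = (Z >= geom.z_base) & (Z <= geom.z_base + height)

    rel = _wrap_deg(theta - geom.start_angle)
    if geom.angular_span >= 360.0:
        in_body = np.ones_like(rel, dtype=bool)
    else:
        in_body = rel <= geom.angular_span
    in_ara = (_wrap_deg(geom.start_angle - theta) <= geom.attachment_span) & ~in_body
    in_pra = (_wrap_deg(theta - geom.start_angle - geom.angular_span) <= geom.attachment_span) & ~in_body

    base = radial_ok & z_ok
    labels = np.zeros(np.broadcast_shapes(base.shape, in_body.shape), dtype=np.int32)
    labels[np.broadcast_to(base & in_body, labels.shape)] = BODY
    if geom.attachment_span > 0:
        labels[np.broadcast_to(base & in_ara, labels.shape)] = ARA
        labels[np.broadcast_to(base & in_pra, labels.shape)] = PRA
    if not labels.any():
        raise ValueError("geometry produced an empty mask — check grid bounds")
    hi_world = np.asarray(origin) + (np.asarray(shape) - 1) * np.asarray(spacing)
    need = geom.outer_radius
    if (geom.center[0] - need < origin[0] or geom.center[1] - need < origin[1]
            or geom.center[0] + need > hi_world[0] or geom.center[1] + need > hi_world[1]):
        raise ValueError("geometry exceeds grid bounds in-plane")
    return LabelMask(labels=labels, spacing=np.asarray(spacing, float), origin=np.asarray(origin, float))


@dataclass(frozen=True)
class DeformationSpec:
    """Analytic ground-truth deformation.

    Modes and their ``params`` keys:

    - ``affine``: ``matrix`` (3x3 displacement gradient A), ``offset`` (b);
      u = A (p - ref) + b, ``ref`` defaulting to the origin.
    - ``uniform_axial``: ``strain`` (signed, e.g. -0.05), ``z_ref`` (mm);
      u = (0, 0, strain * (z - z_ref)).
    - ``radial``: ``alpha``, ``center`` (2-vec); in-plane u = alpha (p - c).
    - ``rigid``: ``angle_deg`` about the z axis, ``center`` (2-vec),
      ``translation`` (3-vec); u = R p + t - p.
    - ``gaussian_bump``: ``center`` (3-vec mm), ``amplitude`` (3-vec mm),
      ``width`` (mm); u = amplitude * exp(-|p - c|^2 / (2 width^2)).
    - ``wedge_axial``: ``profile`` — list of (theta_lo_deg, theta_hi_deg,
      strain) sectors about ``center`` — plus ``default`` strain and
      ``z_ref``; axial strain depends on the angular sector, emulating
      regionally varying compression.
    - ``confined_axial``: ``strain``, ``z_base``, ``z_top``; axial ramp
      confined to the slab — u_z = strain * (clamp(z, z_base, z_top) -
      z_base) — so everything above the slab translates as a plateau
      (the femur riding down on the compressed tissue) and everything
      below stays put (the tibial side). Inside the slab the strain is
      exactly ``strain``, as for ``uniform_axial``.
    - ``composite``: ``members`` — ordered list of DeformationSpec, summed.
    """

    mode: str
    params: dict = field(default_factory=dict)

    _MODES = ("affine", "uniform_axial", "radial", "rigid", "gaussian_bump",
              "wedge_axial", "confined_axial", "composite")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown deformation mode {self.mode!r}")


def _evaluate_field(spec: DeformationSpec, X, Y, Z) -> np.ndarray:
    p = spec.params
    shape = np.broadcast_shapes(X.shape, Y.shape, Z.shape)
    u = np.zeros(shape + (3,))
    if spec.mode == "affine":
        A = np.asarray(p["matrix"], dtype=float)
        b = np.asarray(p.get("offset", np.zeros(3)), dtype=float)
        ref = np.asarray(p.get("ref", np.zeros(3)), dtype=float)
        for a in range(3):
            u[..., a] = A[a, 0] * (X - ref[0]) + A[a, 1] * (Y - ref[1]) + A[a, 2] * (Z - ref[2]) + b[a]
    elif spec.mode == "uniform_axial":
        u[..., 2] = p["strain"] * (Z - p.get("z_ref", 0.0))
    elif spec.mode == "radial":
        c = np.asarray(p.get("center", (0.0, 0.0)), dtype=float)
        u[..., 0] = p["alpha"] * (X - c[0])
        u[..., 1] = p["alpha"] * (Y - c[1])
    elif spec.mode == "rigid":
        ang = np.radians(p.get("angle_deg", 0.0))
        c = np.asarray(p.get("center", (0.0, 0.0)), dtype=float)
        t = np.asarray(p.get("translation", np.zeros(3)), dtype=float)
        ca, sa = np.cos(ang), np.sin(ang)
        dx, dy = X - c[0], Y - c[1]
        u[..., 0] = ca * dx - sa * dy + c[0] - X + t[0]
        u[..., 1] = sa * dx + ca * dy + c[1] - Y + t[1]
        u[..., 2] = np.broadcast_to(t[2], shape)
    elif spec.mode == "gaussian_bump":
        c = np.asarray(p["center"], dtype=float)
        amp = np.asarray(p["amplitude"], dtype=float)
        w = float(p["width"])
        g = np.exp(-((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) / (2 * w * w))
        for a in range(3):
            u[..., a] = amp[a] * g
    elif spec.mode == "wedge_axial":
        c = np.asarray(p.get("center", (0.0, 0.0)), dtype=float)
        theta = np.degrees(np.arctan2(Y - c[1], X - c[0]))
        eps = np.full(shape, float(p.get("default", 0.0)))
        for lo, hi, val in p["profile"]:
            sel = _wrap_deg(theta - lo) <= _wrap_deg(hi - lo)
            eps[np.broadcast_to(sel, shape)] = val
        u[..., 2] = eps * (Z - p.get("z_ref", 0.0))
    elif spec.mode == "confined_axial":
        z0, z1 = p["z_base"], p["z_top"]
        u[..., 2] = p["strain"] * (np.clip(Z, z0, z1) - z0)
    elif spec.mode == "composite":
        for member in p["members"]:
            u += _evaluate_field(member, X, Y, Z)
    return u


def make_displacement(spec: DeformationSpec, grid) -> DisplacementField:
    """Evaluate an analytic deformation at every voxel center of ``grid``
    (any object with shape/spacing/origin)."""
    X, Y, Z = _grid_world(grid.shape, grid.spacing, grid.origin)
    u = _evaluate_field(spec, X, Y, Z)
    return DisplacementField(vectors=u, spacing=np.asarray(grid.spacing, float).copy(),
                             origin=np.asarray(grid.origin, float).copy())


def warp_image(vol: ImageVolume, fld: DisplacementField, background: float = 0.0,
               n_iter: int = 10) -> ImageVolume:
    """Produce the "loaded" image of ``vol`` under forward field ``fld``.

    The field maps reference positions x to deformed positions x + u(x).
    The deformed image L satisfies L(x + u(x)) = vol(x); we evaluate it by
    backward warping: for every output voxel y, the preimage x solves
    x = y - u(x), found by fixed-point iteration, then vol is sampled
    trilinearly at x. Out-of-grid samples take ``background``.
    """
    if not vol.same_grid(fld):
        raise ValueError("image and field grids are not congruent")
    shape = vol.shape
    sp = vol.spacing
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    y_vox = np.stack(idx, axis=-1)  # output voxel-center indices
    u_vox = fld.vectors / sp  # field in voxel units
    x = y_vox.copy()
    for _ in range(n_iter):
        coords = [x[..., a] for a in range(3)]
        u_at_x = np.stack(
            [ndimage.map_coordinates(u_vox[..., a], coords, order=1, mode="nearest") for a in range(3)],
            axis=-1,
        )
        x_new = y_vox - u_at_x
        if np.max(np.abs(x_new - x)) < 1e-4:
            x = x_new
            break
        x = x_new
    out = ndimage.map_coordinates(vol.data.astype(float), [x[..., a] for a in range(3)],
                                  order=1, mode="constant", cval=background)
    return ImageVolume(data=out, spacing=vol.spacing.copy(), origin=vol.origin.copy())


def _intensity_model(mask: LabelMask) -> np.ndarray:
    """Smooth MRI-like intensity: bright textured meniscal tissue on a
    darker, also-textured background emulating the surrounding joint
    soft tissue. Texture everywhere matters: in the knee the meniscus
    deforms together with its neighbors, and the registration needs
    intensity gradients on both sides of the tissue boundary to resolve
    the displacement there."""
    X, Y, Z = _grid_world(mask.shape, mask.spacing, mask.origin)
    texture = (
        100.0
        + 30.0 * np.sin(2 * np.pi * X / 11.0) * np.cos(2 * np.pi * Y / 13.0)
        + 20.0 * np.cos(2 * np.pi * Z / 5.0)
        + 10.0 * np.sin(2 * np.pi * (X + Y) / 17.0)
    )
    surround = (
        40.0
        + 12.0 * np.sin(2 * np.pi * X / 8.0) * np.sin(2 * np.pi * Y / 9.0)
        + 8.0 * np.cos(2 * np.pi * Z / 4.5)
    )
    tissue = np.broadcast_to(texture, mask.shape).copy()
    backgr = np.broadcast_to(surround, mask.shape).copy()
    img = np.where(mask.labels > 0, tissue, backgr)
    # small blur to soften the binary tissue edge (sub-voxel, keeps edges sharp
    # enough to drive the similarity metric)
    return ndimage.gaussian_filter(img, sigma=0.6)


def _rician(rng: np.random.Generator, img: np.ndarray, sd: float) -> np.ndarray:
    """Magnitude-MRI (Rician) noise."""
    if sd <= 0:
        return img
    return np.sqrt((img + rng.normal(0, sd, img.shape)) ** 2 + rng.normal(0, sd, img.shape) ** 2)


def synthesize_specimen(
    geom: PhantomGeometry,
    load_specs: "dict[float, DeformationSpec]",
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Generate one synthetic specimen: mask, unloaded volume, and for
    each load level the loaded volume plus its ground-truth field.

    Returns ``(mask, unloaded, {load: (volume, field)})``. Identical
    (geom, specs, noise_sd, seed) reproduce bit-identical outputs.
    """
    rng = np.random.default_rng(seed)
    mask = make_meniscus_mask(geom)
    clean = _intensity_model(mask)
    unloaded = ImageVolume(data=_rician(rng, clean, noise_sd),
                           spacing=mask.spacing.copy(), origin=mask.origin.copy())
    loaded: dict[float, tuple[ImageVolume, DisplacementField]] = {}
    for level in sorted(load_specs):
        fld = make_displacement(load_specs[level], mask)
        warped = warp_image(ImageVolume(clean, mask.spacing.copy(), mask.origin.copy()),
                            fld, background=15.0)
        vol = ImageVolume(data=_rician(rng, warped.data, noise_sd),
                          spacing=mask.spacing.copy(), origin=mask.origin.copy())
        loaded[level] = (vol, fld)
    return mask, unloaded, loaded


# ---------------------------------------------------------------------------
# cohort generator


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort of characteristic (per-region median) strains.

    ``group_means`` are specimen-level per-region means at 100% body
    weight, in signed percent, per direction, as (mild, severe) pairs;
    means scale linearly with load fraction. Defaults follow the
    reported group averages: axial compression -3.1% (mild) vs -7.3%
    (severe), circumferential +0.35/+0.45%, radial +0.37/+0.41%.
    Standard deviations are not reported for the original cohort; the
    defaults (3.0% axial, 0.5% otherwise) give the 12+12 design roughly
    the study's detection power for the axial contrast while leaving the
    small circumferential/radial differences usually undetected.
    """

    n_per_group: int = 12
    load_levels: tuple[float, ...] = (0.25, 0.50, 1.00)
    group_means: "dict[str, tuple[float, float]]" = field(
        default_factory=lambda: {
            "axial": (-3.1, -7.3),
            "circumferential": (0.35, 0.45),
            "radial": (0.37, 0.41),
        }
    )
    group_sds: "dict[str, float]" = field(
        default_factory=lambda: {"axial": 3.0, "circumferential": 0.5, "radial": 0.5}
    )
    medial_lateral_split: tuple[float, float] = (0.60, 0.40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if any(sd < 0 for sd in self.group_sds.values()):
            raise ValueError("group sds must be non-negative")
        if any(not 0 < lv <= 1 for lv in self.load_levels):
            raise ValueError("load fractions must lie in (0, 1]")


_ZONES = {"ARA": ("attachment",), "AH": ("inner", "outer"), "PI": ("inner", "outer"),
          "PH": ("inner", "outer"), "PRA": ("attachment",)}


def synthesize_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table of characteristic strains.

    One row per (specimen, side, load, region, zone, direction); values
    drawn independently from normal distributions with the configured
    group means and sds, scaled linearly by load fraction and by the
    medial/lateral load split (relative to an even 50/50 split, so the
    two-side average matches the configured mean). Axial entries come
    out negative — compression — by the sign of the configured means.
    """
    rng = np.random.default_rng(spec.seed)
    groups = ("mild", "severe")
    rows = []
    for gi, group in enumerate(groups):
        for s in range(spec.n_per_group):
            spec_id = f"{group[0].upper()}{s + 1:02d}"
            kl = int(rng.integers(1, 3)) if group == "mild" else int(rng.integers(3, 5))
            for side, split in zip(("medial", "lateral"), spec.medial_lateral_split):
                side_scale = split / 0.5
                for load in spec.load_levels:
                    for region in REGIONS:
                        for zone in _ZONES[region]:
                            for direction in DIRECTIONS:
                                mu = spec.group_means[direction][gi] * load * side_scale
                                sd = spec.group_sds[direction] * load * side_scale
                                val = rng.normal(mu, sd)
                                rows.append((spec_id, group, kl, side, load, region,
                                             zone, direction, val))
    return pd.DataFrame(
        rows,
        columns=["specimen", "group", "kl_grade", "side", "load", "region",
                 "zone", "direction", "strain_pct"],
    )


def region_level(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a zone-resolved cohort table to one characteristic value
    per (specimen, side, load, region, direction) — the mean of the
    zone values (a single value for the attachments)."""
    keys = ["specimen", "group", "kl_grade", "side", "load", "region", "direction"]
    return table.groupby(keys, as_index=False)["strain_pct"].mean()
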