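"""Per-meniscus cylindrical frame and anatomical region partition.

The local cylindrical coordinate system of each meniscus is anchored at
the center of a circle fitted to points on the outer circumferential
border (the peripheral rim, where collagen bundles run circumferentially,
giving good azimuth alignment). Strains are later projected onto the
frame's radial, circumferential (hoop) and axial unit vectors.

Region partition mirrors the interactive protocol: two user-specified
separation lines split off the root attachments (ARA, PRA); the internal
angle remaining between them is divided by three into anterior horn
(AH), pars intermedia (PI) and posterior horn (PH); body elements are
further split into inner/outer zones at two-thirds of the local radial
width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hexmesh import HexMesh

__all__ = [
    "CylindricalFrame",
    "SeparationLine",
    "fit_circle",
    "build_frame",
    "to_cylindrical",
    "frame_vectors",
    "outer_rim_points",
    "separate_attachments",
    "trisect_body",
    "split_zones",
    "label_regions",
]

TWO_PI = 2.0 * np.pi


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares (Kasa) circle fit to 2D points (mm).

    Solves the linear system for (a, b, c) in
    2 a x + 2 b y + c = x^2 + y^2, giving center (a, b) and radius
    sqrt(c + a^2 + b^2). Exact when the points lie exactly on a circle.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 two-dimensional points")
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    rhs = (pts ** 2).sum(axis=1)
    sol, residuals, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3:
        raise ValueError("points are collinear — circle is undetermined")
    a, b, c = sol
    r2 = c + a * a + b * b
    if r2 <= 0:
        raise ValueError("degenerate circle fit")
    return np.array([a, b]), float(np.sqrt(r2))


@dataclass(frozen=True)
class CylindricalFrame:
    """Cylindrical coordinates about ``center`` (axial-plane mm) with the
    grid z axis as cylinder axis; theta counterclockwise viewed from
    proximal (+z), in (-pi, pi]."""

    center: tuple[float, float]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius_fit: float = float("nan")

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(ax), 1.0):
            raise ValueError("axis must be a unit vector")
        if not np.allclose(ax, [0, 0, 1]):
            raise ValueError("only the grid z axis is supported as cylinder axis")


def build_frame(center, radius_fit: float = float("nan")) -> CylindricalFrame:
    """Frame from a fitted circle center; the axial (load) direction is
    the grid z axis."""
    c = np.asarray(center, dtype=float)
    return CylindricalFrame(center=(float(c[0]), float(c[1])), radius_fit=radius_fit)


def to_cylindrical(frame: CylindricalFrame, points: np.ndarray) -> np.ndarray:
    """(r, theta, z) of world points, shape (..., 3)."""
    p = np.asarray(points, dtype=float)
    dx = p[..., 0] - frame.center[0]
    dy = p[..., 1] - frame.center[1]
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    return np.stack([r, theta, p[..., 2]], axis=-1)


def frame_vectors(frame: CylindricalFrame, points: np.ndarray,
                  r_tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Local orthonormal (e_r, e_theta, e_z) at world points.

    Returns (e_r, e_theta, e_z, on_axis) where ``on_axis`` flags points
    with r below ``r_tol`` — there the radial/hoop directions are
    undefined and the caller must exclude the element from directional
    projection.
    """
    p = np.asarray(points, dtype=float)
    dx = p[..., 0] - frame.center[0]
    dy = p[..., 1] - frame.center[1]
    r = np.hypot(dx, dy)
    on_axis = r < r_tol
    safe_r = np.where(on_axis, 1.0, r)
    e_r = np.stack([dx / safe_r, dy / safe_r, np.zeros_like(dx)], axis=-1)
    e_t = np.stack([-dy / safe_r, dx / safe_r, np.zeros_like(dx)], axis=-1)
    e_z = np.zeros_like(e_r)
    e_z[..., 2] = 1.0
    return e_r, e_t, e_z, on_axis


def outer_rim_points(mesh: HexMesh, center_guess, angular_bin_deg: float = 5.0) -> np.ndarray:
    """Auto-extract outer-rim points: the outermost element centroid per
    angular bin about a center guess. Stand-in for the interactive
    point selection of the original protocol."""
    cent = mesh.element_centroids()
    c = np.asarray(center_guess, dtype=float)
    dx, dy = cent[:, 0] - c[0], cent[:, 1] - c[1]
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    bins = np.floor((theta + np.pi) / np.radians(angular_bin_deg)).astype(int)
    pts = []
    for b in np.unique(bins):
        sel = bins == b
        k = np.argmax(r[sel])
        pts.append(cent[sel][k, :2])
    return np.asarray(pts)


@dataclass(frozen=True)
class SeparationLine:
    """User-chosen separation line from the cylindrical origin to a point
    on the outer circumference, given by its angle (radians, (-pi, pi]),
    cutting off one root attachment."""

    angle: float
    side: str  # "anterior" or "posterior"

    def __post_init__(self) -> None:
        if self.side not in ("anterior", "posterior"):
            raise ValueError("side must be 'anterior' or 'posterior'")
        if not -np.pi < self.angle <= np.pi + 1e-12:
            raise ValueError("angle must lie in (-pi, pi]")

    @classmethod
    def from_point(cls, frame: CylindricalFrame, point_xy, side: str) -> "SeparationLine":
        p = np.asarray(point_xy, dtype=float)
        ang = float(np.arctan2(p[1] - frame.center[1], p[0] - frame.center[0]))
        return cls(angle=ang, side=side)


def _body_orientation(theta: np.ndarray, a: float, p: float) -> int:
    """+1 if the body arc runs counterclockwise from the anterior line to
    the posterior line, -1 otherwise — decided by which orientation
    contains the majority of element centroid angles."""
    ccw = np.mod(theta - a, TWO_PI) <= np.mod(p - a, TWO_PI) + 1e-12
    return 1 if ccw.mean() >= 0.5 else -1


def separate_attachments(
    mesh: HexMesh,
    frame: CylindricalFrame,
    line_a: SeparationLine,
    line_p: SeparationLine,
) -> tuple[np.ndarray, int]:
    """Split root attachments from the meniscal body by centroid angle.

    Elements beyond the anterior line (outside the body arc, on the
    anterior side) are ARA; beyond the posterior line, PRA; the arc
    between is the body, to be trisected. Returns per-element labels in
    {"ARA", "body", "PRA"} and the body orientation sign (+1 CCW).
    """
    if line_a.side == line_p.side:
        raise ValueError("separation lines must cut opposite ends of the C")
    if line_a.side == "posterior":  # orientation symmetry: swap back
        line_a, line_p = line_p, line_a
    if np.isclose(np.mod(line_a.angle - line_p.angle, TWO_PI), 0.0):
        raise ValueError("separation lines coincide")
    cyl = to_cylindrical(frame, mesh.element_centroids())
    theta = cyl[:, 1]
    orient = _body_orientation(theta, line_a.angle, line_p.angle)
    a, p = line_a.angle, line_p.angle
    # signed angular position along the body orientation, from line_a
    pos = np.mod(orient * (theta - a), TWO_PI)
    span = np.mod(orient * (p - a), TWO_PI)
    if span <= 1e-12:
        raise ValueError("empty body arc between the separation lines")
    labels = np.where(pos <= span, "body", "")
    outside = pos > span
    # outside the arc: nearer end wins (angular distance beyond each line)
    d_a = TWO_PI - pos  # distance going backwards past line_a
    d_p = pos - span    # distance going forwards past line_p
    labels = labels.astype(object)
    labels[outside & (d_a <= d_p)] = "ARA"
    labels[outside & (d_a > d_p)] = "PRA"
    return labels.astype(str), orient


def trisect_body(
    frame: CylindricalFrame,
    mesh: HexMesh,
    body_sel: np.ndarray,
    line_a: SeparationLine,
    line_p: SeparationLine,
    orient: int,
) -> np.ndarray:
    """Divide the body arc into three equal angular sectors: AH adjacent
    to the anterior attachment, PI in the middle, PH adjacent to the
    posterior attachment. Assignment by element centroid angle;
    unwrapping along ``orient`` removes the branch-cut ambiguity."""
    if line_a.side == "posterior":
        line_a, line_p = line_p, line_a
    if not body_sel.any():
        raise ValueError("no body elements to trisect")
    cyl = to_cylindrical(frame, mesh.element_centroids()[body_sel])
    pos = np.mod(orient * (cyl[:, 1] - line_a.angle), TWO_PI)
    span = np.mod(orient * (line_p.angle - line_a.angle), TWO_PI)
    third = span / 3.0
    out = np.where(pos <= third, "AH", np.where(pos <= 2 * third, "PI", "PH"))
    return out.astype(str)


def split_zones(
    frame: CylindricalFrame,
    mesh: HexMesh,
    body_sel: np.ndarray,
    inner_fraction: float = 2.0 / 3.0,
    angular_bin_deg: float = 5.0,
) -> np.ndarray:
    """Inner/outer zone split of the body at a fraction of the LOCAL
    radial width.

    Per angular bin, the min/max centroid radius of body elements in the
    bin define the local meniscal width; an element at normalized radial
    position rho = (r - r_min)/(r_max - r_min) is ``inner`` when
    rho <= inner_fraction (default two-thirds), else ``outer``. A bin
    holding a single radial layer (zero width) is entirely inner.
    """
    if not 0 < inner_fraction <= 1:
        raise ValueError("inner_fraction must lie in (0, 1]")
    if angular_bin_deg <= 0:
        raise ValueError("angular_bin must be positive")
    cyl = to_cylindrical(frame, mesh.element_centroids()[body_sel])
    r, theta = cyl[:, 0], cyl[:, 1]
    nbins = max(1, int(round(360.0 / angular_bin_deg)))
    bins = np.minimum(np.floor((theta + np.pi) / (TWO_PI / nbins)).astype(int), nbins - 1)
    zone = np.empty(len(r), dtype=object)
    for b in np.unique(bins):
        sel = bins == b
        r_min, r_max = r[sel].min(), r[sel].max()
        width = r_max - r_min
        if width <= 0:
            zone[sel] = "inner"
            continue
        rho = (r[sel] - r_min) / width
        zone[sel] = np.where(rho <= inner_fraction, "inner", "outer")
    return zone.astype(str)


def label_regions(
    mesh: HexMesh,
    frame: CylindricalFrame,
    line_a: SeparationLine,
    line_p: SeparationLine,
    inner_fraction: float = 2.0 / 3.0,
    angular_bin_deg: float = 5.0,
) -> pd.DataFrame:
    """Full region + zone labeling of a meniscus mesh.

    Returns a DataFrame with columns ``region`` in
    {ARA, AH, PI, PH, PRA} and ``zone`` in {attachment, inner, outer},
    one row per element, covering every element exactly once.
    """
    coarse, orient = separate_attachments(mesh, frame, line_a, line_p)
    region = coarse.copy()
    body_sel = coarse == "body"
    if body_sel.any():
        region[body_sel] = trisect_body(frame, mesh, body_sel, line_a, line_p, orient)
    zone = np.full(mesh.n_elements, "attachment", dtype=object)
    if body_sel.any():
        zone[body_sel] = split_zones(frame, mesh, body_sel, inner_fraction, angular_bin_deg)
    return pd.DataFrame({"region": region.astype(str), "zone": zone.astype(str)})
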