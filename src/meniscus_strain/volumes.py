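"""Core raster types and NIfTI I/O.

All stages of the pipeline operate on axis-aligned 3D grids with
anisotropic voxel spacing. The world convention is fixed once here:
voxel index (i, j, k) maps to world position ``origin + index * spacing``
(mm), with image intensities and displacement samples living at voxel
CENTERS. Mesh nodes (see :mod:`meniscus_strain.hexmesh`) live on the
corner lattice offset by ``-0.5 * spacing``.

Array axes are (x, y, z) = (sagittal, coronal, axial); the axial (load)
direction is the z axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "LabelMask",
    "DisplacementField",
    "RoiBox",
    "read_volume",
    "read_mask",
    "read_field",
    "write_volume",
    "crop_to_roi",
]


def _check_grid(spacing: np.ndarray, origin: np.ndarray) -> None:
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if spacing.shape != (3,) or origin.shape != (3,):
        raise ValueError("spacing and origin must be 3-vectors")
    if not np.all(spacing > 0):
        raise ValueError(f"voxel spacing must be positive, got {spacing}")


@dataclass
class ImageVolume:
    """3D scalar image on an axis-aligned grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities, arbitrary units.
    spacing : ndarray, shape (3,)
        mm per voxel along (x, y, z).
    origin : ndarray, shape (3,)
        World coordinate (mm) of voxel index (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        _check_grid(self.spacing, self.origin)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have at least one voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers at integer ``index``."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def same_grid(self, other: "ImageVolume | LabelMask | DisplacementField") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LabelMask:
    """Integer segmentation mask on the same grid contract as ImageVolume.

    0 is background; positive integers are anatomical labels.
    """

    labels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("label array must be integer-valued")
            self.labels = self.labels.astype(np.int32)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        _check_grid(self.spacing, self.origin)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.labels.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def data(self) -> np.ndarray:  # grid-duck-typing with ImageVolume
        return self.labels

    voxel_to_world = ImageVolume.voxel_to_world
    same_grid = ImageVolume.same_grid


@dataclass
class DisplacementField:
    """Per-voxel 3D displacement (mm) sampled at voxel centers of the
    unloaded reference grid. ``vectors`` has shape (nx, ny, nz, 3)."""

    vectors: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        _check_grid(self.spacing, self.origin)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("displacement field must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    @property
    def data(self) -> np.ndarray:
        return self.vectors

    voxel_to_world = ImageVolume.voxel_to_world
    same_grid = ImageVolume.same_grid


@dataclass(frozen=True)
class RoiBox:
    """Voxel-index crop box, half-open on the upper side."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=int)
        hi = np.asarray(self.upper, dtype=int)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("RoiBox bounds must be 3-tuples")
        if not np.all(lo < hi):
            raise ValueError(f"RoiBox requires lower < upper, got {self.lower} / {self.upper}")

    @classmethod
    def from_sequence(cls, six: "list[int] | tuple[int, ...]") -> "RoiBox":
        """Build from the six-integer config form (x0, y0, z0, x1, y1, z1)."""
        if len(six) != 6:
            raise ValueError("expected six integers")
        return cls(lower=tuple(six[:3]), upper=tuple(six[3:]))  # type: ignore[arg-type]


def _affine_from_grid(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return affine


def _grid_from_affine(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lin = affine[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(lin))):
        raise ValueError(
            "NIfTI header carries a rotation/shear; this pipeline requires "
            "axis-aligned grids and does not reinterpret oriented volumes"
        )
    spacing = np.abs(np.diag(lin))
    if not np.all(spacing > 0):
        raise ValueError(f"non-positive voxel spacing in header: {np.diag(lin)}")
    return spacing, affine[:3, 3].copy()


def write_volume(vol: ImageVolume | LabelMask | DisplacementField, path: str | Path) -> None:
    """Write a volume, mask or displacement field as NIfTI.

    Displacement fields are stored as 4D images with 3 components on the
    last axis; masks keep their integer dtype so label round-trips are
    bit-exact.
    """
    path = Path(path)
    if isinstance(vol, LabelMask):
        payload = vol.labels.astype(np.int32)
    elif isinstance(vol, DisplacementField):
        payload = vol.vectors
    else:
        payload = vol.data
    img = nib.Nifti1Image(payload, _affine_from_grid(vol.spacing, vol.origin))
    if isinstance(vol, DisplacementField):
        img.header.set_intent("vector")
    nib.save(img, str(path))


def _load(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    spacing, origin = _grid_from_affine(img.affine)
    return np.asarray(img.dataobj), spacing, origin


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D scalar NIfTI. No resampling is performed."""
    data, spacing, origin = _load(path)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D scalar volume, got ndim={data.ndim}")
    return ImageVolume(data=np.asarray(data, dtype=float), spacing=spacing, origin=origin)


def read_mask(path: str | Path) -> LabelMask:
    """Read a 3D integer label mask."""
    data, spacing, origin = _load(path)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D label volume, got ndim={data.ndim}")
    return LabelMask(labels=data, spacing=spacing, origin=origin)


def read_field(path: str | Path) -> DisplacementField:
    """Read a 3-component vector NIfTI as a displacement field."""
    data, spacing, origin = _load(path)
    data = np.squeeze(np.asarray(data, dtype=float))
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError("expected a 4D NIfTI with 3 vector components")
    return DisplacementField(vectors=data, spacing=spacing, origin=origin)


def crop_to_roi(vol, roi: RoiBox):
    """Crop to a voxel-index box, shifting the origin so world
    coordinates of retained voxels are preserved.

    The same box can be applied to all load cases of one specimen since
    all its volumes share the reference grid.
    """
    lo = np.asarray(roi.lower, dtype=int)
    hi = np.asarray(roi.upper, dtype=int)
    if np.any(lo < 0) or np.any(hi > np.asarray(vol.shape)):
        raise ValueError(f"ROI {roi} outside grid of shape {vol.shape}")
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    new_origin = vol.origin + lo * vol.spacing
    if isinstance(vol, LabelMask):
        return LabelMask(labels=vol.labels[sl].copy(), spacing=vol.spacing.copy(), origin=new_origin)
    if isinstance(vol, DisplacementField):
        return DisplacementField(vectors=vol.vectors[sl].copy(), spacing=vol.spacing.copy(), origin=new_origin)
    return ImageVolume(data=vol.data[sl].copy(), spacing=vol.spacing.copy(), origin=new_origin)
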