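"""Voxel-resolution hexahedral meshing and nodal displacement sampling.

Each foreground voxel of the segmentation becomes one 8-node brick
element whose geometry is exactly the voxel box (element size equals
the image resolution). Nodes live on the corner lattice — voxel centers
offset by -spacing/2 — so the element centroid coincides with the voxel
center, where the displacement sample natively lives.

Node ordering within an element follows the VTK hexahedron convention:
counterclockwise bottom face (z-), then the top face (z+):
(0,0,0) (1,0,0) (1,1,0) (0,1,0) (0,0,1) (1,0,1) (1,1,1) (0,1,1)
in local corner offsets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import DisplacementField, LabelMask

__all__ = ["HexMesh", "mask_to_hexmesh", "sample_nodal_displacements",
           "write_vtk", "write_csv"]

# VTK hexahedron local corner offsets (i, j, k)
_CORNERS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=np.int64)


@dataclass
class HexMesh:
    """Conforming voxel hexahedral mesh.

    nodes : (n_nodes, 3) world coordinates, mm
    elements : (n_elem, 8) node indices, VTK hexahedron ordering
    element_to_voxel : (n_elem, 3) voxel index of each element
    labels : (n_elem,) anatomical label carried from the mask
    spacing, origin : grid of the source mask
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_to_voxel: np.ndarray
    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_centroids(self) -> np.ndarray:
        """World coordinates of element centroids = source voxel centers."""
        return self.origin + self.element_to_voxel * self.spacing

    def element_volume(self) -> float:
        """Volume of one element (all elements are congruent boxes)."""
        return float(np.prod(self.spacing))


def mask_to_hexmesh(mask: LabelMask, target_labels=None) -> HexMesh:
    """One hexahedral element per voxel carrying a target label.

    Corner nodes are deduplicated exactly across neighboring voxels via
    the integer corner lattice, so the mesh is conforming by
    construction.
    """
    if target_labels is None:
        sel = mask.labels > 0
    else:
        sel = np.isin(mask.labels, list(target_labels))
    vox = np.argwhere(sel)
    if len(vox) == 0:
        raise ValueError("no voxels carry the requested labels")

    # integer corner lattice of shape (nx+1, ny+1, nz+1)
    lattice_shape = np.asarray(mask.shape) + 1
    corners = vox[:, None, :] + _CORNERS[None, :, :]  # (n_elem, 8, 3)
    flat = np.ravel_multi_index(
        (corners[..., 0], corners[..., 1], corners[..., 2]), lattice_shape)
    unique_flat, inverse = np.unique(flat, return_inverse=True)
    elements = inverse.reshape(len(vox), 8)

    node_idx = np.stack(np.unravel_index(unique_flat, lattice_shape), axis=-1)
    nodes = mask.origin - 0.5 * mask.spacing + node_idx * mask.spacing
    labels = mask.labels[vox[:, 0], vox[:, 1], vox[:, 2]]
    return HexMesh(nodes=nodes, elements=elements, element_to_voxel=vox,
                   labels=labels, spacing=mask.spacing.copy(), origin=mask.origin.copy())


def sample_nodal_displacements(fld: DisplacementField, mesh: HexMesh) -> np.ndarray:
    """Trilinear interpolation of the voxel-center displacement field at
    mesh node positions; clamped-edge beyond the center lattice so no
    artificial strain is fabricated at the mesh surface.

    Returns (n_nodes, 3) displacements in mm.
    """
    if not np.allclose(fld.spacing, mesh.spacing) or not np.allclose(fld.origin, mesh.origin):
        raise ValueError("field grid does not match the mesh's source grid")
    coords = (mesh.nodes - fld.origin) / fld.spacing  # center-lattice units
    out = np.stack(
        [ndimage.map_coordinates(fld.vectors[..., a], coords.T, order=1, mode="nearest")
         for a in range(3)], axis=-1)
    return out


def write_vtk(mesh: HexMesh, path, point_vectors: np.ndarray | None = None,
              cell_scalars: "dict[str, np.ndarray] | None" = None) -> None:
    """Export as VTK legacy ASCII unstructured grid (hexahedron cells),
    optionally with a nodal vector array (e.g. displacements) and
    per-element scalar arrays (e.g. strains, region labels)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmeniscus hex mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}\n")
        for el in mesh.elements:
            fh.write("8 " + " ".join(map(str, el)) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("\n".join(["12"] * mesh.n_elements) + "\n")
        if point_vectors is not None:
            fh.write(f"POINT_DATA {mesh.n_nodes}\nVECTORS displacement float\n")
            for v in point_vectors:
                fh.write(f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
        if cell_scalars:
            fh.write(f"CELL_DATA {mesh.n_elements}\n")
            for name, arr in cell_scalars.items():
                kind = "int" if np.issubdtype(np.asarray(arr).dtype, np.integer) else "float"
                fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.6g}" if kind == "float" else str(int(v)) for v in arr) + "\n")


def write_csv(mesh: HexMesh, node_path, element_path) -> None:
    """Plain node/element CSV pair."""
    with Path(node_path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node", "x_mm", "y_mm", "z_mm"])
        for i, p in enumerate(mesh.nodes):
            w.writerow([i, f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}"])
    with Path(element_path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["element", "label"] + [f"n{k}" for k in range(8)]
                   + ["voxel_i", "voxel_j", "voxel_k"])
        for e in range(mesh.n_elements):
            w.writerow([e, int(mesh.labels[e])] + list(map(int, mesh.elements[e]))
                       + list(map(int, mesh.element_to_voxel[e])))
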