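"""Morphological features of the ROI: volume, surface area, sphericity.

The mask is triangulated with marching cubes at iso-level 0.5, after zero
padding (so surfaces close at image borders) and a light Gaussian
anti-aliasing of the binary indicator (sigma 0.8 voxels).  The anti-aliasing
step matters: on a raw binary mask the marching-cubes surface is a staircase
whose area over-estimates a smooth boundary by a non-vanishing ~8%, so the
sphericity of a digital ball would plateau near 0.92 instead of converging
to 1 under refinement.  Meshing the smoothed indicator restores convergence
(ball sphericity ~0.99 at radius 20 voxels) at the cost of slightly rounding
genuinely sharp corners.  The smoothing is deterministic and fixed; vertices
are scaled to physical millimetres.

Surface area is the summed triangle area; volume comes from the divergence
theorem as a sum of signed tetrahedra.  Sphericity

    psi = pi^(1/3) * (6 V)^(2/3) / A

compares the ROI's surface area with that of the equal-volume sphere: 1 for a
perfect sphere, smaller the more irregular the shape.  The mesh-based volume
is the canonical V used in sphericity; the plain voxel-count volume is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume import VolumeWithMask

__all__ = [
    "TriangleMesh",
    "ShapeFeatures",
    "mask_to_mesh",
    "mesh_volume",
    "mesh_area",
    "voxel_volume",
    "sphericity",
    "shape_features",
]


class GeometryError(ValueError):
    """Mesh fails a geometric precondition (e.g. not closed)."""


@dataclass
class TriangleMesh:
    """A triangulated surface in physical (mm) coordinates."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray     # (m, 3) int vertex indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise GeometryError("face references out-of-range vertex")

    def is_closed(self) -> bool:
        """Every undirected edge is shared by exactly two faces."""
        f = self.faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


@dataclass
class ShapeFeatures:
    volume_voxel: float  # mm^3
    volume_mesh: float   # mm^3
    area: float          # mm^2
    sphericity: float    # dimensionless


#: Anti-aliasing width (voxels) applied to the indicator before meshing.
MESH_SMOOTHING_SIGMA = 0.8


def mask_to_mesh(mask: np.ndarray, spacing: tuple[float, float, float]) -> TriangleMesh:
    """Triangulate the 0.5 isosurface of a binary mask, in mm coordinates.

    The indicator is padded and anti-aliased (fixed Gaussian, sigma
    :data:`MESH_SMOOTHING_SIGMA` voxels) so the triangulated area converges
    to the smooth-boundary area under grid refinement.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot mesh an empty mask")
    padded = np.pad(mask.astype(np.float64), 4)
    smoothed = ndimage.gaussian_filter(padded, sigma=MESH_SMOOTHING_SIGMA)
    if smoothed.max() <= 0.5:
        # ROI too thin to survive anti-aliasing; mesh the raw indicator
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=tuple(spacing))
    return TriangleMesh(vertices=verts, faces=faces)


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume by the divergence theorem (sum of signed tetrahedra)."""
    if not mesh.is_closed():
        raise GeometryError("mesh is not closed; volume undefined")
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    return float(abs(signed))


def mesh_area(mesh: TriangleMesh) -> float:
    """Total triangle area in mm^2."""
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return float(np.linalg.norm(np.cross(b - a, c - a), axis=1).sum() / 2.0)


def voxel_volume(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Foreground voxel count times the physical voxel volume."""
    return float(np.asarray(mask).astype(bool).sum() * np.prod(spacing))


def sphericity(volume: float, area: float) -> float:
    """pi^(1/3) (6V)^(2/3) / A for mesh-based volume V and area A."""
    if volume <= 0 or area <= 0:
        raise ValueError("sphericity requires positive volume and area")
    return float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)


def shape_features(vol: VolumeWithMask) -> ShapeFeatures:
    """All three shape features (plus the voxel-count volume) for one ROI."""
    mesh = mask_to_mesh(vol.mask, vol.spacing)
    v_mesh = mesh_volume(mesh)
    a = mesh_area(mesh)
    return ShapeFeatures(
        volume_voxel=voxel_volume(vol.mask, vol.spacing),
        volume_mesh=v_mesh,
        area=a,
        sphericity=sphericity(v_mesh, a),
    )
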