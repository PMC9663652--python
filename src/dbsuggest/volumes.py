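"""Voxel volumes: sweet spots, atlas structures, and VTA masks.

Thin layer over nibabel NIfTI images.  A :class:`VoxelVolume` couples a 3-D
mask (or weight map) with its voxel-to-world affine; every derived quantity
(center of mass, volume, Dice) is computed in world millimetres.  Voxel
membership for rasterized spheres is decided by the voxel *center* falling
inside the sphere, which makes all overlap and Dice numbers bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .spheres import Sphere

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D scalar grid with a voxel->mm affine."""

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "grid", np.asarray(self.grid))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3-D, got shape {self.grid.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")
        if abs(np.linalg.det(self.affine[:3, :3])) <= 0:
            raise ValueError("affine is singular")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def mask(self) -> np.ndarray:
        return self.grid > 0

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def total_volume(self) -> float:
        return self.n_voxels * self.voxel_volume

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to world mm."""
        idx = np.asarray(indices, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (n_total, 3)."""
        ii = np.indices(self.grid.shape).reshape(3, -1).T
        return self.world_coords(ii)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.grid.astype(np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


def _require_same_grid(a: VoxelVolume, b: VoxelVolume) -> None:
    if a.grid.shape != b.grid.shape or not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ValueError("volumes are defined on different grids")


def load_volume(path, threshold: float | None = None) -> VoxelVolume:
    """Load a NIfTI image as a binary mask.

    Voxels with value >= ``threshold`` are kept; with the default
    ``threshold=None`` strictly positive voxels are kept, which is the right
    behaviour for probabilistic/statistical maps already thresholded
    upstream.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    if threshold is None:
        mask = data > 0
    else:
        if not np.isfinite(threshold):
            raise ValueError("threshold must be finite")
        mask = data >= threshold
    return VoxelVolume(grid=mask.astype(np.uint8), affine=np.asarray(img.affine))


def centroid(volume: VoxelVolume, weighted: bool = False) -> np.ndarray:
    """Center of mass of the mask in world mm.

    ``weighted=True`` weights voxels by their grid values instead of
    treating the mask as binary.
    """
    idx = np.argwhere(volume.mask)
    if idx.shape[0] == 0:
        raise ValueError("cannot compute the centroid of an empty mask")
    pts = volume.world_coords(idx)
    if weighted:
        w = volume.grid[volume.mask].astype(float)
        return np.average(pts, axis=0, weights=w)
    return pts.mean(axis=0)


@dataclass(frozen=True)
class SweetSpot:
    """A sweet-spot mask with its equal-volume spherical approximation."""

    volume_image: VoxelVolume
    center_mm: np.ndarray
    total_volume: float  # mm^3
    sphere: Sphere

    def __post_init__(self):
        if not np.allclose(self.sphere.center, self.center_mm):
            raise ValueError("sphere must be centered on the mask center of mass")
        vol = 4.0 / 3.0 * np.pi * self.sphere.radius**3
        if not np.isclose(vol, self.total_volume, rtol=1e-6):
            raise ValueError("sphere is not the equal-volume approximation")


def summarize_sweetspot(volume: VoxelVolume, weighted: bool = False) -> SweetSpot:
    """Characterize a sweet-spot mask.

    The spherical approximation keeps the mask's center of mass and its
    total volume; the radius is the equal-volume radius
    ``(3 V / 4 pi)^(1/3)``.
    """
    center = centroid(volume, weighted=weighted)
    total = volume.total_volume
    radius = (3.0 * total / (4.0 * np.pi)) ** (1.0 / 3.0)
    return SweetSpot(
        volume_image=volume,
        center_mm=center,
        total_volume=total,
        sphere=Sphere(center=center, radius=radius),
    )


def dice(v1: VoxelVolume, v2: VoxelVolume) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|) of two masks."""
    _require_same_grid(v1, v2)
    a, b = v1.mask, v2.mask
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int(np.count_nonzero(a & b)) / denom


def voxel_overlap_volume(v1: VoxelVolume, v2: VoxelVolume) -> float:
    """Overlap volume (mm^3) of two masks on the same grid."""
    _require_same_grid(v1, v2)
    return int(np.count_nonzero(v1.mask & v2.mask)) * v1.voxel_volume


def rasterize_sphere(sphere: Sphere, reference: VoxelVolume) -> VoxelVolume:
    """Binary mask of reference-grid voxels whose centers lie in the sphere.

    A sphere with radius smaller than roughly half a voxel may rasterize to
    an empty mask if its center falls between grid points.
    """
    if sphere.radius < 0:
        raise ValueError("radius must be non-negative")
    pts = reference.voxel_centers()
    d2 = np.sum((pts - sphere.center) ** 2, axis=1)
    mask = (d2 <= sphere.radius**2).reshape(reference.grid.shape)
    return VoxelVolume(grid=mask.astype(np.uint8), affine=reference.affine)


def mirror_x(volume: VoxelVolume) -> VoxelVolume:
    """Flip a volume across the mid-sagittal plane (world x -> -x).

    A simplified stand-in for nonlinear left/right warping; requires the
    image x-axis to be decoupled from y/z in the affine (resample first
    otherwise).
    """
    A = volume.affine
    coupled = max(abs(A[0, 1]), abs(A[0, 2]), abs(A[1, 0]), abs(A[2, 0]))
    if coupled > 1e-6:
        raise ValueError(
            "affine mixes x with y/z; resample to an axis-aligned grid before mirroring"
        )
    flip = np.diag([-1.0, 1.0, 1.0, 1.0])
    return VoxelVolume(grid=volume.grid, affine=flip @ A)


def make_reference_grid(
    center, half_extent: float, resolution: float = 0.5
) -> VoxelVolume:
    """An empty axis-aligned grid of ``resolution`` mm voxels around a point."""
    if resolution <= 0 or half_extent <= 0:
        raise ValueError("resolution and half_extent must be positive")
    center = np.asarray(center, dtype=float)
    n = int(np.ceil(2 * half_extent / resolution)) + 1
    affine = np.eye(4)
    affine[:3, :3] *= resolution
    affine[:3, 3] = center - resolution * (n - 1) / 2.0
    return VoxelVolume(grid=np.zeros((n, n, n), dtype=np.uint8), affine=affine)
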