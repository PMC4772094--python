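"""3D morphometry of cell compartments: surface area, volume, sphericity.

Given a binary voxel segmentation of a compartment (soma or neurite),
this module reports

* volume ``V`` — foreground voxel count times voxel volume,
* surface area ``A`` — from a level-0.5 isosurface mesh of the mask,
* sphericity ``Psi = pi^(1/3) * (6 V)^(2/3) / A`` (1 for a sphere), and
* specific surface area ``A / V`` — a proxy for how readily the
  compartment exchanges heat with its surroundings.

Surface area deliberately comes from an isosurface mesh and not from
voxel-face counting: face counting overestimates a sphere's area by
roughly 50% and would corrupt sphericity.  The binary mask is lightly
Gaussian-smoothed (sigma = 1 voxel by default) before marching cubes to
suppress the staircase artifact; with it, a sphere voxelized at r/voxel
= 50 recovers its analytic area to within ~0.3%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .errors import SegmentationError

__all__ = [
    "VoxelVolume",
    "ShapeMetrics",
    "ShapeComparison",
    "segment_stack",
    "measure_shape",
    "compare_compartments_shape",
    "export_mesh_obj",
]


@dataclass(frozen=True)
class VoxelVolume:
    """A binary 3D segmentation with physical voxel sizes (z, y, x order)."""

    mask: np.ndarray
    voxel_size_um: tuple[float, float, float]
    label: str = "object"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask).astype(bool)
        if m.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not m.any():
            raise ValueError("mask has no foreground voxel")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size_um must be three positive values")
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "voxel_size_um", vs)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))


@dataclass(frozen=True)
class ShapeMetrics:
    surface_area_um2: float
    volume_um3: float
    sphericity: float
    specific_surface_area_per_um: float
    label: str = "object"
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.surface_area_um2 <= 0 or self.volume_um3 <= 0:
            raise ValueError("surface area and volume must be positive")

    @classmethod
    def from_area_volume(
        cls, surface_area_um2: float, volume_um3: float, label: str = "object"
    ) -> "ShapeMetrics":
        """Build metrics from exact (analytic) area and volume."""
        return cls(
            surface_area_um2=float(surface_area_um2),
            volume_um3=float(volume_um3),
            sphericity=sphericity(surface_area_um2, volume_um3),
            specific_surface_area_per_um=float(surface_area_um2 / volume_um3),
            label=label,
        )


@dataclass(frozen=True)
class ShapeComparison:
    """Ratios of shape metrics between two compartments (a over b)."""

    sphericity_ratio: float
    specific_surface_area_ratio: float
    surface_area_ratio: float
    volume_ratio: float
    label_a: str
    label_b: str


def sphericity(surface_area: float, volume: float) -> float:
    """Psi = pi^(1/3) * (6 V)^(2/3) / A; exactly 1 for a sphere."""
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area)


def segment_stack(
    zstack: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    threshold_policy: str | float = "otsu",
    min_object_voxels: int = 8,
    label: str = "object",
) -> VoxelVolume:
    """Threshold a z-stack and keep the largest connected component.

    ``threshold_policy`` is either ``"otsu"`` or a fixed intensity.
    Components use 26-connectivity; objects smaller than
    ``min_object_voxels`` are removed first.
    """
    stack = np.asarray(zstack, dtype=float)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("zstack must be a non-empty 3-D array")
    if threshold_policy == "otsu":
        if np.ptp(stack) == 0:
            raise SegmentationError("constant stack: no threshold separates it")
        thr = float(filters.threshold_otsu(stack))
    else:
        thr = float(threshold_policy)
    fg = stack > thr
    if not fg.any():
        raise SegmentationError("empty foreground after thresholding")
    fg = morphology.remove_small_objects(fg, max_size=min_object_voxels - 1)
    if not fg.any():
        raise SegmentationError("all objects smaller than min_object_voxels")
    labels, n = measure.label(fg, connectivity=3, return_num=True)
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        fg = labels == (int(np.argmax(counts)) + 1)
    return VoxelVolume(mask=fg, voxel_size_um=voxel_size_um, label=label)


def _isosurface(
    mask: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    smooth_sigma_voxels: float,
) -> tuple[np.ndarray, np.ndarray]:
    f = np.pad(mask.astype(float), 2)
    if smooth_sigma_voxels > 0:
        f = ndimage.gaussian_filter(f, smooth_sigma_voxels)
        if f.max() <= 0.5:  # tiny object smoothed below the level set
            f = np.pad(mask.astype(float), 2)
    verts, faces, _, _ = measure.marching_cubes(f, level=0.5, spacing=voxel_size_um)
    return verts, faces


def measure_shape(
    volume: VoxelVolume, smooth_sigma_voxels: float = 1.0
) -> ShapeMetrics:
    """Surface area, volume, sphericity and specific surface area.

    Volume is the exact voxel count times voxel volume.  Surface area
    comes from marching cubes at level 0.5 on the (lightly smoothed)
    mask; anisotropic voxels are handled through the mesh spacing.
    Single-voxel objects are flagged low-confidence.
    """
    n_fg = int(volume.mask.sum())
    V = n_fg * volume.voxel_volume_um3
    verts, faces = _isosurface(volume.mask, volume.voxel_size_um, smooth_sigma_voxels)
    A = float(measure.mesh_surface_area(verts, faces))
    return ShapeMetrics(
        surface_area_um2=A,
        volume_um3=V,
        sphericity=sphericity(A, V),
        specific_surface_area_per_um=A / V,
        label=volume.label,
        low_confidence=n_fg <= 1,
    )


def compare_compartments_shape(
    metrics_a: ShapeMetrics, metrics_b: ShapeMetrics
) -> ShapeComparison:
    """Ratios (a over b) of sphericity, specific surface area, area, volume."""
    return ShapeComparison(
        sphericity_ratio=metrics_a.sphericity / metrics_b.sphericity,
        specific_surface_area_ratio=(
            metrics_a.specific_surface_area_per_um
            / metrics_b.specific_surface_area_per_um
        ),
        surface_area_ratio=metrics_a.surface_area_um2 / metrics_b.surface_area_um2,
        volume_ratio=metrics_a.volume_um3 / metrics_b.volume_um3,
        label_a=metrics_a.label,
        label_b=metrics_b.label,
    )


def export_mesh_obj(
    volume: VoxelVolume, path, smooth_sigma_voxels: float = 1.0
) -> None:
    """Write the level-0.5 isosurface as a Wavefront OBJ file."""
    verts, faces = _isosurface(volume.mask, volume.voxel_size_um, smooth_sigma_voxels)
    with open(path, "w") as fh:
        fh.write(f"# qdtherm isosurface of {volume.label}\n")
        for v in verts:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
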