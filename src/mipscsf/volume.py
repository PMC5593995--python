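"""Voxel-grid containers shared by the phantom generator and the segmenter."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MRVolume", "LabelMap", "voxel_volume_mm3"]


def voxel_volume_mm3(spacing) -> float:
    """Volume of one voxel in mm^3 from per-axis spacing in mm."""
    s = np.asarray(spacing, dtype=float)
    if s.shape != (3,) or np.any(s <= 0):
        raise ValueError("spacing must be three strictly positive values (mm)")
    return float(np.prod(s))


@dataclass
class MRVolume:
    """A 3D scalar MR volume with grid spacing in mm.

    The affine follows the NIfTI convention with the spacing on the
    diagonal and the origin at the first voxel; orientation metadata
    beyond that is not needed for volumetry and is not modelled.
    """

    intensity: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray | None = None  # optional brain mask carried by preprocessing

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3D array")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        voxel_volume_mm3(self.spacing)  # validates
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensity.shape:
                raise ValueError("mask shape must match intensity shape")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return voxel_volume_mm3(self.spacing)


@dataclass
class LabelMap:
    """Hard per-voxel labels on the same grid as an :class:`MRVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        voxel_volume_mm3(self.spacing)

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def voxel_volume_mm3(self) -> float:
        return voxel_volume_mm3(self.spacing)
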