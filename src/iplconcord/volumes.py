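"""Core image containers: scalar volumes and prostate anatomy label maps.

All volumes in one case share a single analysis grid. Conventions, used
everywhere in the package:

* voxel indices are 0-based ``(i, j, k)`` with axes (x = left-right,
  y = anterior-posterior, z = cranio-caudal); ``k`` indexes axial slices;
* world coordinates are millimetres, ``x_mm = index * spacing`` (grid origin
  at voxel (0,0,0));
* PET volumes carry standardized-uptake values (SUV) and are non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Modality",
    "Region",
    "Zone",
    "ImageVolume",
    "ProstateAnatomy",
]


class Modality(str, Enum):
    """Imaging channel of a volume."""

    PET_GA68 = "PET_GA68"  # 68Ga-PSMA-11 PET, SUV units
    PET_F18 = "PET_F18"    # 18F-PSMA-1007 PET, SUV units
    T2W = "T2W"            # T2-weighted MRI (lesions hypointense)
    ADC = "ADC"            # apparent diffusion coefficient map (lesions dark)
    DCE = "DCE"            # dynamic contrast-enhanced MRI (lesions bright)

    @property
    def is_pet(self) -> bool:
        return self in (Modality.PET_GA68, Modality.PET_F18)


class Region(int, Enum):
    """Cranio-caudal prostate region (axial level of the sector schematic)."""

    APEX = 1
    MID = 2
    BASE = 3


class Zone(int, Enum):
    """Prostate zonal anatomy used by the sector schematic."""

    PERIPHERAL = 1
    TRANSITION = 2


#: Nominal axial acquisition slice thickness in mm per modality.  PET-attached
#: volumes are acquired at 5 mm, MRI sequences at 3 mm; volumes are stored
#: resampled on the shared analysis grid and this value is metadata only.
SLICE_THICKNESS_MM = {
    Modality.PET_GA68: 5.0,
    Modality.PET_F18: 5.0,
    Modality.T2W: 3.0,
    Modality.ADC: 3.0,
    Modality.DCE: 3.0,
}


@dataclass
class ImageVolume:
    """A 3D scalar image with anisotropic voxel spacing.

    Parameters
    ----------
    data:
        3D float array, shape ``(nx, ny, nz)``.
    spacing:
        Voxel spacing ``(dx, dy, dz)`` in mm, all positive.
    modality:
        Imaging channel; PET volumes must be non-negative (SUV).
    slice_thickness_mm:
        Nominal acquisition slice thickness; defaults per modality.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality
    slice_thickness_mm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        self.modality = Modality(self.modality)
        if self.modality.is_pet and np.any(self.data < 0):
            raise ValueError("PET volumes must be non-negative (SUV units)")
        if self.slice_thickness_mm is None:
            self.slice_thickness_mm = SLICE_THICKNESS_MM[self.modality]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0


@dataclass
class ProstateAnatomy:
    """Prostate mask plus region (apex/mid/base) and zone labels.

    ``region_labels`` and ``zone_labels`` are integer volumes that are nonzero
    exactly on ``prostate_mask``; regions partition the mask into three slabs
    along the cranio-caudal (z) axis.
    """

    prostate_mask: np.ndarray
    region_labels: np.ndarray
    zone_labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.prostate_mask = np.asarray(self.prostate_mask, dtype=bool)
        self.region_labels = np.asarray(self.region_labels, dtype=np.int8)
        self.zone_labels = np.asarray(self.zone_labels, dtype=np.int8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if not (self.prostate_mask.shape == self.region_labels.shape == self.zone_labels.shape):
            raise ValueError("mask, region and zone volumes must share one shape")
        if not self.prostate_mask.any():
            raise ValueError("empty prostate mask")
        outside = ~self.prostate_mask
        if self.region_labels[outside].any() or self.zone_labels[outside].any():
            raise ValueError("region/zone labels must be zero outside the prostate mask")
        if (self.region_labels[self.prostate_mask] == 0).any():
            raise ValueError("every prostate voxel needs a region label")
        if (self.zone_labels[self.prostate_mask] == 0).any():
            raise ValueError("every prostate voxel needs a zone label")

    @property
    def voxel_volume_cc(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @property
    def prostate_volume_cc(self) -> float:
        """Prostate volume in cm^3 (voxel count x voxel volume)."""
        return float(self.prostate_mask.sum()) * self.voxel_volume_cc

    def region_mask(self, region: Region) -> np.ndarray:
        return self.region_labels == int(region)

    def zone_mask(self, zone: Zone) -> np.ndarray:
        return self.zone_labels == int(zone)

    def region_slab_slices(self, region: Region) -> np.ndarray:
        """Indices of axial slices where this region has prostate voxels."""
        has = self.region_mask(region).any(axis=(0, 1))
        return np.flatnonzero(has)
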