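"""Automatic lesion contours from PET volumes.

Contours are connected components of the set of prostate voxels whose SUV
meets a threshold — either an absolute SUV (e.g. 3.0) or a fraction of the
prostate SUVmax (the fractional range 40-80% is the clinically used family).
Dominant-lesion selection (volume >= 1 cc and SUVmax >= 3) and isotropic
physical-margin expansion complete the contouring stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, Modality, ProstateAnatomy

__all__ = [
    "Contour",
    "auto_contour",
    "select_dominant",
    "expand_margin",
    "FRACTIONAL_THRESHOLDS",
]

#: The standard fractional-SUVmax threshold family.
FRACTIONAL_THRESHOLDS = (0.4, 0.5, 0.6, 0.7, 0.8)

#: 26-connectivity structuring element for 3D component labelling.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Contour:
    """A binary lesion contour with its provenance.

    ``method`` is one of ``manual_sim`` (simulated human reader), ``SUV_abs``
    (absolute SUV threshold) or ``SUV_frac`` (fraction of prostate SUVmax);
    ``threshold`` is the SUV for ``SUV_abs``, the fraction for ``SUV_frac``
    and ``None`` for manual contours.
    """

    mask: np.ndarray
    modality: Modality
    method: str
    threshold: float | None
    volume_cc: float
    suvmax: float
    lesion_id: int | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def auto_contour(pet: ImageVolume, anatomy: ProstateAnatomy,
                 threshold: float, fractional: bool = True,
                 per_lesion_suvmax: bool = False,
                 connectivity: np.ndarray = _STRUCT_26) -> list[Contour]:
    """Threshold-based automatic contours inside the prostate.

    Parameters
    ----------
    threshold:
        Fraction of SUVmax in ``[0, 1]`` when ``fractional``, else an
        absolute SUV.
    per_lesion_suvmax:
        With ``fractional``, re-threshold each connected uptake focus at the
        given fraction of its own peak instead of the single prostate-wide
        SUVmax.  The prostate-wide definition is the default.

    Returns one :class:`Contour` per connected component (possibly empty).
    An absolute threshold above the prostate SUVmax yields an empty list.
    """
    if not pet.modality.is_pet:
        raise ValueError("auto_contour needs a PET volume in SUV units")
    if pet.data.shape != anatomy.prostate_mask.shape:
        raise ValueError("PET volume and anatomy are on different grids")
    inside = anatomy.prostate_mask
    suvmax = float(pet.data[inside].max())

    if fractional:
        if not 0.0 < threshold <= 1.0:
            raise ValueError("fractional threshold must be in (0, 1]")
        if per_lesion_suvmax:
            return _per_focus_contours(pet, anatomy, threshold, connectivity)
        cut = threshold * suvmax
    else:
        cut = float(threshold)

    binary = (pet.data >= cut) & inside
    return _components_to_contours(binary, pet, threshold, fractional, connectivity)


def _components_to_contours(binary, pet: ImageVolume, threshold, fractional,
                            connectivity) -> list[Contour]:
    labels, n = ndimage.label(binary, structure=connectivity)
    out: list[Contour] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        out.append(Contour(
            mask=comp, modality=pet.modality,
            method="SUV_frac" if fractional else "SUV_abs",
            threshold=float(threshold),
            volume_cc=float(comp.sum()) * pet.voxel_volume_cc,
            suvmax=float(pet.data[comp].max()),
            lesion_id=lab - 1))
    return out


def _per_focus_contours(pet, anatomy, fraction, connectivity) -> list[Contour]:
    """Per-lesion SUVmax variant: seed foci at a loose cut, re-threshold each."""
    inside = anatomy.prostate_mask
    suvmax = float(pet.data[inside].max())
    seeds, n = ndimage.label((pet.data >= 0.4 * suvmax) & inside, structure=connectivity)
    out: list[Contour] = []
    for lab in range(1, n + 1):
        focus = seeds == lab
        peak = float(pet.data[focus].max())
        comp_bin = (pet.data >= fraction * peak) & focus
        out.extend(_components_to_contours(comp_bin, pet, fraction, True, connectivity))
    for i, c in enumerate(out):
        c.lesion_id = i
    return out


def select_dominant(contours: list[Contour], min_volume_cc: float = 1.0,
                    min_suv: float = 3.0) -> list[Contour]:
    """Keep dominant lesions: volume >= 1 cc and observed SUVmax >= 3.

    Both bounds are inclusive; input order is preserved.  Smaller or fainter
    foci are poorly characterised by PET and are excluded from scoring.
    """
    return [c for c in contours
            if c.volume_cc >= min_volume_cc and c.suvmax >= min_suv]


def expand_margin(mask: np.ndarray, margin_mm: float,
                  spacing: tuple[float, float, float]) -> np.ndarray:
    """Dilate a binary mask by a physical ball of radius ``margin_mm``.

    Uses the Euclidean distance transform with anisotropic voxel sampling, so
    a 5 mm margin extends 5 mm in every axis regardless of voxel shape.  A
    voxel is included when its centre lies within ``margin_mm`` of the mask.
    ``margin_mm = 0`` is the identity.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm + 1e-9
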