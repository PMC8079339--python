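"""NIfTI / CSV / JSON serialisation of cases, masks and reports."""

from __future__ import annotations

import json
import pathlib

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PhantomCase
from .volumes import ImageVolume, Modality

__all__ = ["save_volume_nifti", "load_volume_nifti", "save_mask_nifti",
           "write_case", "write_lesion_manifest"]


def _affine(spacing) -> np.ndarray:
    return np.diag([*spacing, 1.0])


def save_volume_nifti(volume: ImageVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing))
    img.header["descrip"] = volume.modality.value.encode()[:80]
    nib.save(img, str(path))


def load_volume_nifti(path, modality: Modality | str) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asarray(img.dataobj, dtype=float), spacing,
                       Modality(modality))


def save_mask_nifti(mask: np.ndarray, spacing, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                             _affine(spacing)), str(path))


def write_case(case: PhantomCase, out_dir) -> None:
    """Write one case: volumes, label maps, lesion manifest and covariates."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for mod, vol in case.volumes.items():
        save_volume_nifti(vol, out / f"case{case.case_id:03d}_{mod.value}.nii.gz")
    a = case.anatomy
    save_mask_nifti(a.prostate_mask, a.spacing,
                    out / f"case{case.case_id:03d}_prostate.nii.gz")
    save_mask_nifti(a.region_labels, a.spacing,
                    out / f"case{case.case_id:03d}_regions.nii.gz")
    save_mask_nifti(a.zone_labels, a.spacing,
                    out / f"case{case.case_id:03d}_zones.nii.gz")
    write_lesion_manifest(case, out / f"case{case.case_id:03d}_lesions.csv")
    with open(out / f"case{case.case_id:03d}_covariates.json", "w") as fh:
        json.dump(case.covariates, fh, indent=2, sort_keys=True)


def write_lesion_manifest(case: PhantomCase, path) -> None:
    rows = [{
        "case_id": case.case_id, "lesion_id": les.id,
        "volume_cc": case.lesion_volume_cc(les),
        "relative_volume_fraction": les.relative_volume_fraction,
        "gleason": les.gleason_score, "assigned_suvmax": les.assigned_suvmax,
        "region": les.region.name.lower(), "zone": les.zone.name.lower(),
        "center_x_mm": les.center_mm[0], "center_y_mm": les.center_mm[1],
        "center_z_mm": les.center_mm[2],
    } for les in case.lesions]
    pd.DataFrame(rows).to_csv(path, index=False)
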