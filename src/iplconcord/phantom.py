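"""Synthetic prostate imaging phantoms with known ground-truth lesions.

A generated *case* consists of co-registered PET (SUV) and MRI-like volumes
on one analysis grid, a prostate anatomy labelling (apex/mid/base regions,
peripheral/transition zones) and a list of ground-truth lesions.  The default
cohort parameters reproduce the descriptive statistics of a clinical
radiotherapy cohort: prostate volumes with median ~31 cc (range 21-54 cc),
lesion SUVmax with median ~8 (range ~1.9-21.4), lesion volume fractions of
roughly 6-75% of the prostate, and PSA with median ~15 ng/mL.

The PET forward model is deliberately minimal: piecewise-constant (or
Gaussian-profile) uptake, convolution with an isotropic Gaussian point-spread
function, and additive Gaussian noise truncated at zero.  This captures the
partial-volume effect that drives fractional-SUVmax contouring without
simulating reconstruction physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .contouring import Contour
from .volumes import ImageVolume, Modality, ProstateAnatomy, Region, Zone

__all__ = [
    "CohortSpec",
    "GroundTruthLesion",
    "PhantomCase",
    "InfeasibleSpecError",
    "generate_case",
    "generate_cohort",
    "simulate_manual_contour",
]

GLEASON_LEVELS = ("6", "7a", "7b", "8", "9")


class InfeasibleSpecError(RuntimeError):
    """A lesion could not be placed inside the prostate after bounded retries."""


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; ``seed`` fixes it byte-for-byte.

    Distribution parameters are (median, log-space sigma, low clip, high clip)
    for log-normal draws, matching the skewed, range-reported clinical
    descriptors they emulate.
    """

    n_patients: int = 35
    shape: tuple[int, int, int] = (48, 48, 26)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    pet_modality: Modality = Modality.PET_GA68

    # prostate volume, cc
    prostate_volume_median_cc: float = 31.0
    prostate_volume_sigma: float = 0.18
    prostate_volume_range_cc: tuple[float, float] = (21.0, 54.0)

    # lesions
    lesion_count_probs: tuple[float, ...] = (0.7, 0.3)  # P(1 lesion), P(2 lesions)
    volume_fraction_median: float = 0.19
    volume_fraction_sigma: float = 0.5
    volume_fraction_range: tuple[float, float] = (0.06, 0.75)
    suvmax_median: float = 8.2
    suvmax_sigma: float = 0.45
    suvmax_range: tuple[float, float] = (1.9, 21.4)
    gleason_probs: tuple[float, ...] = (0.23, 0.17, 0.14, 0.29, 0.17)
    # Gaussian-profile uptake (peaked, heterogeneous) is the default: the
    # fractional-SUVmax contour family only trades sensitivity against
    # specificity when intralesional uptake falls off from the peak, as it
    # does clinically.  "ellipsoid" gives uniform plateau inserts instead.
    lesion_shape: str = "gaussian"

    # satellite microfoci: small, low-uptake tumour deposits that systematic
    # biopsy can hit but imaging cannot resolve — positive biopsy sectors
    # regularly exceed the imaged lesion's footprint because of them
    satellite_rate: float = 1.2                     # Poisson mean per case
    satellite_volume_fraction_range: tuple[float, float] = (0.003, 0.015)
    satellite_suv_range: tuple[float, float] = (1.6, 2.8)

    # imaging
    background_suv: float = 1.5
    body_suv: float = 0.5
    psf_fwhm_mm: float = 6.0       # PET; MRI channels use mri_psf_fwhm_mm
    mri_psf_fwhm_mm: float = 0.0
    noise_suv: float = 0.1         # SD of additive PET noise (SUV)
    mri_noise_frac: float = 0.02   # MRI noise SD as a fraction of prostate signal

    # covariates
    psa_median: float = 15.4
    psa_sigma: float = 1.0
    psa_range: tuple[float, float] = (0.6, 57.9)

    placement_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.lesion_count_probs) - 1.0) > 1e-9:
            raise ValueError("lesion_count_probs must sum to 1")
        if abs(sum(self.gleason_probs) - 1.0) > 1e-9:
            raise ValueError("gleason_probs must sum to 1")
        if self.lesion_shape not in ("ellipsoid", "gaussian"):
            raise ValueError(f"unknown lesion_shape {self.lesion_shape!r}")


@dataclass
class GroundTruthLesion:
    """A simulated tumour focus with its true support and assigned uptake."""

    id: int
    center_mm: np.ndarray            # (3,) world coordinates
    semi_axes_mm: np.ndarray         # ellipsoid semi-axes (Gaussian: half-max radii)
    mask: np.ndarray                 # true binary support, on the case grid
    relative_volume_fraction: float  # lesion voxels / prostate voxels
    gleason_score: str               # one of GLEASON_LEVELS
    assigned_suvmax: float
    region: Region
    zone: Zone
    is_satellite: bool = False


@dataclass
class PhantomCase:
    """One generated patient: volumes, anatomy, lesions, covariates."""

    case_id: int
    volumes: dict[Modality, ImageVolume]
    anatomy: ProstateAnatomy
    lesions: list[GroundTruthLesion]
    covariates: dict[str, float]

    def lesion_volume_cc(self, lesion: GroundTruthLesion) -> float:
        return float(lesion.mask.sum()) * self.anatomy.voxel_volume_cc


def _lognormal(rng: np.random.Generator, median: float, sigma: float,
               lo: float, hi: float) -> float:
    return float(np.clip(median * np.exp(sigma * rng.standard_normal()), lo, hi))


def _grid_coords_mm(shape: tuple[int, int, int],
                    spacing: tuple[float, float, float]) -> list[np.ndarray]:
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def _ellipsoid_mask(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    xs, ys, zs = _grid_coords_mm(shape, spacing)
    u = (xs - center_mm[0]) / semi_axes_mm[0]
    v = (ys - center_mm[1]) / semi_axes_mm[1]
    w = (zs - center_mm[2]) / semi_axes_mm[2]
    return (u[:, None, None] ** 2 + v[None, :, None] ** 2
            + w[None, None, :] ** 2) <= 1.0


def build_anatomy(shape, spacing, prostate_volume_cc: float,
                  center_mm=None) -> ProstateAnatomy:
    """Construct an ellipsoidal prostate of the requested volume.

    Semi-axes follow a fixed anatomical aspect ratio (wider than tall); the
    transition zone is an inner, slightly anterior ellipsoid, the peripheral
    zone the remainder; apex/mid/base are equal thirds of the cranio-caudal
    extent (apex = caudal, base = cranial).
    """
    shape = tuple(shape)
    spacing = tuple(spacing)
    if center_mm is None:
        center_mm = np.array([(n - 1) * s / 2 for n, s in zip(shape, spacing)])
    # aspect ratio a:b:c = 1 : 0.85 : 1.0 (x : y : z), scaled to target volume
    ratio = np.array([1.0, 0.85, 1.0])
    vol_mm3 = prostate_volume_cc * 1000.0
    scale = (vol_mm3 / (4.0 / 3.0 * np.pi * np.prod(ratio))) ** (1.0 / 3.0)
    semi = ratio * scale
    mask = _ellipsoid_mask(shape, spacing, center_mm, semi)
    if not mask.any():
        raise ValueError("prostate does not fit on the grid")

    # transition zone: inner anterior ellipsoid
    tz_center = center_mm + np.array([0.0, -0.15 * semi[1], 0.0])
    tz_semi = semi * np.array([0.60, 0.55, 0.85])
    tz = _ellipsoid_mask(shape, spacing, tz_center, tz_semi) & mask
    zone = np.zeros(shape, dtype=np.int8)
    zone[mask] = int(Zone.PERIPHERAL)
    zone[tz] = int(Zone.TRANSITION)

    # equal-thirds cranio-caudal split; high z = cranial = base
    kz = np.flatnonzero(mask.any(axis=(0, 1)))
    edges = np.linspace(kz[0], kz[-1] + 1, 4)
    kk = np.arange(shape[2])
    region_of_k = np.zeros(shape[2], dtype=np.int8)
    region_of_k[(kk >= edges[0]) & (kk < edges[1])] = int(Region.APEX)
    region_of_k[(kk >= edges[1]) & (kk < edges[2])] = int(Region.MID)
    region_of_k[(kk >= edges[2]) & (kk <= kz[-1])] = int(Region.BASE)
    region = np.where(mask, region_of_k[None, None, :], 0).astype(np.int8)
    return ProstateAnatomy(mask, region, zone, spacing)


def _place_lesions(rng, spec: CohortSpec, anatomy: ProstateAnatomy,
                   prostate_semi: np.ndarray, center_mm: np.ndarray):
    """Sample lesion ellipsoids fully inside the prostate, disjoint from each other."""
    n_lesions = 1 + rng.choice(len(spec.lesion_count_probs), p=spec.lesion_count_probs)
    n_prostate = int(anatomy.prostate_mask.sum())
    lesions: list[GroundTruthLesion] = []
    occupied = np.zeros_like(anatomy.prostate_mask)
    for lid in range(n_lesions):
        frac = _lognormal(rng, spec.volume_fraction_median, spec.volume_fraction_sigma,
                          *spec.volume_fraction_range)
        if len(lesions) == 1 and frac > 0.3:
            frac = 0.3  # a second focus is kept small enough to coexist
        placed = False
        for attempt in range(spec.placement_retries):
            scale = frac ** (1.0 / 3.0)
            aniso = rng.uniform(0.85, 1.15, size=3)
            aniso /= np.prod(aniso) ** (1.0 / 3.0)
            semi = prostate_semi * scale * aniso
            # admissible centre offset shrinks as the lesion grows
            slack = np.maximum(prostate_semi - semi, 0.0)
            offset = rng.uniform(-1, 1, size=3) * slack * 0.8
            c = center_mm + offset
            mask = _ellipsoid_mask(anatomy.prostate_mask.shape, anatomy.spacing, c, semi)
            if not mask.any():
                continue
            if (mask & ~anatomy.prostate_mask).any() or (mask & occupied).any():
                continue
            ci = np.round(c / np.asarray(anatomy.spacing)).astype(int)
            ci = np.clip(ci, 0, np.array(mask.shape) - 1)
            region = Region(int(anatomy.region_labels[tuple(ci)]) or int(Region.MID))
            zone = Zone(int(anatomy.zone_labels[tuple(ci)]) or int(Zone.PERIPHERAL))
            suv = max(_lognormal(rng, spec.suvmax_median, spec.suvmax_sigma,
                                 *spec.suvmax_range), spec.background_suv + 0.3)
            gleason = GLEASON_LEVELS[rng.choice(len(spec.gleason_probs),
                                                p=spec.gleason_probs)]
            lesions.append(GroundTruthLesion(
                id=lid, center_mm=c, semi_axes_mm=semi, mask=mask,
                relative_volume_fraction=float(mask.sum()) / n_prostate,
                gleason_score=gleason, assigned_suvmax=suv,
                region=region, zone=zone))
            occupied |= mask
            placed = True
            break
        if not placed:
            if lid == 0:
                raise InfeasibleSpecError(
                    f"could not place a lesion of volume fraction {frac:.2f} "
                    f"inside the prostate after {spec.placement_retries} retries")
            break  # drop an infeasible secondary focus

    # imaging-occult satellite microfoci
    n_sat = int(rng.poisson(spec.satellite_rate))
    next_id = len(lesions)
    for s in range(n_sat):
        frac = float(rng.uniform(*spec.satellite_volume_fraction_range))
        for attempt in range(spec.placement_retries // 4):
            scale = frac ** (1.0 / 3.0)
            semi = prostate_semi * scale * rng.uniform(0.85, 1.15, size=3)
            slack = np.maximum(prostate_semi - semi, 0.0)
            c = center_mm + rng.uniform(-1, 1, size=3) * slack * 0.9
            mask = _ellipsoid_mask(anatomy.prostate_mask.shape, anatomy.spacing, c, semi)
            if not mask.any() or (mask & ~anatomy.prostate_mask).any() \
                    or (mask & occupied).any():
                continue
            ci = np.clip(np.round(c / np.asarray(anatomy.spacing)).astype(int),
                         0, np.array(mask.shape) - 1)
            lesions.append(GroundTruthLesion(
                id=next_id, center_mm=c, semi_axes_mm=semi, mask=mask,
                relative_volume_fraction=float(mask.sum()) / n_prostate,
                gleason_score=str(rng.choice(["6", "7a", "7b"], p=[0.5, 0.3, 0.2])),
                assigned_suvmax=float(rng.uniform(*spec.satellite_suv_range)),
                region=Region(int(anatomy.region_labels[tuple(ci)]) or int(Region.MID)),
                zone=Zone(int(anatomy.zone_labels[tuple(ci)]) or int(Zone.PERIPHERAL)),
                is_satellite=True))
            occupied |= mask
            next_id += 1
            break
    return lesions


def _fwhm_to_sigma_vox(fwhm_mm: float, spacing) -> list[float]:
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return [sigma_mm / s for s in spacing]


def _lesion_uptake(spec: CohortSpec, shape, spacing, lesion: GroundTruthLesion,
                   amplitude: float) -> np.ndarray:
    """Pre-blur uptake increment of one lesion; peak equals ``amplitude``."""
    if spec.lesion_shape == "ellipsoid":
        return amplitude * lesion.mask.astype(float)
    # Gaussian profile: semi-axes are half-max radii, sigma = r / sqrt(2 ln 2);
    # uptake is confined to the lesion support (tracer lives in tumour tissue,
    # spill-out beyond the boundary comes from the PSF, not the profile)
    xs, ys, zs = _grid_coords_mm(shape, spacing)
    sig = lesion.semi_axes_mm / np.sqrt(2.0 * np.log(2.0))
    u = (xs - lesion.center_mm[0]) / sig[0]
    v = (ys - lesion.center_mm[1]) / sig[1]
    w = (zs - lesion.center_mm[2]) / sig[2]
    q = (u[:, None, None] ** 2 + v[None, :, None] ** 2 + w[None, None, :] ** 2)
    return amplitude * np.exp(-0.5 * q) * lesion.mask


def _render_channel(base: np.ndarray, fwhm_mm: float, noise_sd: float,
                    spacing, rng, nonneg: bool) -> np.ndarray:
    img = base
    if fwhm_mm > 0:
        img = ndimage.gaussian_filter(img, _fwhm_to_sigma_vox(fwhm_mm, spacing))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    if nonneg:
        img = np.clip(img, 0.0, None)
    return img


# MRI channel signal levels (arbitrary units): body, prostate, lesion.
_MRI_LEVELS = {
    Modality.T2W: (60.0, 100.0, 55.0),   # lesion hypointense
    Modality.ADC: (900.0, 1300.0, 650.0),  # restricted diffusion: dark
    Modality.DCE: (40.0, 55.0, 120.0),   # marked enhancement: bright
}


def generate_case(spec: CohortSpec, case_index: int) -> PhantomCase:
    """Generate one synthetic patient, deterministically from (spec.seed, case_index)."""
    if case_index >= spec.n_patients:
        raise ValueError(f"case_index {case_index} >= n_patients {spec.n_patients}")
    rng = np.random.default_rng([int(spec.seed), int(case_index)])

    pvol = _lognormal(rng, spec.prostate_volume_median_cc, spec.prostate_volume_sigma,
                      *spec.prostate_volume_range_cc)
    anatomy = build_anatomy(spec.shape, spec.spacing, pvol)
    center_mm = np.array([(n - 1) * s / 2 for n, s in zip(spec.shape, spec.spacing)])
    ratio = np.array([1.0, 0.85, 1.0])
    scale = (pvol * 1000.0 / (4.0 / 3.0 * np.pi * np.prod(ratio))) ** (1.0 / 3.0)
    lesions = _place_lesions(rng, spec, anatomy, ratio * scale, center_mm)

    # PET: body + prostate background + lesion inserts, blur, truncated noise
    pet = np.full(spec.shape, spec.body_suv, dtype=float)
    pet[anatomy.prostate_mask] = spec.background_suv
    for les in lesions:
        inc = _lesion_uptake(spec, spec.shape, spec.spacing, les,
                             les.assigned_suvmax - spec.background_suv)
        np.maximum(pet, spec.background_suv + inc, out=pet, where=inc > 1e-12)
    pet = _render_channel(pet, spec.psf_fwhm_mm, spec.noise_suv, spec.spacing,
                          rng, nonneg=True)
    volumes = {spec.pet_modality: ImageVolume(pet, spec.spacing, spec.pet_modality)}

    for mod, (body, prost, les_level) in _MRI_LEVELS.items():
        img = np.full(spec.shape, body, dtype=float)
        img[anatomy.prostate_mask] = prost
        for les in lesions:
            if not les.is_satellite:  # microfoci are below MRI visibility
                img[les.mask] = les_level
        img = _render_channel(img, spec.mri_psf_fwhm_mm,
                              spec.mri_noise_frac * prost, spec.spacing,
                              rng, nonneg=False)
        volumes[mod] = ImageVolume(img, spec.spacing, mod)

    covariates = {
        "case_id": float(case_index),
        "psa_ng_ml": _lognormal(rng, spec.psa_median, spec.psa_sigma, *spec.psa_range),
        "prostate_volume_cc": anatomy.prostate_volume_cc,
    }
    return PhantomCase(case_index, volumes, anatomy, lesions, covariates)


def generate_cohort(spec: CohortSpec) -> list[PhantomCase]:
    """All cases of the cohort, in index order."""
    return [generate_case(spec, i) for i in range(spec.n_patients)]


def simulate_manual_contour(mask: np.ndarray, spacing, observer_noise_mm: float,
                            seed: int, modality: Modality | str = Modality.PET_GA68,
                            correlation_mm: float = 6.0) -> Contour:
    """Simulate a human reader's contour of a known lesion.

    The true boundary is displaced by a smooth, zero-mean random field with
    RMS amplitude ``observer_noise_mm`` (correlation length ``correlation_mm``),
    implemented as a level-set shift of the signed distance to the true mask.
    ``observer_noise_mm = 0`` returns the true mask unchanged.
    """
    if observer_noise_mm < 0:
        raise ValueError("observer_noise_mm must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if observer_noise_mm == 0:
        out = mask.copy()
    else:
        rng = np.random.default_rng(seed)
        sd = (ndimage.distance_transform_edt(~mask, sampling=spacing)
              - ndimage.distance_transform_edt(mask, sampling=spacing))
        noise = rng.standard_normal(mask.shape)
        sig_vox = [correlation_mm / s for s in spacing]
        noise = ndimage.gaussian_filter(noise, sig_vox)
        rms = float(np.sqrt(np.mean(noise ** 2)))
        field = observer_noise_mm * noise / max(rms, 1e-12)
        out = sd <= field
        if not out.any():  # never destroy the lesion entirely
            out = mask.copy()
    vox_cc = float(np.prod(spacing)) / 1000.0
    return Contour(mask=out, modality=Modality(modality), method="manual_sim",
                   threshold=None, volume_cc=float(out.sum()) * vox_cc,
                   suvmax=float("nan"))
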