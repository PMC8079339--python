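"""End-to-end cohort analysis: phantom -> biopsy -> registration -> scoring.

``run_cohort`` generates a synthetic cohort, simulates the biopsy reference
standard, registers the sector schematic to each case (per axial level),
produces manual-simulated and fractional/absolute SUV-threshold contours,
scores every dominant lesion's contour against the biopsy sectors, and
returns tidy per-lesion records plus the per-method summary, the selected
best threshold and the factor-correlation table.  All randomness derives
from one seed; identical seeds give byte-identical report CSVs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as met
from . import stats as st
from .contouring import FRACTIONAL_THRESHOLDS, Contour, auto_contour, select_dominant
from .phantom import CohortSpec, PhantomCase, generate_case, simulate_manual_contour
from .registration import (angle_sorted_outline, fit_deformation, fit_rigid,
                           prostate_outline, transfer_sectors)
from .sectors import (SCHEMATIC_RADIUS, BiopsyScheme, SectorMap,
                      build_sector_map, simulate_biopsy)
from .volumes import Modality, Region

__all__ = ["PipelineConfig", "CaseResult", "CohortResult", "run_cohort",
           "register_case", "analyse_case"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the analysis stage (not of the phantom)."""

    fractional_thresholds: tuple[float, ...] = FRACTIONAL_THRESHOLDS
    absolute_threshold_suv: float = 3.0
    margin_mm: float = 5.0
    margin_mode: str = "contour"    # contour | both | reference
    overlap_fraction: float = 0.0   # tau: sector-hit voxel fraction
    unsampled_as_negative: bool = True
    n_control_points: int = 16
    pet_observer_noise_mm: float = 1.5
    mri_observer_noise_mm: float = 2.5
    dominant_min_volume_cc: float = 1.0
    dominant_min_suv: float = 3.0

    def __post_init__(self) -> None:
        if self.margin_mode not in ("both", "contour", "reference"):
            raise ValueError(f"unknown margin_mode {self.margin_mode!r}")

    def method_labels(self) -> list[str]:
        labels = [f"SUV_abs{self.absolute_threshold_suv:g}"]
        labels += [f"SUV_{int(round(f * 100))}%" for f in self.fractional_thresholds]
        labels += ["PET_man", "mpMRI_man"]
        return labels


@dataclass
class CaseResult:
    case: PhantomCase
    biopsy_map: SectorMap
    registered_assignment: np.ndarray
    records: list[met.MetricsRecord]


@dataclass
class CohortResult:
    records: pd.DataFrame          # one row per lesion x method
    summary: pd.DataFrame          # per-method mean +/- SD (table-shaped)
    per_threshold: pd.DataFrame    # fractional/absolute rows of the summary
    best_threshold: float
    best_threshold_info: dict
    factor_table: pd.DataFrame
    factor_correlations: pd.DataFrame
    method_comparison: st.StatResult
    manifest: dict

    def write_reports(self, out_dir) -> None:
        """Write the deterministic report CSVs and the run manifest."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "lesion_metrics.csv", index=False,
                            float_format="%.10g")
        self.summary.to_csv(out / "method_summary.csv", index=False,
                            float_format="%.10g")
        self.factor_correlations.to_csv(out / "factor_correlations.csv",
                                        index=False, float_format="%.10g")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def register_case(case: PhantomCase, sector_map: SectorMap,
                  n_control_points: int = 16) -> np.ndarray:
    """Warp the schematic onto the case, one registration per axial level.

    For each region the prostate outline of the representative (middle)
    slice drives the rigid + thin-plate-spline fit; the fitted mapping then
    assigns sectors on every slice of that region's slab.  Correspondence is
    anchored anatomically (both outlines resampled counter-clockwise from
    the patient-right direction), as the standard display orientation fixes
    it for a human operator.  Returns the registered 3D sector-uid volume.
    """
    anatomy = case.anatomy
    theta = np.linspace(0.0, 2.0 * np.pi, 72, endpoint=False)
    schematic_outline = SCHEMATIC_RADIUS * np.column_stack([np.cos(theta),
                                                            np.sin(theta)])
    n_anchor = 64
    src_anchored = angle_sorted_outline(schematic_outline, n_anchor)
    assignment = np.zeros(anatomy.prostate_mask.shape, dtype=np.int16)
    for region in (Region.APEX, Region.MID, Region.BASE):
        slab = anatomy.region_slab_slices(region)
        rep = int(slab[len(slab) // 2])
        target = angle_sorted_outline(prostate_outline(anatomy, rep), n_anchor)
        rigid = fit_rigid(src_anchored, target, with_scale=True,
                          assume_matched=True)
        warp = fit_deformation(rigid.apply(src_anchored), target,
                               n_control_points=n_control_points)
        for k in slab:
            if anatomy.prostate_mask[:, :, k].any():
                assignment[:, :, k] = transfer_sectors(
                    sector_map, region, warp, rigid, anatomy, int(k))
    return assignment


def _lesion_covariates(case: PhantomCase, lesion) -> dict:
    return {"region": lesion.region.name.lower(),
            "volume_fraction": lesion.relative_volume_fraction,
            "gleason": lesion.gleason_score,
            "psa_ng_ml": case.covariates["psa_ng_ml"],
            "suvmax": lesion.assigned_suvmax}


def selected_lesions(case: PhantomCase, config: PipelineConfig) -> list:
    """The dominant lesions entering the correlation analysis.

    A lesion is selected once — imaged volume >= 1 cc and uptake >= SUV 3 —
    and every contouring arm is then evaluated on this fixed set, so
    per-threshold means are paired across thresholds.
    """
    vox_cc = case.anatomy.voxel_volume_cc
    return [l for l in case.lesions
            if not l.is_satellite
            and l.mask.sum() * vox_cc >= config.dominant_min_volume_cc
            and l.assigned_suvmax >= config.dominant_min_suv]


def _lesion_mask_for(contours: list[Contour], lesion) -> np.ndarray:
    """Union of threshold-contour components overlapping one lesion.

    The empty mask (lesion invisible at this threshold) is a valid result:
    it scores zero predicted sectors rather than dropping the lesion.
    """
    out = np.zeros_like(lesion.mask)
    for c in contours:
        if (c.mask & lesion.mask).any():
            out |= c.mask
    return out


def _case_contour_masks(case: PhantomCase, config: PipelineConfig,
                        rng: np.random.Generator):
    """Per-arm, per-selected-lesion contour masks: {label: [(lesion, mask)]}."""
    anatomy = case.anatomy
    pet = next(v for v in case.volumes.values() if v.modality.is_pet)
    chosen = selected_lesions(case, config)
    arms: dict[str, list] = {}
    abs_label = f"SUV_abs{config.absolute_threshold_suv:g}"
    components = {abs_label: auto_contour(pet, anatomy,
                                          config.absolute_threshold_suv,
                                          fractional=False)}
    for f in config.fractional_thresholds:
        components[f"SUV_{int(round(f * 100))}%"] = auto_contour(
            pet, anatomy, f, fractional=True)
    for label, comps in components.items():
        arms[label] = [(les, _lesion_mask_for(comps, les)) for les in chosen]
    for label, noise in (("PET_man", config.pet_observer_noise_mm),
                         ("mpMRI_man", config.mri_observer_noise_mm)):
        pairs = []
        for les in chosen:
            c = simulate_manual_contour(les.mask, anatomy.spacing, noise,
                                        seed=int(rng.integers(2 ** 31)),
                                        modality=pet.modality if label == "PET_man"
                                        else Modality.T2W)
            pairs.append((les, c.mask))
        arms[label] = pairs
    return arms


def analyse_case(case: PhantomCase, config: PipelineConfig,
                 biopsy_map: SectorMap, registered_assignment: np.ndarray,
                 rng: np.random.Generator) -> list[met.MetricsRecord]:
    """Score every contouring arm of one case against its biopsy sectors."""
    anatomy = case.anatomy
    ref_margin: set[int] | None = None
    if config.margin_mode in ("both", "reference"):
        ref_margin = met.biopsy_margin_sectors(biopsy_map, config.margin_mm)
    contour_margin = (config.margin_mm
                      if config.margin_mode in ("both", "contour") else 0.0)
    records = []
    for label, pairs in _case_contour_masks(case, config, rng).items():
        for lesion, mask in pairs:
            predicted = met.sectorize_contour(
                mask, registered_assignment, anatomy.spacing,
                margin_mm=contour_margin,
                overlap_fraction=config.overlap_fraction)
            rec = met.score(predicted, biopsy_map,
                            case_id=case.case_id,
                            lesion_id=lesion.id,
                            method=label,
                            covariates=_lesion_covariates(case, lesion),
                            unsampled_as_negative=config.unsampled_as_negative,
                            margin_sectors=ref_margin)
            if not mask.any():
                rec.flags.append("empty_contour")
            records.append(rec)
    return records


def run_cohort(spec: CohortSpec, config: PipelineConfig | None = None,
               scheme: BiopsyScheme | None = None,
               keep_cases: bool = False) -> CohortResult | tuple:
    """Run the full validation pipeline on a synthetic cohort.

    Returns a :class:`CohortResult`; with ``keep_cases`` additionally the
    list of per-case intermediates (for inspection and plotting).
    """
    config = config or PipelineConfig()
    scheme = scheme or BiopsyScheme()
    all_records: list[met.MetricsRecord] = []
    case_results: list[CaseResult] = []
    for i in range(spec.n_patients):
        case = generate_case(spec, i)
        smap = build_sector_map(case.anatomy, case_id=i)
        biopsy_seed = int(np.random.default_rng([spec.seed, i, 1]).integers(2 ** 31))
        visible = [l for l in case.lesions if not l.is_satellite]
        labelled = simulate_biopsy(case.anatomy, case.lesions, scheme, smap,
                                   targeted_lesions=visible,
                                   seed=biopsy_seed)
        reg = register_case(case, smap, config.n_control_points)
        rng = np.random.default_rng([spec.seed, i, 2])
        records = analyse_case(case, config, labelled, reg, rng)
        all_records.extend(records)
        if keep_cases:
            case_results.append(CaseResult(case, labelled, reg, records))

    df = met.records_to_frame(all_records)
    summary = met.aggregate(df, by="method")
    thr_rows = []
    for _, row in summary.iterrows():
        label = row["method"]
        if label.startswith("SUV_abs"):
            thr_rows.append({**row, "threshold": float(label[7:]), "kind": "abs"})
        elif label.startswith("SUV_") and label.endswith("%"):
            thr_rows.append({**row, "threshold": float(label[4:-1]) / 100.0,
                             "kind": "frac"})
    per_threshold = pd.DataFrame(thr_rows)
    frac_only = per_threshold[per_threshold["kind"] == "frac"]
    best, info = met.best_threshold(frac_only)

    ft = st.factor_table(df[df["volume_fraction"].notna()].copy())
    fct = st.factor_correlation_table(ft.assign(method=ft["method"]))
    groups = {m: g["dsc"].dropna().to_numpy()
              for m, g in df.groupby("method", sort=False)}
    usable = {m: v for m, v in groups.items() if len(v) >= 3}
    if len(usable) >= 2:
        comparison = st.compare_methods(usable)
        if len(usable) < len(groups):
            comparison.flags.append("methods_with_n_lt_3_excluded")
    else:
        comparison = st.StatResult(test="kruskal_wallis", statistic=float("nan"),
                                   p_value=float("nan"),
                                   group_labels=tuple(groups),
                                   n_per_group=tuple(len(v) for v in groups.values()),
                                   flags=["insufficient_group_sizes"])

    manifest = {"seed": int(spec.seed), "n_patients": int(spec.n_patients),
                "thresholds": list(config.fractional_thresholds),
                "absolute_threshold_suv": config.absolute_threshold_suv,
                "margin_mm": config.margin_mm,
                "margin_mode": config.margin_mode,
                "n_systematic_cores": scheme.n_systematic_cores,
                "targeted": scheme.targeted}
    result = CohortResult(records=df, summary=summary,
                          per_threshold=per_threshold,
                          best_threshold=float(best),
                          best_threshold_info=info,
                          factor_table=ft, factor_correlations=fct,
                          method_comparison=comparison, manifest=manifest)
    return (result, case_results) if keep_cases else result
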