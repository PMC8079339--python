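"""Sector-level scoring of lesion contours against biopsy labels.

The reference standard is the labelled 36-sector map: a contour predicts a
sector positive when its (margin-expanded) mask overlaps the sector's voxels;
biopsy-positive sectors are the ground truth.  From the resulting confusion
counts the Dice similarity coefficient (DSC), sensitivity, specificity and
Youden index (YI = sensitivity + specificity - 1) are computed per lesion
and per contouring method, then aggregated as mean +/- SD across lesions.

Sector-level (not voxel-level) scoring is the primary definition because the
reference standard is discrete biopsy sectors (a section model); a voxel-level
Dice against the margin-expanded positive-sector volume is available as a
secondary mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contouring import Contour, expand_margin
from .sectors import SectorMap

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "sectorize_contour",
    "score",
    "score_sets",
    "voxel_dice",
    "aggregate",
    "best_threshold",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Sector-level confusion counts of one contour vs one labelled map."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def dice(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2.0 * self.tp / denom if denom else math.nan

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else math.nan

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass
class MetricsRecord:
    """Per-lesion, per-method metric row with its covariates."""

    case_id: int
    lesion_id: int
    method: str
    counts: ConfusionCounts
    covariates: dict[str, object] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def dice(self) -> float:
        return self.counts.dice

    @property
    def youden(self) -> float:
        return self.counts.youden

    @property
    def sensitivity(self) -> float:
        return self.counts.sensitivity

    @property
    def specificity(self) -> float:
        return self.counts.specificity

    def to_row(self) -> dict:
        row = {"case_id": self.case_id, "lesion_id": self.lesion_id,
               "method": self.method,
               "tp": self.counts.tp, "fp": self.counts.fp,
               "fn": self.counts.fn, "tn": self.counts.tn,
               "dsc": self.dice, "yi": self.youden,
               "sensitivity": self.sensitivity, "specificity": self.specificity,
               "flags": ";".join(self.flags)}
        row.update(self.covariates)
        return row


def sectorize_contour(contour: Contour | np.ndarray, assignment: np.ndarray,
                      spacing, margin_mm: float = 5.0,
                      overlap_fraction: float = 0.0) -> set[int]:
    """Sectors predicted positive by a (margin-expanded) contour.

    A sector is predicted when the expanded contour covers more than
    ``overlap_fraction`` of its voxels (the default, 0, means any overlap).
    ``assignment`` may be the full 3D sector-uid volume or a stack of
    registered 2D slice assignments on the same grid.
    """
    mask = contour.mask if isinstance(contour, Contour) else np.asarray(contour, bool)
    if mask.shape != assignment.shape:
        raise ValueError("contour and sector assignment are on different grids")
    if not mask.any():
        return set()
    expanded = expand_margin(mask, margin_mm, spacing)
    uids = np.unique(assignment[expanded & (assignment > 0)])
    if overlap_fraction <= 0:
        return set(int(u) for u in uids)
    out = set()
    for u in uids:
        sector_vox = assignment == u
        frac = float((sector_vox & expanded).sum()) / float(sector_vox.sum())
        if frac >= overlap_fraction:
            out.add(int(u))
    return out


def score_sets(predicted: set[int], positive: set[int],
               scored: set[int]) -> ConfusionCounts:
    """Confusion counts over an explicit universe of scored sector uids."""
    predicted = predicted & scored
    positive = positive & scored
    tp = len(predicted & positive)
    fp = len(predicted - positive)
    fn = len(positive - predicted)
    tn = len(scored) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def score(predicted: set[int], biopsy_map: SectorMap,
          case_id: int = 0, lesion_id: int = 0, method: str = "",
          covariates: dict | None = None,
          unsampled_as_negative: bool = True,
          margin_sectors: set[int] | None = None) -> MetricsRecord:
    """Score predicted sectors against the biopsy-labelled map.

    With ``unsampled_as_negative`` (default) all 36 sectors are scored and a
    sector without a positive biopsy counts against the contour; otherwise
    only sampled sectors enter the counts.  ``margin_sectors`` optionally
    widens the reference by marking the biopsy contour's own margin sectors
    positive (the two-sided margin mode).  A map with no positive sector
    leaves sensitivity undefined; the record is flagged.
    """
    positive = biopsy_map.positive_uids
    if margin_sectors:
        positive = positive | set(margin_sectors)
    scored = ({s.uid for s in biopsy_map.sectors} if unsampled_as_negative
              else biopsy_map.sampled_uids | positive)
    counts = score_sets(set(predicted), positive, scored)
    flags = []
    if not positive:
        flags.append("no_positive_sectors")
    rec = MetricsRecord(case_id=case_id, lesion_id=lesion_id, method=method,
                        counts=counts, covariates=dict(covariates or {}),
                        flags=flags)
    return rec


def biopsy_margin_sectors(biopsy_map: SectorMap, margin_mm: float = 5.0) -> set[int]:
    """Sectors within ``margin_mm`` of any biopsy-positive sector's voxels.

    Implements the reference-side half of the isotropic margin: the positive
    sectors' voxel support is dilated and every sector it reaches is treated
    as positive for scoring.
    """
    pos = biopsy_map.positive_uids
    if not pos:
        return set()
    mask = np.isin(biopsy_map.assignment, sorted(pos))
    expanded = expand_margin(mask, margin_mm, biopsy_map.spacing)
    uids = np.unique(biopsy_map.assignment[expanded & (biopsy_map.assignment > 0)])
    return set(int(u) for u in uids)


def voxel_dice(contour: Contour, biopsy_map: SectorMap,
               margin_mm: float = 5.0) -> float:
    """Secondary voxel-level Dice: expanded contour vs expanded positive sectors."""
    pos = biopsy_map.positive_uids
    ref = np.isin(biopsy_map.assignment, sorted(pos)) if pos else np.zeros_like(
        biopsy_map.assignment, dtype=bool)
    ref = expand_margin(ref, margin_mm, biopsy_map.spacing)
    pred = expand_margin(contour.mask, margin_mm, biopsy_map.spacing)
    denom = int(ref.sum()) + int(pred.sum())
    return 2.0 * float((ref & pred).sum()) / denom if denom else math.nan


_METRICS = ("dsc", "yi", "sensitivity", "specificity")


def records_to_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


def aggregate(records: list[MetricsRecord] | pd.DataFrame,
              by: str = "method") -> pd.DataFrame:
    """Mean +/- sample SD of each metric per method (or another grouping).

    Undefined metric values (e.g. sensitivity of a case without positive
    sectors) are excluded pairwise; ``n`` counts records, ``n_<metric>``
    the values actually averaged.  Single-record groups report SD 0 and are
    flagged ``n=1``.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no records to aggregate")
    rows = []
    for label, grp in df.groupby(by, sort=False):
        row = {by: label, "n": len(grp)}
        for m in _METRICS:
            vals = grp[m].dropna()
            row[f"{m}_mean"] = float(vals.mean()) if len(vals) else math.nan
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row[f"n_{m}"] = int(len(vals))
        row["flag"] = "n=1" if len(grp) == 1 else ""
        rows.append(row)
    return pd.DataFrame(rows)


def best_threshold(per_threshold: pd.DataFrame,
                   threshold_col: str = "threshold",
                   dsc_col: str = "dsc_mean", yi_col: str = "yi_mean",
                   spec_col: str = "specificity_mean"):
    """Pick the contouring threshold with the highest mean DSC.

    The best automatic contouring method is the one maximising mean DSC; the
    function asserts that the same threshold also maximises mean YI and flags
    discordance otherwise (returning the DSC maximiser).  Exact DSC ties are
    broken by YI, then by higher specificity.

    Returns ``(threshold, info_dict)``.
    """
    df = pd.DataFrame(per_threshold)
    if len(df) < 2:
        raise ValueError("need aggregates for at least two thresholds")
    order = [c for c in (dsc_col, yi_col, spec_col) if c in df.columns]
    ranked = df.sort_values(order, ascending=False, kind="mergesort")
    best_row = ranked.iloc[0]
    info = {"discordant": False, "tie": False}
    top_dsc = df[dsc_col].max()
    ties = df[np.isclose(df[dsc_col], top_dsc)]
    if len(ties) > 1:
        info["tie"] = True
    if yi_col in df.columns:
        yi_best = df.loc[df[yi_col].idxmax(), threshold_col]
        if yi_best != best_row[threshold_col]:
            info["discordant"] = True
            info["yi_maximizer"] = yi_best
    return best_row[threshold_col], info
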