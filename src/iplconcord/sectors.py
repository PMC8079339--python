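"""The biopsy sector schematic and simulated prostate punch biopsy.

The prostate is divided into 12 segments at each of the apex, mid and base
levels (36 sectors total).  A segment is the product of side (left/right),
zone (peripheral/transition) and one of three angular wedges, which yields an
even, zone-aware 12-fold subdivision per level.  Each sector exists both as

* a voxel set on the case grid (via the region partition and an angular /
  zonal subdivision around the per-region centroid), and
* a 2D polygon on an idealised schematic plane (one plane per region), the
  object that registration deforms onto a patient slice.

``simulate_biopsy`` sends systematic (and optionally targeted) cores through
the gland; a core that traverses a lesion detects it with probability
``1 - exp(-path_length / lambda)``, so short intralesional paths — small
foci — are missed more often.  Positive sectors inherit the lesion's Gleason
score; sectors no core passed through are ``unsampled``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .phantom import GroundTruthLesion
from .volumes import ProstateAnatomy, Region, Zone

__all__ = [
    "Sector",
    "SectorMap",
    "BiopsyScheme",
    "build_sector_map",
    "simulate_biopsy",
]

SIDES = ("left", "right")
STATUS = ("unsampled", "negative", "positive")

#: schematic prostate outline radius (schematic units ~ mm)
SCHEMATIC_RADIUS = 25.0
#: transition-zone ellipse of the schematic: semi-axes and anterior shift,
#: as fractions of the outline radius (mirrors the phantom's zonal anatomy)
_TZ_SEMI = (0.60, 0.55)
_TZ_SHIFT = -0.15
#: angular wedge boundaries (radians) of the mirrored half-plane angle
_WEDGE_EDGES = (-np.pi / 6.0, np.pi / 6.0)


@dataclass
class Sector:
    """One of the 36 schematic sectors, optionally carrying a biopsy label."""

    region: Region
    segment: int              # 1..12 within the region
    side: str                 # left | right
    zone: Zone
    wedge: int                # 0..2 angular wedge within the side
    polygon: Polygon          # schematic-plane footprint
    biopsy_status: str = "unsampled"
    gleason_score: str | None = None

    @property
    def uid(self) -> int:
        """Global sector id 1..36; doubles as the label-volume value."""
        return (int(self.region) - 1) * 12 + self.segment


def _segment_index(side: str, zone: Zone, wedge: int) -> int:
    """Fixed 1..12 enumeration: side-major, then zone, then wedge."""
    return SIDES.index(side) * 6 + (int(zone) - 1) * 3 + wedge + 1


def _wedge_of(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Angular wedge (0..2) of points, mirrored so left/right are symmetric."""
    phi = np.arctan2(dy, np.abs(dx))  # [-pi/2, pi/2]
    return np.digitize(phi, _WEDGE_EDGES)


def _schematic_polygons() -> dict[tuple[str, Zone, int], Polygon]:
    """Tile the schematic disc into the 12 side x zone x wedge polygons."""
    r = SCHEMATIC_RADIUS
    disc = Point(0.0, 0.0).buffer(r, quad_segs=90)
    unit = np.asarray(Point(0.0, 0.0).buffer(1.0, quad_segs=90).exterior.coords)
    tz = Polygon([(x * _TZ_SEMI[0] * r, _TZ_SHIFT * r + y * _TZ_SEMI[1] * r)
                  for x, y in unit]).intersection(disc)
    far = 4.0 * r
    polys: dict[tuple[str, Zone, int], Polygon] = {}
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        half = Polygon([(0, -far), (sgn * far, -far), (sgn * far, far), (0, far)])
        edges = (-np.pi / 2, *_WEDGE_EDGES, np.pi / 2)
        for w in range(3):
            a0, a1 = edges[w], edges[w + 1]
            cone = Polygon([(0.0, 0.0),
                            *[(sgn * far * np.cos(a), far * np.sin(a))
                              for a in np.linspace(a0, a1, 30)]])
            cell = disc.intersection(half).intersection(cone)
            polys[(side, Zone.TRANSITION, w)] = cell.intersection(tz)
            polys[(side, Zone.PERIPHERAL, w)] = cell.difference(tz)
    return polys


@dataclass
class SectorMap:
    """The 36-sector schematic bound to one case's voxel grid.

    ``assignment`` is an integer volume holding each prostate voxel's sector
    uid (1..36), zero outside the prostate.
    """

    sectors: list[Sector]
    assignment: np.ndarray
    spacing: tuple[float, float, float]
    case_id: int | None = None

    def __post_init__(self) -> None:
        if len(self.sectors) != 36:
            raise ValueError(f"a sector map has 36 sectors, got {len(self.sectors)}")

    def sector(self, uid: int) -> Sector:
        return self.sectors[uid - 1]

    def voxels_of(self, uid: int) -> np.ndarray:
        return self.assignment == uid

    @property
    def positive_uids(self) -> set[int]:
        return {s.uid for s in self.sectors if s.biopsy_status == "positive"}

    @property
    def sampled_uids(self) -> set[int]:
        return {s.uid for s in self.sectors if s.biopsy_status != "unsampled"}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{
            "case_id": self.case_id, "uid": s.uid,
            "region": s.region.name.lower(), "segment": s.segment,
            "side": s.side, "zone": s.zone.name.lower(),
            "status": s.biopsy_status,
            "gleason": s.gleason_score if s.gleason_score is not None else "",
        } for s in self.sectors]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def with_labels_from(self, df: pd.DataFrame) -> "SectorMap":
        """Return a copy whose biopsy labels are read back from a label table."""
        by_uid = {int(r.uid): r for r in df.itertuples()}
        sectors = []
        for s in self.sectors:
            r = by_uid[s.uid]
            gs = str(r.gleason) if str(r.gleason) not in ("", "nan") else None
            sectors.append(replace(s, biopsy_status=str(r.status), gleason_score=gs))
        return replace(self, sectors=sectors)

    def schematic_geojson(self) -> dict:
        """Sector polygons as a GeoJSON-style FeatureCollection."""
        feats = []
        for s in self.sectors:
            feats.append({
                "type": "Feature",
                "properties": {"uid": s.uid, "region": s.region.name.lower(),
                               "segment": s.segment, "side": s.side,
                               "zone": s.zone.name.lower()},
                "geometry": {"type": "Polygon",
                             "coordinates": [list(map(list, s.polygon.exterior.coords))]},
            })
        return {"type": "FeatureCollection", "features": feats}


def build_sector_map(anatomy: ProstateAnatomy, case_id: int | None = None) -> SectorMap:
    """Sectorise a prostate: 12 segments at each of apex, mid and base.

    Every prostate voxel receives exactly one sector (the sectors partition
    the gland); the schematic polygons tile the schematic disc per region.
    """
    polys = _schematic_polygons()
    sectors: list[Sector] = []
    assignment = np.zeros(anatomy.prostate_mask.shape, dtype=np.int16)
    xs = np.arange(anatomy.prostate_mask.shape[0]) * anatomy.spacing[0]
    ys = np.arange(anatomy.prostate_mask.shape[1]) * anatomy.spacing[1]

    for region in (Region.APEX, Region.MID, Region.BASE):
        rmask = anatomy.region_mask(region)
        if not rmask.any():
            raise ValueError(f"degenerate anatomy: region {region.name} is empty")
        ii, jj, kk = np.nonzero(rmask)
        cx, cy = xs[ii].mean(), ys[jj].mean()
        dx, dy = xs[ii] - cx, ys[jj] - cy
        side_idx = (dx >= 0).astype(int)              # 0 = left, 1 = right
        wedge = _wedge_of(dx, dy)
        zone = anatomy.zone_labels[ii, jj, kk]
        seg = side_idx * 6 + (zone.astype(int) - 1) * 3 + wedge + 1
        assignment[ii, jj, kk] = (int(region) - 1) * 12 + seg
        for side in SIDES:
            for zn in (Zone.PERIPHERAL, Zone.TRANSITION):
                for w in range(3):
                    sectors.append(Sector(
                        region=region, segment=_segment_index(side, zn, w),
                        side=side, zone=zn, wedge=w, polygon=polys[(side, zn, w)]))
    sectors.sort(key=lambda s: s.uid)
    return SectorMap(sectors=sectors, assignment=assignment,
                     spacing=anatomy.spacing, case_id=case_id)


@dataclass
class BiopsyScheme:
    """Systematic (and optional targeted) core layout plus the detection model.

    ``detection_scale_mm`` is the exponential scale of the per-core hit
    probability ``1 - exp(-path / scale)``; ``None`` makes every traversal a
    certain detection, ``inf`` makes detection impossible.
    """

    n_systematic_cores: int = 12
    targeted: bool = True
    detection_scale_mm: float | None = 3.0
    core_step_mm: float = 0.5
    lateral_fracs: tuple[float, float] = (0.3, 0.65)  # medial, lateral core offsets

    def __post_init__(self) -> None:
        if not 10 <= self.n_systematic_cores <= 12:
            raise ValueError("guideline-conform schemes use 10-12 systematic cores")

    def hit_probability(self, path_mm: float) -> float:
        if path_mm <= 0:
            return 0.0
        if self.detection_scale_mm is None:
            return 1.0
        if np.isinf(self.detection_scale_mm):
            return 0.0
        return 1.0 - float(np.exp(-path_mm / self.detection_scale_mm))


def _systematic_core_positions(anatomy: ProstateAnatomy, scheme: BiopsyScheme):
    """(x, z) entry positions: {left,right} x {medial,lateral} x {apex,mid,base}."""
    ii, jj, kk = np.nonzero(anatomy.prostate_mask)
    xs = ii * anatomy.spacing[0]
    cx = xs.mean()
    half_width = (xs.max() - xs.min()) / 2.0
    positions = []
    for region in (Region.APEX, Region.MID, Region.BASE):
        slab = anatomy.region_slab_slices(region)
        zc = (slab.mean()) * anatomy.spacing[2]
        for sgn in (-1.0, 1.0):
            for frac in scheme.lateral_fracs:
                positions.append((cx + sgn * frac * half_width, zc))
    # 12-core template; 10/11-core guideline variants drop medial apex cores
    drop = 12 - scheme.n_systematic_cores
    if drop:
        medial_apex = [p for p in positions[:4] if abs(p[0] - cx) < 0.5 * half_width]
        for p in medial_apex[:drop]:
            positions.remove(p)
    return positions


def _core_traversal(anatomy: ProstateAnatomy, lesions, assignment,
                    x_mm: float, z_mm: float, step_mm: float):
    """March a needle along the anterior-posterior axis at fixed (x, z).

    Returns per-lesion intralesional path length, the sector uids the core
    samples, and per-lesion sector uids traversed inside that lesion.
    """
    ny = anatomy.prostate_mask.shape[1]
    y = np.arange(0.0, ny * anatomy.spacing[1], step_mm)
    i = int(round(x_mm / anatomy.spacing[0]))
    k = int(round(z_mm / anatomy.spacing[2]))
    shape = anatomy.prostate_mask.shape
    if not (0 <= i < shape[0] and 0 <= k < shape[2]):
        return {}, set(), {}
    j = np.clip(np.round(y / anatomy.spacing[1]).astype(int), 0, ny - 1)
    in_prostate = anatomy.prostate_mask[i, j, k]
    sampled = set(int(u) for u in np.unique(assignment[i, j[in_prostate], k]) if u > 0)
    path: dict[int, float] = {}
    hit_sectors: dict[int, set[int]] = {}
    for les in lesions:
        inside = les.mask[i, j, k]
        if inside.any():
            path[les.id] = float(inside.sum()) * step_mm
            hit_sectors[les.id] = set(
                int(u) for u in np.unique(assignment[i, j[inside], k]) if u > 0)
    return path, sampled, hit_sectors


def simulate_biopsy(anatomy: ProstateAnatomy,
                    lesions: list[GroundTruthLesion],
                    scheme: BiopsyScheme,
                    sector_map: SectorMap,
                    targeted_lesions: list[GroundTruthLesion] | None = None,
                    seed: int = 0) -> SectorMap:
    """Label a sector map with simulated systematic + targeted biopsy results.

    Each core is a straight needle along the anterior-posterior axis; a core
    traversing a lesion detects it with the scheme's path-length probability.
    Detected lesions turn the sectors the core crossed *inside the lesion*
    positive (inheriting the lesion's Gleason score); all other sectors a core
    sampled become negative; the rest stay unsampled.
    """
    rng = np.random.default_rng(seed)
    positions = _systematic_core_positions(anatomy, scheme)
    if scheme.targeted and targeted_lesions:
        positions = positions + [(float(l.center_mm[0]), float(l.center_mm[2]))
                                 for l in targeted_lesions]
    sampled_all: set[int] = set()
    positive: dict[int, str] = {}
    for x_mm, z_mm in positions:
        path, sampled, hit_sectors = _core_traversal(
            anatomy, lesions, sector_map.assignment, x_mm, z_mm, scheme.core_step_mm)
        sampled_all |= sampled
        for les in lesions:
            if les.id in path and rng.random() < scheme.hit_probability(path[les.id]):
                for uid in hit_sectors[les.id]:
                    positive[uid] = les.gleason_score
    sectors = []
    for s in sector_map.sectors:
        if s.uid in positive:
            sectors.append(replace(s, biopsy_status="positive",
                                   gleason_score=positive[s.uid]))
        elif s.uid in sampled_all:
            sectors.append(replace(s, biopsy_status="negative", gleason_score=None))
        else:
            sectors.append(replace(s, biopsy_status="unsampled", gleason_score=None))
    return replace(sector_map, sectors=sectors)
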