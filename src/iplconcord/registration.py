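"""Two-step 2D mapping of the sector schematic onto a patient's axial slice.

Stage one is a least-squares rigid alignment (translation + rotation, with an
optional isotropic scale to absorb image-size differences).  Stage two is an
interpolating thin-plate-spline warp driven by control-point pairs sampled at
matched arc-length fractions along the schematic and patient prostate
outlines — the algorithmic analogue of interactive multipoint contour
deformation.  Registration is per axial level (apex, mid, base): the sector
schematic is a planar object and the validation uses a section model, so no
3D registration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import RBFInterpolator
from shapely.geometry import LinearRing, Polygon

from .sectors import SectorMap
from .volumes import ProstateAnatomy, Region

__all__ = [
    "RigidTransform2D",
    "DeformationWarp",
    "fit_rigid",
    "fit_deformation",
    "transfer_sectors",
    "resample_closed",
    "angle_sorted_outline",
    "prostate_outline",
]


@dataclass
class RigidTransform2D:
    """Similarity transform ``p -> s * R(theta) p + t`` in the axial plane."""

    tx: float
    ty: float
    theta: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix.T + (self.tx, self.ty)

    def inverse(self) -> "RigidTransform2D":
        inv = RigidTransform2D(tx=0.0, ty=0.0, theta=-self.theta,
                               scale=1.0 / self.scale)
        t_inv = -inv.matrix @ np.array([self.tx, self.ty])
        inv.tx, inv.ty = float(t_inv[0]), float(t_inv[1])
        return inv

    def to_dict(self) -> dict:
        return {"tx": self.tx, "ty": self.ty, "theta": self.theta, "scale": self.scale}


def _polyline_arclength(points: np.ndarray, closed: bool = True) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline at ``n`` equally spaced arc-length fractions."""
    pts = np.asarray(points, dtype=float)
    if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("need at least 3 points on a closed outline")
    s = _polyline_arclength(pts, closed=True)
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate outline with zero length")
    targets = np.linspace(0.0, total, n, endpoint=False)
    loop = np.vstack([pts, pts[:1]])
    out = np.empty((n, 2))
    for d in range(2):
        out[:, d] = np.interp(targets, s, loop[:, d])
    return out


def angle_sorted_outline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed outline counter-clockwise, starting at angle 0.

    Orders the points by polar angle about their centroid (robust for the
    near-convex prostate cross-section) and resamples at equal arc-length
    fractions from the +x direction.  Two outlines prepared this way are in
    anatomically matched correspondence — the role the standard display
    orientation plays when a human aligns the schematic.
    """
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    ang = np.mod(np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0]), 2.0 * np.pi)
    order = np.argsort(ang, kind="stable")
    return resample_closed(pts[order], n)


def _umeyama(src: np.ndarray, tgt: np.ndarray, with_scale: bool):
    """Least-squares similarity fit of corresponding 2D point sets."""
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    xs, xt = src - mu_s, tgt - mu_t
    cov = xt.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    if np.linalg.det(U @ Vt) < 0:
        S[1, 1] = -1.0  # guard against reflections
    R = U @ S @ Vt
    if with_scale:
        var_s = (xs ** 2).sum() / len(src)
        scale = float(np.trace(np.diag(D) @ S) / var_s)
    else:
        scale = 1.0
    t = mu_t - scale * (R @ mu_s)
    theta = float(np.arctan2(R[1, 0], R[0, 0]))
    rigid = RigidTransform2D(tx=float(t[0]), ty=float(t[1]), theta=theta, scale=scale)
    resid = float(np.mean(np.sum((rigid.apply(src) - tgt) ** 2, axis=1)))
    return rigid, resid


def _check_nondegenerate(points: np.ndarray, name: str) -> None:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError(f"{name}: need >= 3 points")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError(f"{name}: points are collinear; rotation unidentifiable")


def fit_rigid(source_contour: np.ndarray, target_contour: np.ndarray,
              with_scale: bool = False, n_samples: int = 100,
              assume_matched: bool = False) -> RigidTransform2D:
    """Least-squares rigid (+optional scale) alignment of two closed contours.

    Without known correspondences the contours are resampled at equal
    arc-length fractions and a circular shift (both orientations) is searched
    to resolve the starting-point ambiguity; with ``assume_matched`` the
    points are taken as already paired index-by-index.
    """
    src = np.asarray(source_contour, dtype=float)
    tgt = np.asarray(target_contour, dtype=float)
    _check_nondegenerate(src, "source")
    _check_nondegenerate(tgt, "target")
    if assume_matched:
        if len(src) != len(tgt):
            raise ValueError("assume_matched requires equally many points")
        rigid, _ = _umeyama(src, tgt, with_scale)
        return rigid
    s = resample_closed(src, n_samples)
    t = resample_closed(tgt, n_samples)
    best = None
    for cand in (t, t[::-1]):
        for shift in range(n_samples):
            rigid, resid = _umeyama(s, np.roll(cand, -shift, axis=0), with_scale)
            if best is None or resid < best[1]:
                best = (rigid, resid)
    return best[0]


@dataclass
class DeformationWarp:
    """Interpolating thin-plate-spline displacement between paired control points.

    Maps the (rigid-aligned) schematic plane onto the patient slice; the warp
    passes exactly through every control-point pair and is the identity when
    all pairs coincide.  An inverse interpolant (patient -> schematic),
    fitted on the swapped pairs, is used to pull voxel centres back onto the
    schematic for sector lookup.
    """

    source_points: np.ndarray
    target_points: np.ndarray
    _forward: RBFInterpolator = field(init=False, repr=False)
    _inverse: RBFInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        src = np.asarray(self.source_points, dtype=float)
        tgt = np.asarray(self.target_points, dtype=float)
        if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2:
            raise ValueError("control points must be matched (n, 2) arrays")
        self.source_points, self.target_points = src, tgt
        self._forward = RBFInterpolator(src, tgt - src,
                                        kernel="thin_plate_spline", smoothing=0.0)
        self._inverse = RBFInterpolator(tgt, src - tgt,
                                        kernel="thin_plate_spline", smoothing=0.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts + self._forward(pts)

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        """Approximate inverse (exact at control points)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts + self._inverse(pts)

    def control_point_residual(self) -> float:
        return float(np.max(np.linalg.norm(
            self.apply(self.source_points) - self.target_points, axis=1)))

    def to_dict(self) -> dict:
        return {"source_points": self.source_points.tolist(),
                "target_points": self.target_points.tolist()}


def _check_simple(points: np.ndarray, name: str) -> None:
    ring = LinearRing(np.asarray(points, dtype=float))
    if not ring.is_simple:
        raise ValueError(f"{name}: outline is self-intersecting")


def fit_deformation(schematic_outline: np.ndarray, patient_outline: np.ndarray,
                    n_control_points: int = 16) -> DeformationWarp:
    """Fit the multipoint contour warp between two closed outlines.

    Control points are sampled at matched arc-length fractions on both
    outlines (circular shift chosen to minimise total pair distance; the
    rigid stage is assumed already applied to the schematic outline).
    """
    if n_control_points < 3:
        raise ValueError("need at least 3 control points")
    _check_simple(schematic_outline, "schematic outline")
    _check_simple(patient_outline, "patient outline")
    src = resample_closed(schematic_outline, n_control_points)
    tgt = resample_closed(patient_outline, n_control_points)
    best = None
    for cand in (tgt, tgt[::-1]):
        for shift in range(n_control_points):
            rolled = np.roll(cand, -shift, axis=0)
            cost = float(np.sum((src - rolled) ** 2))
            if best is None or cost < best[1]:
                best = (rolled, cost)
    return DeformationWarp(source_points=src, target_points=best[0])


def transfer_sectors(sector_map: SectorMap, region: Region,
                     warp: DeformationWarp, rigid: RigidTransform2D,
                     anatomy: ProstateAnatomy, slice_k: int) -> np.ndarray:
    """Assign every prostate voxel of one axial slice to a warped sector.

    Voxel centres are pulled back through the inverse warp and inverse rigid
    onto the schematic plane and located in the region's sector polygons.  A
    voxel whose preimage lands outside all polygons (a numerical edge case)
    is assigned to the nearest polygon — never dropped.

    Returns a 2D ``(nx, ny)`` integer array of sector uids (0 outside the
    prostate on that slice).
    """
    if slice_k not in anatomy.region_slab_slices(region):
        raise ValueError(f"slice {slice_k} is not part of region {region.name}")
    mask2d = anatomy.prostate_mask[:, :, slice_k]
    out = np.zeros(mask2d.shape, dtype=np.int16)
    ii, jj = np.nonzero(mask2d)
    if len(ii) == 0:
        return out
    pts = np.column_stack([ii * anatomy.spacing[0], jj * anatomy.spacing[1]])
    schematic_pts = rigid.inverse().apply(warp.apply_inverse(pts))

    region_sectors = [s for s in sector_map.sectors if s.region == region]
    geoms = np.array([s.polygon for s in region_sectors], dtype=object)
    uids = np.array([s.uid for s in region_sectors], dtype=np.int16)
    points = shapely.points(schematic_pts)
    assigned = np.zeros(len(pts), dtype=np.int16)
    for poly, uid in zip(geoms, uids):
        hit = shapely.covers(poly, points) & (assigned == 0)
        assigned[hit] = uid
    missing = assigned == 0
    if missing.any():
        dist = np.stack([shapely.distance(poly, points[missing]) for poly in geoms])
        assigned[missing] = uids[np.argmin(dist, axis=0)]
    out[ii, jj] = assigned
    return out


def prostate_outline(anatomy: ProstateAnatomy, slice_k: int,
                     n_points: int = 64) -> np.ndarray:
    """Closed outline (mm) of the prostate cross-section on one axial slice."""
    from skimage import measure

    mask2d = anatomy.prostate_mask[:, :, slice_k].astype(float)
    contours = measure.find_contours(mask2d, 0.5)
    if not contours:
        raise ValueError(f"no prostate cross-section on slice {slice_k}")
    longest = max(contours, key=len)
    pts = longest * np.array(anatomy.spacing[:2])
    return resample_closed(pts, n_points)
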