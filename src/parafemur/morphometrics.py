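"""Morphological measures on corresponded femur meshes.

The measures mirror the classic femoral morphometrics used to sanity-check a
cohort against anthropometry: femur length, caput-collum-diaphyseal (CCD,
neck-shaft) angle, anterior mid-shaft cortical thickness and mid-shaft
cortical cross-section area, plus simple linear trendlines of measure vs
predictor with a two-sided slope p-value.

Axes are constructed algorithmically from landmark node sets defined once on
the template topology (and therefore valid for every corresponded mesh):

* femoral axis — first principal direction of all nodes;
* shaft axis — first principal direction of the proximal-shaft landmark
  cloud; neck axis — first principal direction of the neck landmark cloud,
  oriented head-ward;
* anterior cortical thickness — along rays cast from the mid-shaft axis
  through the anterior mid-shaft surface nodes, the span of consecutively
  cortical elements crossed, averaged over the patch;
* cortical cross-section area — exact plane/hexahedron intersection polygons
  at the mid-length plane perpendicular to the femoral axis, summed over
  cortical elements.

All measures are invariant to rigid motion; length and thickness scale
linearly and area quadratically under uniform scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .material import CORTICAL
from .mesh import HexMesh

__all__ = [
    "AxisLandmarks",
    "MorphometricsRecord",
    "Trendline",
    "MeasurementError",
    "femur_length",
    "ccd_angle",
    "anterior_midshaft_cortical_thickness",
    "midshaft_cortical_area",
    "fit_trendline",
    "measure_sample",
]


class MeasurementError(ValueError):
    """Raised when a geometric measure is undefined on the given input."""


@dataclass(frozen=True)
class AxisLandmarks:
    """Node-index sets (template topology) anchoring the axis constructions.

    ``anterior_midshaft_surface`` holds the outer-surface nodes of the
    anterior mid-shaft patch used for the cortical-thickness rays.
    """

    head: np.ndarray
    neck: np.ndarray
    proximal_shaft: np.ndarray
    mid_shaft: np.ndarray
    distal: np.ndarray
    anterior_midshaft_surface: np.ndarray

    def validate(self, n_nodes: int) -> None:
        for name in ("head", "neck", "proximal_shaft", "mid_shaft", "distal",
                     "anterior_midshaft_surface"):
            ids = getattr(self, name)
            if ids.size == 0:
                raise MeasurementError(f"landmark set {name!r} is empty")
            if ids.min() < 0 or ids.max() >= n_nodes:
                raise MeasurementError(f"landmark set {name!r} has indices outside [0, n)")


@dataclass(frozen=True)
class MorphometricsRecord:
    femur_length: float  # mm
    ccd_angle: float  # degrees, CCD (obtuse) convention
    anterior_midshaft_cortical_thickness: float  # mm
    midshaft_cortical_area: float  # mm^2


def _principal_direction(points: np.ndarray) -> np.ndarray:
    """Unit first principal direction of a point cloud."""
    if points.shape[0] < 3:
        raise MeasurementError("need at least 3 points for a principal direction")
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    if w[-1] <= 0:
        raise MeasurementError("degenerate (coincident) landmark cloud")
    return v[:, -1]


def femur_length(mesh: HexMesh, landmarks: AxisLandmarks) -> float:
    """Distance between the head and distal landmark centroids projected on
    the first principal axis of all nodes (mm)."""
    landmarks.validate(mesh.n_nodes)
    axis = _principal_direction(mesh.nodes)
    c_head = mesh.nodes[landmarks.head].mean(axis=0)
    c_dist = mesh.nodes[landmarks.distal].mean(axis=0)
    return float(abs(axis @ (c_head - c_dist)))


def ccd_angle(mesh: HexMesh, landmarks: AxisLandmarks) -> float:
    """Neck-shaft (CCD) angle in degrees, obtuse convention.

    Shaft axis: principal direction of the proximal-shaft landmark nodes,
    oriented toward the neck.  Neck axis: principal direction of the neck
    landmark nodes, oriented head-ward.
    """
    landmarks.validate(mesh.n_nodes)
    prox = mesh.nodes[landmarks.proximal_shaft]
    neck = mesh.nodes[landmarks.neck]
    c_head = mesh.nodes[landmarks.head].mean(axis=0)
    c_neck = neck.mean(axis=0)
    c_prox = prox.mean(axis=0)
    v_shaft = _principal_direction(prox)
    if v_shaft @ (c_neck - c_prox) < 0:
        v_shaft = -v_shaft
    v_neck = _principal_direction(neck)
    if v_neck @ (c_head - c_neck) < 0:
        v_neck = -v_neck
    cosang = float(np.clip(v_shaft @ v_neck, -1.0, 1.0))
    theta = float(np.degrees(np.arccos(cosang)))
    if theta in (0.0, 180.0):
        raise MeasurementError("collinear shaft and neck axes")
    return theta if theta >= 90.0 else 180.0 - theta


# VTK hexahedron faces (outward-ish ordering irrelevant here) and edges.
_HEX_FACES = np.array([
    [0, 1, 2, 3], [4, 7, 6, 5], [0, 4, 5, 1],
    [1, 5, 6, 2], [2, 6, 7, 3], [3, 7, 4, 0],
])
_HEX_EDGES = np.array([
    [0, 1], [1, 2], [2, 3], [3, 0],
    [4, 5], [5, 6], [6, 7], [7, 4],
    [0, 4], [1, 5], [2, 6], [3, 7],
])
# Each quad face split into two triangles.
_HEX_TRIS = np.vstack([
    np.concatenate([_HEX_FACES[:, [0, 1, 2]], _HEX_FACES[:, [0, 2, 3]]], axis=0)
])


def _ray_hex_intervals(origin: np.ndarray, direction: np.ndarray,
                       hex_coords: np.ndarray) -> list[tuple[int, float, float]]:
    """Entry/exit parameters of a ray through each (near-convex) hexahedron.

    ``hex_coords`` is (E, 8, 3).  Returns (element_position, t_in, t_out) for
    every hex the ray crosses, via Moller-Trumbore on the 12 face triangles
    with inclusive tolerances so shared-edge grazing hits are kept.
    """
    E = hex_coords.shape[0]
    if E == 0:
        return []
    tris = hex_coords[:, _HEX_TRIS, :]  # (E, 12, 3, 3)
    v0 = tris[:, :, 0, :]
    e1 = tris[:, :, 1, :] - v0
    e2 = tris[:, :, 2, :] - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("eij,eij->ei", e1, pvec)
    eps = 1e-12
    ok = np.abs(det) > eps
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin - v0
    u = np.einsum("eij,eij->ei", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,eij->ei", direction, qvec) * inv_det
    t = np.einsum("eij,eij->ei", e2, qvec) * inv_det
    tol = 1e-9
    hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1.0 + tol)
    out: list[tuple[int, float, float]] = []
    for e in range(E):
        ts = t[e][hit[e]]
        if ts.size >= 2:
            t_in, t_out = float(ts.min()), float(ts.max())
            if t_out - t_in > 1e-9:
                out.append((e, t_in, t_out))
    return out


def anterior_midshaft_cortical_thickness(mesh: HexMesh, tissue_class: np.ndarray,
                                         landmarks: AxisLandmarks) -> float:
    """Mean cortical wall thickness (mm) over the anterior mid-shaft patch.

    For each anterior surface node, a ray is cast from the mid-shaft axis
    through the node; the thickness along that ray is the total span of the
    consecutive run of cortical elements ending at the surface.  Raises
    :class:`MeasurementError` if no ray crosses cortical bone.
    """
    landmarks.validate(mesh.n_nodes)
    mid_nodes = mesh.nodes[landmarks.mid_shaft]
    axis_dir = _principal_direction(mid_nodes)
    axis_point = mid_nodes.mean(axis=0)

    # Prefilter candidate elements to the mid-shaft axial band.
    centroids = mesh.nodes[mesh.elements].mean(axis=1)
    band = axis_dir @ (mid_nodes - axis_point).T
    lo, hi = band.min() - 5.0, band.max() + 5.0
    axial = axis_dir @ (centroids - axis_point).T
    cand = np.nonzero((axial >= lo) & (axial <= hi))[0]
    if cand.size == 0:
        raise MeasurementError("mid-shaft band contains no elements")
    hex_coords = mesh.nodes[mesh.elements[cand]]
    cand_cortical = tissue_class[cand] == CORTICAL
    if not np.any(cand_cortical):
        raise MeasurementError("no cortical elements in the mid-shaft band")

    thicknesses = []
    for nid in landmarks.anterior_midshaft_surface:
        p = mesh.nodes[nid]
        foot = axis_point + (axis_dir @ (p - axis_point)) * axis_dir
        ray = p - foot
        L = float(np.linalg.norm(ray))
        if L < 1e-9:
            continue
        direction = ray / L
        intervals = _ray_hex_intervals(foot, direction, hex_coords)
        if not intervals:
            continue
        gap_tol = 1e-6 * L
        cortical_iv = sorted(
            ((t_in, t_out) for e, t_in, t_out in intervals if cand_cortical[e]),
            key=lambda iv: -iv[1],
        )
        if not cortical_iv or cortical_iv[0][1] < L - max(1e-6, gap_tol) * 10:
            continue  # surface element along this ray is not cortical
        # Walk inward through contiguous cortical intervals.
        outer = cortical_iv[0][1]
        inner = cortical_iv[0][0]
        changed = True
        while changed:
            changed = False
            for t_in, t_out in cortical_iv:
                if t_out >= inner - gap_tol and t_in < inner - gap_tol:
                    inner = t_in
                    changed = True
        thicknesses.append(outer - inner)
    if not thicknesses:
        raise MeasurementError("no cortical wall crossed on the anterior mid-shaft patch")
    return float(np.mean(thicknesses))


def _plane_hex_polygon_area(hex_coords: np.ndarray, signed: np.ndarray,
                            basis: tuple[np.ndarray, np.ndarray]) -> float:
    """Area of the intersection polygon of one hexahedron with the plane.

    ``signed`` are the vertex signed distances; intersection points are
    gathered on sign-changing edges (plus on-plane vertices), projected onto
    the in-plane ``basis`` and integrated with the shoelace formula after
    angular ordering (valid for convex sections).
    """
    pts = []
    eps = 1e-12
    for a, b in _HEX_EDGES:
        sa, sb = signed[a], signed[b]
        if sa * sb < 0:
            w = sa / (sa - sb)
            pts.append(hex_coords[a] + w * (hex_coords[b] - hex_coords[a]))
    on_plane = np.abs(signed) <= eps
    for v in hex_coords[on_plane]:
        pts.append(v)
    if len(pts) < 3:
        return 0.0
    P = np.array(pts)
    u, v = basis
    xy = np.column_stack([P @ u, P @ v])
    # dedupe near-coincident points
    order = np.lexsort((xy[:, 1], xy[:, 0]))
    xy = xy[order]
    keep = np.ones(len(xy), dtype=bool)
    for i in range(1, len(xy)):
        if np.linalg.norm(xy[i] - xy[i - 1]) < 1e-9:
            keep[i] = False
    xy = xy[keep]
    if len(xy) < 3:
        return 0.0
    c = xy.mean(axis=0)
    ang = np.arctan2(xy[:, 1] - c[1], xy[:, 0] - c[0])
    xy = xy[np.argsort(ang)]
    x, y = xy[:, 0], xy[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def midshaft_cortical_area(mesh: HexMesh, tissue_class: np.ndarray,
                           landmarks: AxisLandmarks | None = None,
                           plane_point: np.ndarray | None = None,
                           plane_normal: np.ndarray | None = None) -> float:
    """Cortical cross-section area (mm^2) at the femoral mid-length plane.

    The plane defaults to the midpoint of the femur-length measure along the
    first principal axis of all nodes, oriented perpendicular to that axis;
    an explicit ``plane_point``/``plane_normal`` overrides it.
    """
    if plane_point is None or plane_normal is None:
        if landmarks is None:
            raise ValueError("either landmarks or an explicit plane is required")
        landmarks.validate(mesh.n_nodes)
        axis = _principal_direction(mesh.nodes)
        c0 = mesh.nodes.mean(axis=0)
        t_head = axis @ (mesh.nodes[landmarks.head].mean(axis=0) - c0)
        t_dist = axis @ (mesh.nodes[landmarks.distal].mean(axis=0) - c0)
        plane_point = c0 + 0.5 * (t_head + t_dist) * axis
        plane_normal = axis
    normal = np.asarray(plane_normal, dtype=np.float64)
    normal = normal / np.linalg.norm(normal)
    point = np.asarray(plane_point, dtype=np.float64)
    # in-plane orthonormal basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)

    signed_all = (mesh.nodes - point) @ normal
    elem_signed = signed_all[mesh.elements]  # (m, 8)
    straddles = (elem_signed.min(axis=1) <= 0) & (elem_signed.max(axis=1) >= 0)
    if not np.any(straddles):
        raise MeasurementError("cross-section plane misses the mesh")
    cortical = tissue_class == CORTICAL
    which = np.nonzero(straddles & cortical)[0]
    if which.size == 0:
        raise MeasurementError("no cortical elements intersect the cross-section plane")
    total = 0.0
    for e in which:
        total += _plane_hex_polygon_area(mesh.nodes[mesh.elements[e]], elem_signed[e], (u, v))
    return float(total)


@dataclass(frozen=True)
class Trendline:
    """Simple linear regression y = k x + b with a two-sided zero-slope test."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    stderr: float
    significance_threshold: float = 0.01

    @property
    def significant(self) -> bool:
        return self.p_value < self.significance_threshold


def fit_trendline(x, y, significance_threshold: float = 0.01) -> Trendline:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a trendline")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; trendline undefined")
    if np.ptp(y) == 0:
        # Degenerate but well-defined: flat line, no explanatory power.
        return Trendline(0.0, float(y[0]), 0.0, 1.0, int(x.size), 0.0,
                         significance_threshold)
    res = stats.linregress(x, y)
    return Trendline(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), p_value=float(res.pvalue),
        n=int(x.size), stderr=float(res.stderr),
        significance_threshold=significance_threshold,
    )


def measure_sample(mesh: HexMesh, tissue_class: np.ndarray,
                   landmarks: AxisLandmarks) -> MorphometricsRecord:
    """All four morphometrics of one corresponded femur."""
    return MorphometricsRecord(
        femur_length=femur_length(mesh, landmarks),
        ccd_angle=ccd_angle(mesh, landmarks),
        anterior_midshaft_cortical_thickness=anterior_midshaft_cortical_thickness(
            mesh, tissue_class, landmarks),
        midshaft_cortical_area=midshaft_cortical_area(mesh, tissue_class, landmarks),
    )
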