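"""3D-model measurements on a simulated neck osteotomy plane: AM-3D and AT-3D.

The simulated osteotomy plane passes through the center of the piriformis
fossa and the calcar point at the 5/10 mm cutting height above the lesser
trochanter apex; as the package's convention it additionally contains the AP
direction, so the cut is anterior–posterior symmetric.  On that oblique cut:

* the 3D *midcortical line* connects the centers of circles fitted to the
  contour arcs at the two ends of the cut — the inferomedial (calcar) margin
  and the superolateral (piriformis) margin;
* *IMI* is the intersection of the midcortical line with the inferior margin
  of the contour;
* the *T-line* connects the trochanteric fossa to IMI.

AM-3D and AT-3D are the signed axial angles of the midcortical line and the
T-line against the posterior condylar axis.

In-plane coordinates: because the plane contains AP, its in-plane axes are
forced to v = normalized projection of +SI (in-plane superior, so the calcar
corner is the -v extreme) and u = v x normal (= +AP).  The contour is stored
counter-clockwise in (u, v).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from shapely.geometry import Polygon

from .anatomy import AnatomicalFrame, Axis3D, LandmarkSet, axial_projected_angle, posterior_condylar_axis
from .exceptions import DegenerateGeometryError, FitError, MeasurementError
from .sections import AnteversionMeasure, _ensure_ccw, _mesh_plane_loops, _signed_area, extract_cross_section

__all__ = [
    "OsteotomyPlane",
    "PlanarContour",
    "MarginCircle",
    "build_osteotomy_plane",
    "plane_contour",
    "circle_fit",
    "fit_margin_circle",
    "midcortical_line_3d",
    "am_3d",
    "imi_point",
    "at_3d",
]

#: angular window (degrees, about the contour centroid) of a margin arc
MARGIN_ARC_WINDOW_DEG = 60.0
#: minimum number of points in a margin arc
MIN_MARGIN_POINTS = 5
#: circle centers closer than this are a degenerate midline (mm)
MIN_CENTER_SEPARATION_MM = 1.0


@dataclass(frozen=True)
class OsteotomyPlane:
    """The simulated neck-cut plane with its defining construction."""

    point: np.ndarray
    normal: np.ndarray
    construction: dict
    frame_ref: AnatomicalFrame

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))
        n = np.asarray(self.normal, dtype=float).reshape(3)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            raise DegenerateGeometryError("osteotomy plane normal is degenerate")
        n = n / nn
        object.__setattr__(self, "normal", n)
        for key in ("piriformis_center", "calcar_point"):
            p = np.asarray(self.construction[key], dtype=float)
            if abs(float((p - self.point) @ n)) > 1e-9:
                raise DegenerateGeometryError(f"{key} does not lie on the osteotomy plane")

    def distance(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal


@dataclass(frozen=True)
class PlanarContour:
    """Closed contour of the osteotomy cut with in-plane (u, v) coordinates."""

    points3d: np.ndarray
    uv: np.ndarray
    plane_ref: OsteotomyPlane
    u_axis: np.ndarray
    v_axis: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points3d, dtype=float)
        uv = np.asarray(self.uv, dtype=float)
        if len(pts) != len(uv) or len(pts) < 16:
            raise MeasurementError("contour needs >= 16 matched 3D/uv points", stage="plane_contour")
        if np.max(np.abs(self.plane_ref.distance(pts))) > 1e-6:
            raise MeasurementError("contour points do not lie on the plane", stage="plane_contour")
        poly = Polygon(uv)
        if not poly.is_valid or not poly.is_simple:
            raise MeasurementError("contour self-intersects", stage="plane_contour")
        object.__setattr__(self, "points3d", pts)
        object.__setattr__(self, "uv", uv)

    @property
    def area(self) -> float:
        return _signed_area(self.uv)

    def point3d(self, uv) -> np.ndarray:
        return self.plane_ref.point + float(uv[0]) * self.u_axis + float(uv[1]) * self.v_axis


@dataclass(frozen=True)
class MarginCircle:
    """Least-squares circle fitted to one margin arc of the cut contour."""

    center_uv: np.ndarray
    radius: float
    arc_indices: np.ndarray
    rms_residual: float

    def __post_init__(self):
        object.__setattr__(self, "center_uv", np.asarray(self.center_uv, dtype=float).reshape(2))
        object.__setattr__(self, "arc_indices", np.asarray(self.arc_indices, dtype=int))
        if self.radius <= 0 or self.rms_residual < 0:
            raise FitError("margin circle with non-positive radius or negative rms")


def build_osteotomy_plane(mesh, landmarks: LandmarkSet, frame: AnatomicalFrame, height_mm: float) -> OsteotomyPlane:
    """Construct the simulated osteotomy plane at the given cutting height.

    The plane contains the piriformis fossa center and the calcar point (the
    most medial point of the axial cross-section at ``height_mm``), and
    contains the AP direction; its normal points proximally.
    """
    cs = extract_cross_section(mesh, frame, landmarks, height_mm)
    idx = int(np.argmax(cs.outer_contour[:, 0]))
    calcar = cs.point3d(cs.outer_contour[idx])
    pf = landmarks.piriformis_fossa_center
    d = pf - calcar
    if np.linalg.norm(d) < 1e-9:
        raise DegenerateGeometryError("piriformis center coincides with the calcar point")
    n = np.cross(frame.ap_axis, d)
    if np.linalg.norm(n) < 1e-9:
        raise DegenerateGeometryError("plane degenerate: piriformis-calcar line parallel to AP")
    n = n / np.linalg.norm(n)
    si_comp = float(n @ frame.si_axis)
    if abs(si_comp) > 1e-12:
        n = n if si_comp > 0 else -n
    elif float(n @ frame.ml_axis) < 0:  # vertical piriformis-calcar line: normal is +-ML
        n = -n
    return OsteotomyPlane(
        point=pf,
        normal=n,
        construction={"piriformis_center": pf, "calcar_point": calcar, "height_mm": float(height_mm)},
        frame_ref=frame,
    )


def plane_contour(mesh, plane: OsteotomyPlane) -> PlanarContour:
    """Intersect the mesh with the osteotomy plane and return the cut contour.

    The largest-area closed loop is kept, expressed in (u, v) in-plane
    coordinates with counter-clockwise orientation.
    """
    frame = plane.frame_ref
    si_in_plane = frame.si_axis - float(frame.si_axis @ plane.normal) * plane.normal
    if np.linalg.norm(si_in_plane) < 1e-9:
        raise DegenerateGeometryError("osteotomy plane is axial: in-plane superior undefined")
    v = si_in_plane / np.linalg.norm(si_in_plane)
    u = np.cross(v, plane.normal)
    loops = _mesh_plane_loops(mesh, plane.point, plane.normal)
    if not loops:
        raise MeasurementError("osteotomy plane does not intersect the mesh", stage="plane_contour")
    uv_loops = []
    for pts, closed in loops:
        if not closed:
            raise MeasurementError("open intersection with osteotomy plane", stage="plane_contour")
        rel = pts - plane.point
        uv_loops.append((pts, np.column_stack([rel @ u, rel @ v])))
    pts, uv = max(uv_loops, key=lambda t: abs(_signed_area(t[1])))
    if _signed_area(uv) < 0:
        pts, uv = pts[::-1], uv[::-1]
    return PlanarContour(points3d=pts, uv=uv, plane_ref=plane, u_axis=u, v_axis=v)


def circle_fit(points) -> tuple[np.ndarray, float, float]:
    """Least-squares circle through 2D points: Kåsa start, geometric refinement.

    Returns (center, radius, rms radial residual).  Three non-collinear
    points give their exact circumscribed circle.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise FitError("circle fit needs >= 3 2D points")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise FitError("points are collinear: no circle")
    # Kåsa: minimize ||x^2+y^2 - 2ax - 2by - c||
    A = np.column_stack([2 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:2]

    def residuals(c):
        d = np.linalg.norm(pts - c, axis=1)
        return d - d.mean()

    if len(pts) > 3:
        center = least_squares(residuals, center, method="lm").x
    d = np.linalg.norm(pts - center, axis=1)
    radius = float(d.mean())
    rms = float(np.sqrt(np.mean((d - radius) ** 2)))
    return np.asarray(center), radius, rms


_MARGIN_DIRECTIONS = {
    # the calcar corner of the cut (inferomedial) is the -v extreme
    "medial": np.array([0.0, -1.0]),
    "inferior": np.array([0.0, -1.0]),
    # the piriformis corner (superolateral) is the +v extreme
    "superior": np.array([0.0, 1.0]),
    "lateral": np.array([0.0, 1.0]),
}


def fit_margin_circle(
    contour: PlanarContour,
    margin: str,
    window_deg: float = MARGIN_ARC_WINDOW_DEG,
    min_points: int = MIN_MARGIN_POINTS,
) -> MarginCircle:
    """Fit the best circle to one margin arc of the cut contour.

    The arc is the contiguous run of contour points inside a ``window_deg``
    angular window (about the contour centroid) centered on the contour's
    extreme point in the margin direction.
    """
    try:
        direction = _MARGIN_DIRECTIONS[margin]
    except KeyError:
        raise ValueError(f"margin must be one of {sorted(_MARGIN_DIRECTIONS)}, got {margin!r}")
    uv = contour.uv
    centroid = uv.mean(axis=0)
    rel = uv - centroid
    angles = np.arctan2(rel[:, 1], rel[:, 0])
    ext = int(np.argmax(uv @ direction))
    delta = np.degrees(np.angle(np.exp(1j * (angles - angles[ext]))))
    mask = np.abs(delta) <= window_deg / 2.0
    # contiguous circular run containing the extreme point
    n = len(uv)
    run = [ext]
    i = (ext + 1) % n
    while mask[i] and i != ext:
        run.append(i)
        i = (i + 1) % n
    i = (ext - 1) % n
    while mask[i] and i != ext and i not in run:
        run.insert(0, i)
        i = (i - 1) % n
    idx = np.asarray(run, dtype=int)
    if len(idx) < min_points:
        raise MeasurementError(
            f"{margin} margin arc shorter than {min_points} points", stage="fit_margin_circle"
        )
    try:
        center, radius, rms = circle_fit(uv[idx])
    except FitError as err:
        raise MeasurementError(str(err), stage="fit_margin_circle") from err
    return MarginCircle(center_uv=center, radius=radius, arc_indices=idx, rms_residual=rms)


def midcortical_line_3d(contour: PlanarContour) -> Axis3D:
    """The 3D midcortical line of the cut: through both margin-circle centers.

    Connects the superolateral (piriformis) margin circle center to the
    inferomedial (calcar) one, i.e. oriented lateral -> medial along the cut
    like the condylar reference axis.
    """
    c_med = contour.point3d(fit_margin_circle(contour, "medial").center_uv)
    c_sup = contour.point3d(fit_margin_circle(contour, "superior").center_uv)
    if np.linalg.norm(c_med - c_sup) < MIN_CENTER_SEPARATION_MM:
        raise DegenerateGeometryError("margin circle centers coincide: degenerate midline")
    return Axis3D(point=c_sup, direction=c_med - c_sup)


def am_3d(mesh, landmarks: LandmarkSet, frame: AnatomicalFrame, height_mm: float, meta: dict | None = None) -> AnteversionMeasure:
    """Anteversion of the 3D midcortical line on the osteotomy plane (AM-3D)."""
    plane = build_osteotomy_plane(mesh, landmarks, frame, height_mm)
    contour = plane_contour(mesh, plane)
    midline = midcortical_line_3d(contour)
    pca = posterior_condylar_axis(landmarks)
    angle = axial_projected_angle(midline.direction, pca, frame)
    return AnteversionMeasure(
        method="AM-3D", angle_deg=angle, height_mm=float(height_mm), meta=dict(meta or {})
    )


def imi_point(contour: PlanarContour, midline3d: Axis3D) -> np.ndarray:
    """Intersection of the midcortical line with the inferior contour margin.

    Of the (generically two) line-contour crossings the one with smaller v
    (inferior) is returned; exact v-ties resolve to larger u.
    """
    plane = contour.plane_ref
    p0 = np.array(
        [
            float((midline3d.point - plane.point) @ contour.u_axis),
            float((midline3d.point - plane.point) @ contour.v_axis),
        ]
    )
    d = np.array([float(midline3d.direction @ contour.u_axis), float(midline3d.direction @ contour.v_axis)])
    if np.linalg.norm(d) < 1e-9:
        raise MeasurementError("midline is perpendicular to the plane", stage="imi_point")
    d = d / np.linalg.norm(d)
    uv = contour.uv
    nxt = np.roll(uv, -1, axis=0)
    hits = []
    for a, b in zip(uv, nxt):
        e = b - a
        denom = d[0] * e[1] - d[1] * e[0]
        if abs(denom) < 1e-14:
            continue
        # a + s e = p0 + t d  ->  s = cross(a - p0, d) / cross(d, e)
        s = ((a[0] - p0[0]) * d[1] - (a[1] - p0[1]) * d[0]) / denom
        if -1e-12 <= s <= 1 + 1e-12:
            hits.append(a + np.clip(s, 0.0, 1.0) * e)
    if not hits:
        raise MeasurementError("midline does not cross the contour", stage="imi_point")
    hits = np.asarray(hits)
    v_min = hits[:, 1].min()
    cand = hits[hits[:, 1] <= v_min + 1e-9]
    best = cand[int(np.argmax(cand[:, 0]))]
    return contour.point3d(best)


def at_3d(mesh, landmarks: LandmarkSet, frame: AnatomicalFrame, height_mm: float, meta: dict | None = None) -> AnteversionMeasure:
    """Anteversion of the T-line (trochanteric fossa to IMI) — AT-3D."""
    plane = build_osteotomy_plane(mesh, landmarks, frame, height_mm)
    contour = plane_contour(mesh, plane)
    midline = midcortical_line_3d(contour)
    imi = imi_point(contour, midline)
    d = imi - landmarks.trochanteric_fossa  # lateral fossa -> medial IMI
    if np.linalg.norm(d) < 1e-9:
        raise DegenerateGeometryError("trochanteric fossa coincides with IMI")
    pca = posterior_condylar_axis(landmarks)
    angle = axial_projected_angle(d, pca, frame)
    return AnteversionMeasure(
        method="AT-3D", angle_deg=angle, height_mm=float(height_mm), meta=dict(meta or {})
    )
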