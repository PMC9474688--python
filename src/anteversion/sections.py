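"""CT-style axial slice measurements: AM-CT and PSA.

The clinical procedure these functions reproduce selects an axial plane 5 or
10 mm proximal to the apex of the lesser trochanter, traces the anterior and
posterior cortical boundaries of the femoral section, fits a line to each,
and takes their angular bisector (the *midcortical line*).  AM-CT is the
signed axial angle between that bisector and the posterior condylar axis;
PSA is the same angle measured for the implanted stem's neck axis.

Sections can be taken either directly from a surface mesh (mesh–plane
intersection) or from a binary pseudo-CT volume (marching-squares
iso-contour of the selected slice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely
from shapely.geometry import Polygon

from .anatomy import AnatomicalFrame, Axis3D, LandmarkSet, axial_projected_angle, posterior_condylar_axis
from .exceptions import FitError, MeasurementError

__all__ = [
    "CrossSection",
    "Line2D",
    "AnteversionMeasure",
    "VoxelGrid",
    "extract_cross_section",
    "slice_from_image",
    "classify_cortex_arcs",
    "fit_cortex_line",
    "midcortical_line",
    "am_ct",
    "psa_from_stem",
]

#: half-width (degrees) of the outward-normal window that classifies a
#: contour point as anterior/posterior cortex
CORTEX_ARC_WINDOW_DEG = 40.0
#: minimum number of contour points per cortex arc
MIN_ARC_POINTS = 5
#: minimum principal-axis ratio for a cortex-line fit to be well conditioned
MIN_AXIS_RATIO = 1.05


def _signed_area(loop: np.ndarray) -> float:
    x, y = loop[:, 0], loop[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _ensure_ccw(loop: np.ndarray) -> np.ndarray:
    return loop if _signed_area(loop) > 0 else loop[::-1]


@dataclass(frozen=True)
class Line2D:
    """A 2D line: anchor point and unit direction (mm)."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(2))
        d = np.asarray(self.direction, dtype=float).reshape(2)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise FitError("line direction is near-zero")
        object.__setattr__(self, "direction", d / n)


@dataclass(frozen=True)
class CrossSection:
    """A closed axial contour of the femur at a given height above the LT apex.

    ``outer_contour`` is an ordered counter-clockwise loop in axial
    coordinates (x = ML, y = AP, mm, relative to the slice plane's anchor
    point); the closing edge back to the first point is implied.
    """

    height_mm: float
    outer_contour: np.ndarray
    frame_ref: AnatomicalFrame
    plane_origin: np.ndarray
    inner_contour: Optional[np.ndarray] = None

    def __post_init__(self):
        loop = np.asarray(self.outer_contour, dtype=float)
        if loop.ndim != 2 or loop.shape[1] != 2 or loop.shape[0] < 16:
            raise MeasurementError(
                "outer contour must be an (n>=16, 2) point loop", stage="cross_section"
            )
        loop = _ensure_ccw(loop)
        poly = Polygon(loop)
        if not poly.is_valid or not poly.is_simple:
            raise MeasurementError("outer contour self-intersects", stage="cross_section")
        object.__setattr__(self, "outer_contour", loop)
        object.__setattr__(self, "plane_origin", np.asarray(self.plane_origin, dtype=float).reshape(3))
        if self.inner_contour is not None:
            inner = _ensure_ccw(np.asarray(self.inner_contour, dtype=float))
            if not poly.contains(Polygon(inner)):
                raise MeasurementError(
                    "inner contour not strictly inside outer contour", stage="cross_section"
                )
            object.__setattr__(self, "inner_contour", inner)

    @property
    def area(self) -> float:
        return _signed_area(self.outer_contour)

    def point3d(self, uv) -> np.ndarray:
        """Lift an axial (ML, AP) coordinate back to 3D world space."""
        return self.plane_origin + self.frame_ref.from_axial(uv)


@dataclass(frozen=True)
class AnteversionMeasure:
    """One anteversion angle: method tag, slice height, signed degrees."""

    method: str
    angle_deg: float
    height_mm: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (-180.0 < self.angle_deg <= 180.0):
            raise MeasurementError("angle out of (-180, 180]", stage="measure")
        if self.method in ("AM-CT", "AM-3D", "AT-3D") and self.height_mm is None:
            raise MeasurementError(f"{self.method} requires a height", stage="measure")


@dataclass(frozen=True)
class VoxelGrid:
    """A binary occupancy grid with mm spacing, axes aligned to the frame.

    World position of voxel (i, j, k) center is ``origin + (i, j, k) * spacing``
    with the grid axes parallel to (ML, AP, SI) of the anatomical frame.
    """

    data: np.ndarray
    spacing: tuple
    origin: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))


def _mesh_plane_loops(mesh, plane_origin, plane_normal):
    """Closed 3D loops of a mesh-plane intersection (trimesh section)."""
    section = mesh.section(plane_origin=plane_origin, plane_normal=plane_normal)
    if section is None:
        return []
    loops = []
    for disc in section.discrete:
        pts = np.asarray(disc, dtype=float)
        if len(pts) < 3:
            continue
        closed = np.allclose(pts[0], pts[-1], atol=1e-8)
        if closed:
            pts = pts[:-1]
        loops.append((pts, closed))
    return loops


def extract_cross_section(mesh, frame: AnatomicalFrame, landmarks: LandmarkSet, height_mm: float) -> CrossSection:
    """Slice the femur mesh with the axial plane ``height_mm`` above the LT apex.

    The plane is anchored at ``lesser_trochanter_apex + height_mm * SI`` with
    normal SI.  If the intersection has several closed loops (e.g. a partially
    attached lesser trochanter) the largest-area loop is taken as the femoral
    section and the rest are ignored with a warning.
    """
    origin = landmarks.lesser_trochanter_apex + height_mm * frame.si_axis
    loops = _mesh_plane_loops(mesh, origin, frame.si_axis)
    if not loops:
        raise MeasurementError(
            f"axial plane at height {height_mm} mm misses the mesh", stage="extract_cross_section"
        )
    closed_uv = []
    for pts, closed in loops:
        if not closed:
            raise MeasurementError(
                "open (non-manifold) mesh-plane intersection", stage="extract_cross_section"
            )
        uv = np.column_stack([(pts - origin) @ frame.ml_axis, (pts - origin) @ frame.ap_axis])
        closed_uv.append(uv)
    areas = [abs(_signed_area(uv)) for uv in closed_uv]
    if len(closed_uv) > 1:
        warnings.warn(
            f"{len(closed_uv)} loops in axial section; keeping largest-area loop", stacklevel=2
        )
    outer = closed_uv[int(np.argmax(areas))]
    return CrossSection(height_mm=height_mm, outer_contour=outer, frame_ref=frame, plane_origin=origin)


def slice_from_image(
    image: VoxelGrid,
    frame: AnatomicalFrame,
    landmarks: LandmarkSet,
    height_mm: float,
    smooth_sigma: float = 1.0,
) -> CrossSection:
    """Extract the bone contour from the binary volume slice nearest the plane.

    The slice is binarized, lightly Gaussian-smoothed (``smooth_sigma`` in
    voxels, for a sub-voxel boundary estimate), padded, and the 0.5-level
    iso-contour extracted with marching squares; pixel coordinates are
    converted to mm in the axial (ML, AP) frame relative to the plane anchor.
    """
    from scipy.ndimage import gaussian_filter
    from skimage import measure

    origin3 = landmarks.lesser_trochanter_apex + height_mm * frame.si_axis
    z_target = float((origin3 - image.origin) @ frame.si_axis)
    k = int(round(z_target / image.spacing[2]))
    if k < 0 or k >= image.data.shape[2]:
        raise MeasurementError("slice height outside the image grid", stage="slice_from_image")
    sl = image.data[:, :, k].astype(float)
    if not np.any(sl > 0.5):
        raise MeasurementError("empty slice: no bone voxels", stage="slice_from_image")
    if smooth_sigma > 0:
        sl = gaussian_filter(sl, smooth_sigma)
    padded = np.pad(sl, 1)
    contours = measure.find_contours(padded, 0.5)
    closed = [c for c in contours if np.allclose(c[0], c[-1])]
    if not closed:
        raise MeasurementError("no closed iso-contour in slice", stage="slice_from_image")
    best = max(closed, key=lambda c: abs(_signed_area(c)))
    ij = best[:-1] - 1.0  # unpad; (i, j) float pixel coords
    ml_mm = image.origin @ frame.ml_axis + ij[:, 0] * image.spacing[0]
    ap_mm = image.origin @ frame.ap_axis + ij[:, 1] * image.spacing[1]
    uv = np.column_stack([ml_mm - origin3 @ frame.ml_axis, ap_mm - origin3 @ frame.ap_axis])
    return CrossSection(height_mm=height_mm, outer_contour=uv, frame_ref=frame, plane_origin=origin3)


def _outward_normals(loop: np.ndarray) -> np.ndarray:
    """Per-vertex outward unit normals of a CCW loop."""
    nxt = np.roll(loop, -1, axis=0)
    edges = nxt - loop
    edge_n = np.column_stack([edges[:, 1], -edges[:, 0]])  # CCW -> outward
    norms = np.linalg.norm(edge_n, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    edge_n = edge_n / norms
    vert_n = edge_n + np.roll(edge_n, 1, axis=0)
    vn = np.linalg.norm(vert_n, axis=1, keepdims=True)
    vn[vn == 0] = 1.0
    return vert_n / vn


def _longest_circular_run(mask: np.ndarray) -> np.ndarray:
    """Indices of the longest contiguous circular True run."""
    n = len(mask)
    if mask.all():
        return np.arange(n)
    if not mask.any():
        return np.array([], dtype=int)
    ext = np.concatenate([mask, mask])
    best_start, best_len, cur_start, cur_len = 0, 0, None, 0
    for i, m in enumerate(ext):
        if m:
            if cur_start is None:
                cur_start, cur_len = i, 1
            else:
                cur_len += 1
        else:
            if cur_start is not None and cur_len > best_len:
                best_start, best_len = cur_start, cur_len
            cur_start, cur_len = None, 0
    if cur_start is not None and cur_len > best_len:
        best_start, best_len = cur_start, cur_len
    best_len = min(best_len, n)
    return np.arange(best_start, best_start + best_len) % n


def classify_cortex_arcs(
    cs: CrossSection,
    window_deg: float = CORTEX_ARC_WINDOW_DEG,
    min_points: int = MIN_ARC_POINTS,
    reference: str = "auto",
):
    """Split the outer contour into anterior and posterior cortex point runs.

    A point belongs to the anterior (posterior) cortex when its outward
    normal lies within ``window_deg`` of the anterior (posterior) reference
    direction; the longest contiguous run on each side is returned.

    With ``reference='auto'`` (default) the reference is the normal of the
    contour's own principal axis, oriented toward +AP — this follows the
    oblique cortical walls of a strongly anteverted neck the way manual
    tracing does, and coincides with ±AP for a section whose long axis is
    mediolateral.  Near-isotropic contours (principal-axis ratio < 1.05) and
    ``reference='ap'`` use ±AP directly.
    """
    loop = cs.outer_contour
    normals = _outward_normals(loop)
    ant_ref = np.array([0.0, 1.0])
    if reference == "auto":
        centered = loop - loop.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[1] > 0 and s[0] / s[1] >= MIN_AXIS_RATIO:
            perp = np.array([-vt[0, 1], vt[0, 0]])
            ant_ref = perp if perp[1] >= 0 else -perp
    elif reference != "ap":
        raise ValueError("reference must be 'auto' or 'ap'")
    cos_win = np.cos(np.radians(window_deg))
    out = []
    for sign, label in ((1.0, "anterior"), (-1.0, "posterior")):
        mask = normals @ (sign * ant_ref) >= cos_win
        run = _longest_circular_run(mask)
        if len(run) < min_points:
            raise MeasurementError(
                f"fewer than {min_points} {label} cortex points", stage="classify_cortex_arcs"
            )
        out.append(loop[run])
    return tuple(out)


def fit_cortex_line(points: np.ndarray, min_axis_ratio: float = MIN_AXIS_RATIO) -> Line2D:
    """Total-least-squares line through a 2D point set.

    The direction is the principal axis of the centered points (first right
    singular vector), anchored at the centroid and oriented with
    non-negative ML component.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < MIN_ARC_POINTS:
        raise FitError(f"need >= {MIN_ARC_POINTS} 2D points for a cortex line")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0):
        raise FitError("all points coincide")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] > 0 and s[0] / s[1] < min_axis_ratio:
        raise FitError(
            f"isotropic point set (principal-axis ratio {s[0] / s[1]:.3f} < {min_axis_ratio})"
        )
    d = vt[0]
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d
    return Line2D(point=centroid, direction=d)


def midcortical_line(anterior: Line2D, posterior: Line2D) -> Line2D:
    """Angular bisector of the anterior and posterior cortex lines.

    Directions are co-oriented, summed and normalized; the anchor is the
    midpoint of the two anchors.  For parallel inputs the bisector is the
    parallel midline.
    """
    d1 = anterior.direction
    d2 = posterior.direction if anterior.direction @ posterior.direction >= 0 else -posterior.direction
    return Line2D(point=0.5 * (anterior.point + posterior.point), direction=d1 + d2)


def am_ct(mesh, frame: AnatomicalFrame, landmarks: LandmarkSet, height_mm: float, meta: dict | None = None) -> AnteversionMeasure:
    """Anteversion of the midcortical line on the axial slice (AM-CT).

    Composition: extract the axial cross-section, classify anterior/posterior
    cortex arcs, fit a total-least-squares line to each, bisect, and measure
    the signed axial angle of the bisector against the posterior condylar
    axis.
    """
    if height_mm not in (5.0, 10.0, 5, 10):
        warnings.warn(
            f"AM-CT height {height_mm} mm is outside the conventional 5/10 mm levels",
            stacklevel=2,
        )
    cs = extract_cross_section(mesh, frame, landmarks, height_mm)
    anterior, posterior = classify_cortex_arcs(cs)
    try:
        la = fit_cortex_line(anterior)
        lp = fit_cortex_line(posterior)
    except FitError as err:
        raise MeasurementError(str(err), stage="fit_cortex_line") from err
    mid = midcortical_line(la, lp)
    pca = posterior_condylar_axis(landmarks)
    angle = axial_projected_angle(frame.from_axial(mid.direction), pca, frame)
    return AnteversionMeasure(
        method="AM-CT", angle_deg=angle, height_mm=float(height_mm), meta=dict(meta or {})
    )


def psa_from_stem(stem_neck_axis: Axis3D, frame: AnatomicalFrame, meta: dict | None = None) -> AnteversionMeasure:
    """Postoperative stem anteversion: stem neck axis vs the condylar axis.

    The reference is the frame's ML axis, which equals the axial-plane
    projection of the posterior condylar axis by construction of the frame.
    """
    angle = axial_projected_angle(stem_neck_axis.direction, frame.ml_axis, frame)
    return AnteversionMeasure(method="PSA", angle_deg=angle, height_mm=None, meta=dict(meta or {}))
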