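"""Femoral anatomical frame, posterior condylar axis and the signed axial angle.

Every anteversion measurement in this package reduces to one primitive: the
signed angle, in the axial (transverse) plane of an anatomical frame, between
the projection of a direction of interest and the projection of the posterior
condylar axis (PCA).  This module builds that frame from named landmarks,
canonicalizes left hips into the right-side convention, and provides the
angle primitive.

Conventions
-----------
* Landmarks are 3D points in millimetres, named as in :class:`LandmarkSet`.
* The frame is right-handed in the ordering (ML, AP, SI): SI points proximal
  (distal epicondyle midpoint -> femoral head centre), ML points medial
  (lateral -> medial posterior condyle, orthogonalized against SI), and
  AP = SI x ML points anterior.
* Anteversion is positive: a neck/stem axis whose medial end is tipped
  anteriorly yields a positive angle.  Left femurs are mirrored through the
  sagittal plane on load so the same sign convention applies to both sides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import DegenerateGeometryError, LandmarkError

__all__ = [
    "LandmarkSet",
    "AnatomicalFrame",
    "Axis3D",
    "canonicalize_side",
    "build_femoral_frame",
    "posterior_condylar_axis",
    "axial_projected_angle",
    "load_landmarks",
    "save_landmarks",
]

LANDMARK_NAMES = (
    "head_center",
    "lesser_trochanter_apex",
    "piriformis_fossa_center",
    "trochanteric_fossa",
    "post_condyle_medial",
    "post_condyle_lateral",
    "epicondyle_medial",
    "epicondyle_lateral",
)

_SIDES = ("left", "right")


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    return a


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"cannot normalize near-zero {what}")
    return v / n


@dataclass(frozen=True)
class LandmarkSet:
    """Named anatomical points (mm) of one femur plus its side tag."""

    head_center: np.ndarray
    lesser_trochanter_apex: np.ndarray
    piriformis_fossa_center: np.ndarray
    trochanteric_fossa: np.ndarray
    post_condyle_medial: np.ndarray
    post_condyle_lateral: np.ndarray
    epicondyle_medial: np.ndarray
    epicondyle_lateral: np.ndarray
    side: str = "right"

    def __post_init__(self):
        for name in LANDMARK_NAMES:
            object.__setattr__(self, name, _as_point(getattr(self, name)))
            if not np.all(np.isfinite(getattr(self, name))):
                raise LandmarkError(f"landmark {name!r} is not finite")
        if self.side not in _SIDES:
            raise LandmarkError(f"side must be one of {_SIDES}, got {self.side!r}")
        epi_mid = 0.5 * (self.epicondyle_medial + self.epicondyle_lateral)
        if np.linalg.norm(self.head_center - epi_mid) <= 1.0:
            raise LandmarkError("head_center coincides with epicondyle midpoint")
        if np.allclose(self.post_condyle_medial, self.post_condyle_lateral):
            raise LandmarkError("posterior condyle landmarks coincide")

    def points(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in LANDMARK_NAMES}

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn(point) -> point`` to every landmark."""
        return LandmarkSet(
            **{name: fn(getattr(self, name)) for name in LANDMARK_NAMES},
            side=self.side,
        )

    def to_dict(self) -> dict:
        d = {name: getattr(self, name).tolist() for name in LANDMARK_NAMES}
        d["side"] = self.side
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        missing = [n for n in LANDMARK_NAMES if n not in d]
        if missing:
            raise LandmarkError(f"missing landmarks: {missing}")
        if "side" not in d:
            raise LandmarkError("missing side tag")
        return cls(**{n: d[n] for n in LANDMARK_NAMES}, side=d["side"])


def load_landmarks(path) -> LandmarkSet:
    """Read a landmark JSON file (eight named [x,y,z] mm arrays plus side)."""
    with open(path) as fh:
        return LandmarkSet.from_dict(json.load(fh))


def save_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).write_text(json.dumps(landmarks.to_dict(), indent=1))


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal femoral frame (ML, AP, SI), origin in mm."""

    origin: np.ndarray
    si_axis: np.ndarray
    ap_axis: np.ndarray
    ml_axis: np.ndarray
    side: str = "right"

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_point(self.origin))
        for name in ("si_axis", "ap_axis", "ml_axis"):
            v = _as_point(getattr(self, name))
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise DegenerateGeometryError(f"{name} is not unit-norm")
            object.__setattr__(self, name, v)
        for a, b in (
            (self.si_axis, self.ap_axis),
            (self.si_axis, self.ml_axis),
            (self.ap_axis, self.ml_axis),
        ):
            if abs(float(a @ b)) > 1e-9:
                raise DegenerateGeometryError("frame axes are not orthogonal")
        if np.linalg.norm(np.cross(self.ml_axis, self.ap_axis) - self.si_axis) > 1e-9:
            raise DegenerateGeometryError("frame is not right-handed (ml x ap != si)")

    def axial_coords(self, v) -> np.ndarray:
        """Project a 3D vector into axial-plane coordinates (ML, AP)."""
        v = _as_point(v)
        return np.array([float(v @ self.ml_axis), float(v @ self.ap_axis)])

    def from_axial(self, uv) -> np.ndarray:
        """Lift 2D axial-plane components back to a 3D vector."""
        u, v = float(uv[0]), float(uv[1])
        return u * self.ml_axis + v * self.ap_axis


@dataclass(frozen=True)
class Axis3D:
    """A 3D line given by a point on it and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", _as_point(self.point))
        object.__setattr__(self, "direction", _unit(_as_point(self.direction), "axis direction"))


def canonicalize_side(landmarks: LandmarkSet, mesh=None):
    """Mirror a left hip into the right-side convention; right hips pass through.

    The mirror is a reflection through the sagittal plane x = 0 (the first
    coordinate is assumed to be the scanner left–right axis).  Landmark names
    stay attached to the same anatomical points, so a mirrored left femur is
    processed exactly like a geometric right femur and its anteversion carries
    the same sign.  Applying the function twice restores the input.

    Parameters
    ----------
    landmarks : LandmarkSet
    mesh : trimesh.Trimesh, optional
        Mirrored alongside the landmarks (face winding flipped to keep
        outward normals).

    Returns
    -------
    (LandmarkSet, mesh) with side == "right".
    """
    if landmarks.side not in _SIDES:  # pragma: no cover - guarded by dataclass
        raise LandmarkError("missing side tag")
    if landmarks.side == "right":
        return landmarks, mesh
    mirrored = landmarks.transformed(lambda p: p * np.array([-1.0, 1.0, 1.0]))
    mirrored = replace(mirrored, side="right")
    if mesh is not None:
        mesh = mesh.copy()
        mesh.vertices = mesh.vertices * np.array([-1.0, 1.0, 1.0])
        mesh.faces = mesh.faces[:, ::-1]
    return mirrored, mesh


def build_femoral_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Construct the femoral frame from canonicalized landmarks.

    SI runs from the epicondyle midpoint to the head centre; ML is the
    component of the lateral->medial posterior condylar direction orthogonal
    to SI; AP = SI x ML (anterior positive).  Origin is the head centre.

    Raises
    ------
    DegenerateGeometryError
        If the condylar line is within 0.5 degrees of SI.
    """
    epi_mid = 0.5 * (landmarks.epicondyle_medial + landmarks.epicondyle_lateral)
    si = _unit(landmarks.head_center - epi_mid, "SI axis")
    condylar = landmarks.post_condyle_medial - landmarks.post_condyle_lateral
    cond_dir = _unit(condylar, "condylar line")
    if abs(float(cond_dir @ si)) > np.cos(np.radians(0.5)):
        raise DegenerateGeometryError("condylar line is (near-)parallel to the SI axis")
    ml = _unit(condylar - (condylar @ si) * si, "ML axis")
    ap = np.cross(si, ml)
    return AnatomicalFrame(
        origin=landmarks.head_center, si_axis=si, ap_axis=ap, ml_axis=ml, side=landmarks.side
    )


def posterior_condylar_axis(landmarks: LandmarkSet) -> Axis3D:
    """The PCA: the line through the posterior condyles, oriented lateral->medial.

    Orientation comes from the landmark names, never from input order.
    """
    d = landmarks.post_condyle_medial - landmarks.post_condyle_lateral
    if np.linalg.norm(d) < 1e-9:
        raise DegenerateGeometryError("posterior condyle landmarks coincide")
    return Axis3D(point=landmarks.post_condyle_lateral, direction=d)


def axial_projected_angle(direction, reference: Axis3D | np.ndarray, frame: AnatomicalFrame) -> float:
    """Signed axial-plane angle (degrees) from ``reference`` to ``direction``.

    Both vectors are projected onto the plane perpendicular to the frame's SI
    axis; the returned angle is measured about +SI and lies in (-180, 180].
    With the right-side convention a medial axis tipped anteriorly (an
    anteverted neck or stem) gives a positive angle.

    Raises
    ------
    DegenerateGeometryError
        If either vector is (near-)parallel to SI so that its axial
        projection has norm <= 1e-6 of the vector norm.
    """
    d = _as_point(direction)
    r = reference.direction if isinstance(reference, Axis3D) else _as_point(reference)

    def _proj(v, name):
        p = v - (v @ frame.si_axis) * frame.si_axis
        if np.linalg.norm(p) <= 1e-6 * max(np.linalg.norm(v), 1e-30):
            raise DegenerateGeometryError(
                f"{name} is parallel to SI: axial projection is degenerate"
            )
        return p

    dp = _proj(d, "direction")
    rp = _proj(r, "reference")
    s = float(frame.si_axis @ np.cross(rp, dp))
    c = float(rp @ dp)
    ang = float(np.degrees(np.arctan2(s, c)))
    if ang <= -180.0:  # map (-180, 180]
        ang += 360.0
    return ang
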