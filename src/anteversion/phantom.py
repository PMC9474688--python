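"""Parametric proximal-femur phantoms with exact anteversion ground truth.

Real patient meshes are not available to this package, so everything the
measurement pipeline consumes is generated here: watertight femur surfaces
with a controllable neck anteversion (0°–60° covers the dysplastic range),
analytically placed landmarks, implanted-stem neck axes with known
anteversion, binary pseudo-CT volumes, and two kinds of virtual cohorts —
*geometric* (full meshes, measured end-to-end) and *statistical* (angle
tables drawn from the calibrated moment structure of the reference cohort).

Construction
------------
The femur is a single lofted surface: axial cross-sections stacked along the
SI axis, blending smoothly between a condylar block, a cylindrical shaft
that drifts laterally toward the hip, an elliptical neck whose section long
axis points along the anteversion azimuth, and a spherical head centered on
the SI axis.  Greater/lesser trochanter bosses are radial bumps; all
landmarks are evaluated analytically from the same radius function, so the
ground truth is exact by construction rather than annotated.

Because every supra-condylar section center and section orientation depends
on the anteversion azimuth only through a rotation about SI, two specs that
differ only in anteversion produce meshes whose proximal vertices are
related by exactly that rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import shapely
import trimesh
from shapely.geometry import Polygon

from .anatomy import Axis3D, LandmarkSet, build_femoral_frame, posterior_condylar_axis
from .exceptions import GenerationError
from .sections import VoxelGrid

__all__ = [
    "FemurSpec",
    "StemSpec",
    "VirtualSubject",
    "CohortSpec",
    "generate_femur",
    "generate_stem",
    "voxelize",
    "generate_geometric_cohort",
    "generate_statistical_cohort",
    "neck_canal_center",
]

# fixed shape constants of the phantom (mm / deg); see docs/methods.md
CONDYLE_HALF_WIDTH = 35.0  # ML semi-axis of the condylar block
CONDYLE_HALF_DEPTH = 27.0  # AP semi-axis of the condylar block
NECK_VERTICAL_EXTENT = 40.0  # SI span of the neck region below the head center
LT_BUMP_HEIGHT = 10.0
LT_BUMP_SPAN = 20.0
LT_WINDOW_DEG = 45.0
GT_BUMP_HEIGHT = 12.0
GT_BUMP_SPAN = 33.0
GT_WINDOW_DEG = 55.0
PF_AZIMUTH_DEG = 150.0  # piriformis fossa azimuth relative to the neck azimuth
PF_HEIGHT_ABOVE_APEX = 23.0
TF_AZIMUTH_DEG = -130.0  # trochanteric fossa base azimuth (posterolateral)
TF_HEIGHT_ABOVE_APEX = 20.0
CONDYLE_SINPHI = 0.7  # parametric offset of the posterior condyle landmarks


@dataclass(frozen=True)
class FemurSpec:
    """Parameters of one synthetic proximal femur.

    ``nfa_deg`` is the ground-truth native femoral anteversion: the axial
    angle of the neck azimuth relative to the posterior condylar axis.
    ``neck_radii`` are the axial-section semi-axes of the neck (along the
    neck azimuth, transverse), in mm.
    """

    nfa_deg: float = 15.0
    neck_shaft_angle_deg: float = 130.0
    head_radius: float = 22.0
    neck_radii: tuple = (16.0, 11.0)
    shaft_radius: float = 14.0
    cortical_thickness: float = 5.0
    lt_height_offset: float = 0.0
    fossa_posterior_offset: float = 3.0
    condylar_torsion_deg: float = 0.0
    lt_azimuth_deg: float = -45.0
    side: str = "right"
    mesh_resolution: int = 64
    femur_length: float = 400.0
    seed: int = 0

    def __post_init__(self):
        for name in ("head_radius", "shaft_radius", "cortical_thickness", "femur_length"):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be positive")
        if any(r <= 0 for r in self.neck_radii):
            raise GenerationError("neck_radii must be positive")
        if not (-30.0 <= self.nfa_deg <= 80.0):
            raise GenerationError("nfa_deg outside [-30, 80]")
        if self.mesh_resolution < 16:
            raise GenerationError("mesh_resolution must be >= 16 segments")
        if not (95.0 < self.neck_shaft_angle_deg < 175.0):
            raise GenerationError("neck_shaft_angle_deg outside the buildable range")
        if self.side not in ("left", "right"):
            raise GenerationError("side must be 'left' or 'right'")


@dataclass(frozen=True)
class StemSpec:
    """Implanted stem: ground-truth anteversion, neck length and inclination."""

    stem_anteversion_deg: float = 15.0
    neck_length: float = 35.0
    neck_inclination_deg: float = 40.0

    def __post_init__(self):
        vals = (self.stem_anteversion_deg, self.neck_length, self.neck_inclination_deg)
        if not all(np.isfinite(vals)):
            raise GenerationError("stem parameters must be finite")
        if not (-180.0 < self.stem_anteversion_deg <= 180.0):
            raise GenerationError("stem anteversion outside (-180, 180]")


@dataclass(frozen=True)
class VirtualSubject:
    """One simulated hip: specs, mesh, landmarks, stem axis and ground truth."""

    femur_spec: FemurSpec
    stem_spec: StemSpec
    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    stem_neck_axis: Axis3D
    truth: dict


@dataclass(frozen=True)
class CohortSpec:
    """Virtual cohort parameters (defaults mirror the reference cohort)."""

    n: int = 28
    psa_mean: float = 29.8
    psa_sd: float = 17.7
    methods: dict = field(default_factory=dict)  # key -> {mean, sd, r}
    mode: str = "statistical"
    seed: int = 0
    stem_noise_sd: float = 5.0
    nfa_bounds: tuple = (-10.0, 70.0)

    def __post_init__(self):
        if self.n < 3:
            raise GenerationError("cohort needs n >= 3")
        if self.psa_sd <= 0 or self.stem_noise_sd < 0:
            raise GenerationError("cohort SDs must be positive")
        for key, cell in self.methods.items():
            if cell["sd"] <= 0:
                raise GenerationError(f"{key}: sd must be positive")
            if abs(cell["r"]) > 1:
                raise GenerationError(f"{key}: |r| > 1 implies a non-PSD covariance")
        if self.mode not in ("geometric", "statistical"):
            raise GenerationError("mode must be 'geometric' or 'statistical'")


def _smoothstep(z, z0, z1):
    t = np.clip((z - z0) / (z1 - z0), 0.0, 1.0)
    return 3 * t**2 - 2 * t**3


def _ellipse_radius(theta, a, b, phi):
    """Radius of an origin-centered ellipse (semi-axes a along phi, b across)."""
    c = np.cos(theta - phi)
    s = np.sin(theta - phi)
    return a * b / np.sqrt((b * c) ** 2 + (a * s) ** 2)


class _FemurGeometry:
    """Analytic section model of one femur spec (right-side canonical)."""

    def __init__(self, spec: FemurSpec):
        self.spec = spec
        self.z_head = spec.femur_length
        self.nu = np.radians(spec.nfa_deg + spec.condylar_torsion_deg)
        self.tau = np.radians(spec.condylar_torsion_deg)
        self.m = np.array([np.cos(self.nu), np.sin(self.nu)])
        eps = np.radians(spec.neck_shaft_angle_deg - 90.0)
        self.cot_eps = 1.0 / np.tan(eps)
        self.z_neck_base = self.z_head - NECK_VERTICAL_EXTENT
        self.s_max = NECK_VERTICAL_EXTENT * self.cot_eps
        self.z_apex = self.z_head - 55.0 + spec.lt_height_offset
        # region transitions (mm)
        self.t_cond = (38.0, 55.0)
        self.t_neck = (self.z_apex - 10.0, self.z_apex + 13.0)
        self.t_head = (self.z_head - 20.0, self.z_head - 5.0)
        self.theta_lt = self.nu + np.radians(spec.lt_azimuth_deg)
        self.theta_gt = self.nu + np.pi

    # --- section centers -------------------------------------------------
    def center(self, z):
        """xy center of the axial section at height z (2-vector)."""
        t1 = _smoothstep(z, *self.t_cond)
        t2 = _smoothstep(z, *self.t_neck)
        t3 = _smoothstep(z, *self.t_head)
        drift = -self.s_max * np.clip((z - self.t_cond[1]) / (self.z_neck_base - self.t_cond[1]), 0.0, 1.0)
        neck = -self.cot_eps * min(self.z_head - z, NECK_VERTICAL_EXTENT)
        s = (1 - t2) * t1 * drift + t2 * (1 - t3) * neck  # head/condyle centers are 0
        return s * self.m

    # --- section radius ---------------------------------------------------
    def base_radius(self, theta, z):
        """Radius (without trochanter bumps) of the section at (theta, z)."""
        spec = self.spec
        t1 = _smoothstep(z, *self.t_cond)
        t2 = _smoothstep(z, *self.t_neck)
        t3 = _smoothstep(z, *self.t_head)
        w_cond = 1 - t1
        w_shaft = t1 * (1 - t2)
        w_neck = t2 * (1 - t3)
        w_head = t2 * t3
        r = 0.0
        if w_cond > 0:
            r += w_cond * _ellipse_radius(theta, CONDYLE_HALF_WIDTH, CONDYLE_HALF_DEPTH, self.tau)
        if w_shaft > 0:
            r += w_shaft * spec.shaft_radius
        if w_neck > 0:
            r += w_neck * _ellipse_radius(theta, spec.neck_radii[0], spec.neck_radii[1], self.nu)
        if w_head > 0:
            r += w_head * np.sqrt(max(spec.head_radius**2 - (z - self.z_head) ** 2, 0.25))
        return r

    def bump(self, theta, z):
        """Radial addition of the greater/lesser trochanter bosses."""
        out = 0.0
        z0 = self.z_apex - LT_BUMP_SPAN
        if z0 < z < self.z_apex:
            delta = np.degrees(np.angle(np.exp(1j * (theta - self.theta_lt))))
            if abs(delta) < LT_WINDOW_DEG:
                amp = LT_BUMP_HEIGHT * np.sin(np.pi * (z - z0) / LT_BUMP_SPAN) ** 2
                out += amp * np.cos(np.pi / 2 * delta / LT_WINDOW_DEG) ** 2
        if self.z_apex < z < self.z_apex + GT_BUMP_SPAN:
            delta = np.degrees(np.angle(np.exp(1j * (theta - self.theta_gt))))
            if abs(delta) < GT_WINDOW_DEG:
                amp = GT_BUMP_HEIGHT * np.sin(np.pi * (z - self.z_apex) / GT_BUMP_SPAN) ** 2
                out += amp * np.cos(np.pi / 2 * delta / GT_WINDOW_DEG) ** 2
        return out

    def radius(self, theta, z):
        return self.base_radius(theta, z) + self.bump(theta, z)

    def surface_point(self, theta, z):
        c = self.center(z)
        r = self.radius(theta, z)
        return np.array([c[0] + r * np.cos(theta), c[1] + r * np.sin(theta), z])

    # --- ring schedule ----------------------------------------------------
    def ring_levels(self):
        z_fine0 = self.z_apex - LT_BUMP_SPAN - 1.0
        levels = np.concatenate(
            [
                np.arange(-24.0, 30.0, 6.0),
                np.arange(30.0, 55.0, 4.0),
                np.arange(55.0, 320.0, 15.0),
                np.arange(320.0, z_fine0, 4.0),
                np.arange(z_fine0, self.t_head[1] + 1.0, 1.5),
                np.arange(self.t_head[1] + 1.5, self.z_head + 0.985 * self.spec.head_radius, 2.0),
            ]
        )
        return np.unique(np.round(levels, 6))


def generate_femur(spec: FemurSpec):
    """Build the femur mesh, its landmark set and the ground-truth record.

    Returns ``(mesh, landmarks, truth)`` where ``truth`` holds the exact
    anteversion (``nfa_deg``), the neck azimuth, and the LT apex height used
    by the measurement planes.  Deterministic for a given spec.
    """
    geo = _FemurGeometry(spec)
    n_theta = int(spec.mesh_resolution)
    # ring sampling rotates with the neck azimuth, so femurs differing only in
    # anteversion have proximal vertices related by exactly that rotation
    thetas = geo.nu + 2 * np.pi * np.arange(n_theta) / n_theta
    levels = geo.ring_levels()

    verts = []
    for z in levels:
        c = geo.center(z)
        r = np.array([geo.radius(t, z) for t in thetas])
        if np.any(r <= 0):
            raise GenerationError(f"non-positive section radius at z={z:.1f} (check radii)")
        ring = np.column_stack([c[0] + r * np.cos(thetas), c[1] + r * np.sin(thetas), np.full(n_theta, z)])
        verts.append(ring)
    verts = np.concatenate(verts)
    bottom = np.array([[*geo.center(levels[0]), levels[0] - 2.0]])
    top = np.array([[0.0, 0.0, geo.z_head + spec.head_radius]])
    vertices = np.concatenate([verts, bottom, top])
    i_bottom = len(vertices) - 2
    i_top = len(vertices) - 1

    faces = []
    n_rings = len(levels)
    # alternate the quad diagonal between the two theta half-ranges so the
    # triangulation is mirror-symmetric under y -> -y (j -> n-1-j)
    for i in range(n_rings - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + (j + 1) % n_theta
            d = (i + 1) * n_theta + j
            if j < n_theta // 2:
                faces.append((a, b, c))
                faces.append((a, c, d))
            else:
                faces.append((a, b, d))
                faces.append((b, c, d))
    for j in range(n_theta):
        faces.append((i_bottom, (j + 1) % n_theta, j))
        base = (n_rings - 1) * n_theta
        faces.append((i_top, base + j, base + (j + 1) % n_theta))
    faces = np.asarray(faces, dtype=np.int64)

    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if mesh.volume < 0:
        mesh = trimesh.Trimesh(vertices=vertices, faces=faces[:, ::-1], process=False)
    if not mesh.is_watertight:
        raise GenerationError("generated surface is not watertight")

    landmarks = _analytic_landmarks(geo)
    truth = {
        "nfa_deg": float(spec.nfa_deg),
        "neck_azimuth_deg": float(np.degrees(geo.nu)),
        "z_apex": float(geo.z_apex),
        "head_center": np.array([0.0, 0.0, geo.z_head]),
    }
    if spec.side == "left":
        flip = np.array([-1.0, 1.0, 1.0])
        mesh = trimesh.Trimesh(vertices=mesh.vertices * flip, faces=mesh.faces[:, ::-1], process=False)
        landmarks = landmarks.transformed(lambda p: p * flip)
        landmarks = replace(landmarks, side="left")
        truth["head_center"] = truth["head_center"] * flip
    return mesh, landmarks, truth


def _analytic_landmarks(geo: _FemurGeometry) -> LandmarkSet:
    spec = geo.spec
    tau = geo.tau
    rot = np.array([[np.cos(tau), -np.sin(tau)], [np.sin(tau), np.cos(tau)]])

    def condyle_pt(xy):
        return np.array([*(rot @ np.asarray(xy)), 0.0])

    sp, cp = CONDYLE_SINPHI, np.sqrt(1 - CONDYLE_SINPHI**2)
    pc_med = condyle_pt([CONDYLE_HALF_WIDTH * sp, -CONDYLE_HALF_DEPTH * cp])
    pc_lat = condyle_pt([-CONDYLE_HALF_WIDTH * sp, -CONDYLE_HALF_DEPTH * cp])
    epi_med = condyle_pt([CONDYLE_HALF_WIDTH, 0.0])
    epi_lat = condyle_pt([-CONDYLE_HALF_WIDTH, 0.0])

    lt_apex = geo.surface_point(geo.theta_lt, geo.z_apex)
    pf = geo.surface_point(geo.nu + np.radians(PF_AZIMUTH_DEG), geo.z_apex + PF_HEIGHT_ABOVE_APEX)
    z_tf = geo.z_apex + TF_HEIGHT_ABOVE_APEX
    theta_tf = geo.nu + np.radians(TF_AZIMUTH_DEG)
    r_local = geo.radius(theta_tf, z_tf)
    theta_tf += spec.fossa_posterior_offset / r_local  # posteriorize along the surface
    tf = geo.surface_point(theta_tf, z_tf)

    return LandmarkSet(
        head_center=np.array([0.0, 0.0, geo.z_head]),
        lesser_trochanter_apex=lt_apex,
        piriformis_fossa_center=pf,
        trochanteric_fossa=tf,
        post_condyle_medial=pc_med,
        post_condyle_lateral=pc_lat,
        epicondyle_medial=epi_med,
        epicondyle_lateral=epi_lat,
        side="right",
    )


def neck_canal_center(spec: FemurSpec, z: float) -> np.ndarray:
    """Analytic centerline point of the neck/shaft canal at height ``z`` (mm)."""
    geo = _FemurGeometry(spec)
    c = geo.center(z)
    p = np.array([c[0], c[1], z])
    if spec.side == "left":
        p = p * np.array([-1.0, 1.0, 1.0])
    return p


def generate_stem(spec: StemSpec, landmarks: LandmarkSet) -> Axis3D:
    """Implanted-stem neck axis with exact anteversion relative to the PCA.

    The axis direction makes ``neck_inclination_deg`` with the axial plane
    and azimuth ``stem_anteversion_deg`` from the projected condylar axis,
    measured about +SI; it is anchored at the canal level 10 mm above the
    lesser trochanter apex.
    """
    frame = build_femoral_frame(landmarks)
    pca = posterior_condylar_axis(landmarks)
    p = pca.direction - float(pca.direction @ frame.si_axis) * frame.si_axis
    p = p / np.linalg.norm(p)
    q = np.cross(frame.si_axis, p)
    psi = np.radians(spec.stem_anteversion_deg)
    incl = np.radians(spec.neck_inclination_deg)
    direction = np.cos(incl) * (np.cos(psi) * p + np.sin(psi) * q) + np.sin(incl) * frame.si_axis
    anchor = landmarks.lesser_trochanter_apex + 10.0 * frame.si_axis
    return Axis3D(point=anchor, direction=direction)


def voxelize(mesh, spacing=(0.98, 0.98, 1.0), bounds=None, pad=2) -> VoxelGrid:
    """Binary occupancy grid of a closed mesh (inside test per voxel center).

    Each z-level is filled by even-odd rasterization of the mesh-plane
    section polygons, which is exact for voxel centers away from the
    surface.  ``bounds`` (2x3 array) restricts the grid to a sub-region.
    """
    if not mesh.is_watertight:
        raise GenerationError("voxelize requires a closed (watertight) mesh")
    spacing = np.asarray(spacing, dtype=float)
    lo, hi = (np.asarray(bounds, dtype=float) if bounds is not None else mesh.bounds)
    origin = lo - pad * spacing
    dims = np.ceil((hi - lo) / spacing).astype(int) + 2 * pad + 1
    xs = origin[0] + spacing[0] * np.arange(dims[0])
    ys = origin[1] + spacing[1] * np.arange(dims[1])
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    data = np.zeros(dims, dtype=bool)
    for k in range(dims[2]):
        z = origin[2] + spacing[2] * k
        section = mesh.section(plane_origin=[0, 0, z], plane_normal=[0, 0, 1])
        if section is None:
            continue
        mask = np.zeros(dims[:2], dtype=bool)
        for disc in section.discrete:
            pts = np.asarray(disc)
            if len(pts) < 4 or not np.allclose(pts[0], pts[-1], atol=1e-8):
                continue
            poly = Polygon(pts[:-1, :2])
            if not poly.is_valid:
                poly = poly.buffer(0)
            inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(dims[:2])
            mask ^= inside
        data[:, :, k] = mask
    return VoxelGrid(data=data, spacing=tuple(spacing), origin=origin)


def _truncated_normal(rng, mean, sd, lo, hi):
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x


def generate_geometric_cohort(cohort: CohortSpec) -> list[VirtualSubject]:
    """Simulate ``n`` hips as full femur meshes with implanted stems.

    Native anteversion is drawn from a truncated normal with the cohort's
    PSA moments; the stem anteversion is the native anteversion plus
    zero-mean normal surgical noise; per-subject size parameters are
    jittered.  Deterministic for a given (cohort, seed).
    """
    if cohort.mode != "geometric":
        raise GenerationError("generate_geometric_cohort requires mode='geometric'")
    rng = np.random.default_rng(cohort.seed)
    subjects = []
    for i in range(cohort.n):
        nfa = _truncated_normal(rng, cohort.psa_mean, cohort.psa_sd, *cohort.nfa_bounds)
        psa = nfa + rng.normal(0.0, cohort.stem_noise_sd)
        spec = FemurSpec(
            nfa_deg=nfa,
            neck_shaft_angle_deg=float(np.clip(rng.normal(130.0, 4.0), 118.0, 142.0)),
            head_radius=float(np.clip(rng.normal(22.0, 1.5), 18.0, 26.0)),
            neck_radii=(
                float(np.clip(rng.normal(16.0, 1.0), 13.0, 19.0)),
                float(np.clip(rng.normal(11.0, 0.8), 9.0, 13.0)),
            ),
            shaft_radius=float(np.clip(rng.normal(14.0, 1.0), 11.0, 17.0)),
            fossa_posterior_offset=float(np.clip(rng.normal(3.0, 1.0), 0.0, 6.0)),
            side="right",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        mesh, landmarks, truth = generate_femur(spec)
        stem = StemSpec(stem_anteversion_deg=float(psa))
        axis = generate_stem(stem, landmarks)
        truth = {**truth, "psa_deg": float(psa)}
        subjects.append(
            VirtualSubject(
                femur_spec=spec,
                stem_spec=stem,
                mesh=mesh,
                landmarks=landmarks,
                stem_neck_axis=axis,
                truth=truth,
            )
        )
    return subjects


_CROWE_TYPES = np.array(["I", "II", "III", "IV"])
_CROWE_P = np.array([17.0, 3.0, 3.0, 5.0]) / 28.0  # reference cohort proportions


def generate_statistical_cohort(cohort: CohortSpec):
    """Draw a Table-style cohort of (PSA, per-method angle) records.

    For each hip PSA ~ N(psa_mean, psa_sd^2); each method cell is drawn from
    the bivariate normal implied by its configured (mean, sd, target r) with
    PSA, via the conditional construction.  Returns a pandas DataFrame with
    the canonical cohort columns.
    """
    import pandas as pd

    if cohort.mode != "statistical":
        raise GenerationError("generate_statistical_cohort requires mode='statistical'")
    if not cohort.methods:
        from .defaults import table2_defaults

        cohort = replace(cohort, methods=table2_defaults()["methods"])
        cohort.__post_init__()
    rng = np.random.default_rng(cohort.seed)
    n = cohort.n
    psa = rng.normal(cohort.psa_mean, cohort.psa_sd, size=n)
    cols = {
        "hip_id": [f"hip{i + 1:03d}" for i in range(n)],
        "side": rng.choice(["left", "right"], size=n),
        "crowe_type": rng.choice(_CROWE_TYPES, size=n, p=_CROWE_P),
        "psa_deg": psa,
    }
    for key in ("am_ct_5", "am_ct_10", "am_3d_5", "am_3d_10", "at_3d_5", "at_3d_10"):
        cell = cohort.methods.get(key)
        if cell is None:
            cols[key] = np.full(n, np.nan)
            continue
        r, m_mean, m_sd = float(cell["r"]), float(cell["mean"]), float(cell["sd"])
        cond_mean = m_mean + r * (m_sd / cohort.psa_sd) * (psa - cohort.psa_mean)
        cond_sd = m_sd * np.sqrt(max(1.0 - r**2, 0.0))
        cols[key] = cond_mean + cond_sd * rng.standard_normal(n)
    cols["truth_nfa_deg"] = np.full(n, np.nan)
    return pd.DataFrame(cols)
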