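"""Synthetic stand-ins for the CT-derived study inputs.

The real study worked from CT-segmented femur/tibia surfaces of an
end-stage knee-OA cohort plus a healthy articulated shape model; neither
dataset is public.  This module generates everything downstream code
needs from such data:

* parametric healthy lower limbs with controllable hip-knee-ankle (HKA)
  angle, femoral/tibial torsion, tibial slope, femoral bowing and size,
  all in dense point-to-point correspondence with a canonical template;
* arthritic degradation — osteophyte-like surface outliers, joint-space
  narrowing (optionally patterned "wear carving"), and extra coronal
  misalignment — with the exact applied deformation recorded so
  reconstruction accuracy can be scored against ground truth;
* 2D wear fields that are known mixtures of five spatial patterns
  (medial, lateral, anteromedial, posteromedial, tibial-spine);
* a cohort roster reproducing the study's inclusion/exclusion tallies.

Geometry is deliberately schematic (tube-with-condyle-cap surfaces, not
anatomically detailed bones): the downstream pipeline only requires
correspondence, landmarks and a measurable joint gap.

Coordinate convention (canonical frame): +x medial, +y posterior,
+z superior; the knee joint centre sits at the origin, the femur extends
up (+z) and the tibia down (−z).  All lengths are millimetres, all
angles degrees.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import trimesh

__all__ = [
    "LimbParams",
    "ArticulatedLimb",
    "ArthritisRecord",
    "WearField",
    "CohortRecord",
    "PATTERN_NAMES",
    "DEFAULT_CLASS_MIX",
    "generate_limb",
    "sample_limb_params",
    "impose_arthritis",
    "random_outlier_map",
    "pattern_templates",
    "generate_wear_cohort",
    "generate_roster",
    "apply_exclusions",
    "write_roster_csv",
    "read_roster_csv",
    "save_wear_fields",
    "load_wear_fields",
]

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LimbParams:
    """Parametric description of one lower limb.

    ``hka_deg`` follows the radiographic convention: 180 is a neutral
    mechanical axis, values above 180 are varus (bow-legged), below 180
    valgus.  Torsions are axial twists of the bone ends (positive =
    external).  ``tibial_slope_deg`` is the posterior inclination of the
    tibial plateau.  ``scale_mm`` is the femoral length; every other
    dimension scales proportionally.
    """

    hka_deg: float = 180.0
    femoral_torsion_deg: float = 0.0
    tibial_torsion_deg: float = 0.0
    tibial_slope_deg: float = 0.0
    femoral_bowing_deg: float = 0.0
    scale_mm: float = 420.0

    def validate(self) -> None:
        vals = [
            self.hka_deg,
            self.femoral_torsion_deg,
            self.tibial_torsion_deg,
            self.tibial_slope_deg,
            self.femoral_bowing_deg,
            self.scale_mm,
        ]
        if not np.all(np.isfinite(vals)):
            raise ValueError("limb parameters must all be finite")
        if self.scale_mm <= 0:
            raise ValueError("scale_mm must be positive")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.hka_deg,
                self.femoral_torsion_deg,
                self.tibial_torsion_deg,
                self.tibial_slope_deg,
                self.femoral_bowing_deg,
                self.scale_mm,
            ]
        )


@dataclass
class ArticulatedLimb:
    """Femur + tibia meshes with joint landmarks and anatomical axes.

    All limbs produced by :func:`generate_limb` at the same resolution
    share vertex count and ordering, i.e. they are in dense
    correspondence with a canonical template.
    """

    femur: trimesh.Trimesh
    tibia: trimesh.Trimesh
    landmarks: dict[str, np.ndarray]  # hip, knee, ankle centres
    axes: dict[str, np.ndarray]  # unit vectors, see measure_alignment
    params: LimbParams | None = None
    joint_gap_mm: float = 0.0
    femur_cap_ids: np.ndarray | None = None  # distal femoral articular ROI
    tibia_cap_ids: np.ndarray | None = None  # tibial plateau ROI
    cap_uv: np.ndarray | None = None  # canonical (u,v) of the femoral ROI

    def copy(self) -> "ArticulatedLimb":
        return ArticulatedLimb(
            femur=self.femur.copy(),
            tibia=self.tibia.copy(),
            landmarks={k: v.copy() for k, v in self.landmarks.items()},
            axes={k: v.copy() for k, v in self.axes.items()},
            params=self.params,
            joint_gap_mm=self.joint_gap_mm,
            femur_cap_ids=None if self.femur_cap_ids is None else self.femur_cap_ids.copy(),
            tibia_cap_ids=None if self.tibia_cap_ids is None else self.tibia_cap_ids.copy(),
            cap_uv=None if self.cap_uv is None else self.cap_uv.copy(),
        )

    def transformed(self, matrix: np.ndarray) -> "ArticulatedLimb":
        """Apply a rigid 4x4 transform to meshes, landmarks and axes."""
        R = np.asarray(matrix)[:3, :3]
        t = np.asarray(matrix)[:3, 3]
        out = self.copy()
        out.femur.vertices = out.femur.vertices @ R.T + t
        out.tibia.vertices = out.tibia.vertices @ R.T + t
        out.landmarks = {k: R @ v + t for k, v in out.landmarks.items()}
        out.axes = {k: R @ v for k, v in out.axes.items()}
        return out

    @property
    def all_vertices(self) -> np.ndarray:
        return np.vstack([self.femur.vertices, self.tibia.vertices])


@dataclass
class ArthritisRecord:
    """Exact deformation applied by :func:`impose_arthritis`.

    ``femur_disp``/``tibia_disp`` are the total per-vertex displacement
    vectors (new − old), so subtracting them restores the input mesh to
    machine precision.  The structured fields allow component-wise
    scoring of a reconstruction.
    """

    femur_disp: np.ndarray
    tibia_disp: np.ndarray
    outlier_offsets: np.ndarray  # magnitudes over femur+tibia vertices
    narrowing_mm: float
    extra_varus_deg: float
    pre_hka_deg: float
    wear_depth_mm: np.ndarray | None = None


@dataclass
class WearField:
    """A per-vertex wear field with its generating ground truth."""

    weights: np.ndarray  # 5-vector of pattern loadings
    noise_sd: float
    field: np.ndarray  # values in [0, 1]
    label: str = ""
    seed: int = 0


@dataclass(frozen=True)
class CohortRecord:
    case_id: str
    sex: str  # "female" | "male"
    has_hip_prosthesis: bool = False
    has_knee_prosthesis: bool = False
    has_osteosynthesis: bool = False
    has_segmentation_error: bool = False

    @property
    def excluded(self) -> bool:
        return (
            self.has_hip_prosthesis
            or self.has_knee_prosthesis
            or self.has_osteosynthesis
            or self.has_segmentation_error
        )


# ---------------------------------------------------------------------------
# Parametric limb construction
# ---------------------------------------------------------------------------

_JOINT_GAP_FRACTION = 6.0 / 420.0  # neutral femorotibial gap per unit femur length
_TIBIA_LENGTH_FRACTION = 0.88


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def _grid_counts(resolution: int) -> tuple[int, int, int]:
    """Choose (n_around, n_shaft_rings, n_cap_rings) for a vertex budget."""
    n_around = max(12, int(round(np.sqrt(resolution / 3.0))))
    n_cap_rings = max(3, n_around // 4)
    cap_verts = n_cap_rings * n_around + 1
    n_shaft = max(6, int(np.ceil((resolution - cap_verts) / n_around)))
    return n_around, n_shaft, n_cap_rings


def _bone_template(
    n_around: int,
    n_shaft: int,
    n_cap: int,
    length: float,
    radius_profile,
    cap_radius: float,
    cap_height,
    upward: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Tube along +z (knee end at z=0) with an articular cap disk at z=0.

    Returns (vertices, faces, cap_vertex_ids, cap_uv).  ``upward`` True
    for the femur (shaft extends to +z, cap faces −z), False for the
    tibia (shaft to −z, cap faces +z).
    """
    sgn = 1.0 if upward else -1.0
    theta = np.linspace(0.0, 2 * np.pi, n_around, endpoint=False)
    verts: list[np.ndarray] = []

    # articular cap: polar disk, centre vertex first
    verts.append(np.array([0.0, 0.0, sgn * cap_height(0.0, 0.0)]))
    cap_uv = [np.array([0.5, 0.5])]
    for i in range(1, n_cap + 1):
        rho = i / n_cap
        r = rho * cap_radius
        x = r * np.cos(theta)
        y = r * np.sin(theta)
        z = sgn * cap_height(rho, theta)
        verts.append(np.column_stack([x, y, z]))
        # canonical chart: u along −x (medial→lateral as u: 0→1), v along +y
        cap_uv.append(
            np.column_stack([0.5 - 0.5 * rho * np.cos(theta), 0.5 + 0.5 * rho * np.sin(theta)])
        )
    n_cap_verts = 1 + n_cap * n_around

    # shaft rings from the cap rim towards the far end; the cross-section
    # is deliberately asymmetric (as real bone is) so rigid registration
    # cannot lock onto a rotated pose about the shaft axis.  The asymmetry
    # ramps in away from the joint so the articular cap rim joins the
    # shaft without a ledge.
    cross = 1.0 + 0.14 * np.cos(theta) - 0.10 * np.sin(theta) + 0.06 * np.cos(3 * theta)
    # first shaft ring sits one step above the cap rim (the rim itself is
    # the cap's outer ring; coincident rings would degenerate the strip)
    z_shaft = np.linspace(length / n_shaft, length, n_shaft)
    for z in z_shaft:
        t_rel = z / length
        ramp = min(t_rel / 0.15, 1.0)
        r = radius_profile(t_rel) * (1.0 + (cross - 1.0) * ramp)
        x = r * np.cos(theta)
        y = r * np.sin(theta)
        verts.append(np.column_stack([x, y, np.full(n_around, sgn * z)]))

    V = np.vstack([v if v.ndim == 2 else v[None, :] for v in verts])

    faces: list[tuple[int, int, int]] = []

    def ring_ids(i_ring: int) -> np.ndarray:  # cap rings, 1-based
        return 1 + (i_ring - 1) * n_around + np.arange(n_around)

    # cap centre fan
    r1 = ring_ids(1)
    for k in range(n_around):
        faces.append((0, r1[k], r1[(k + 1) % n_around]))
    # cap annuli
    for i in range(1, n_cap):
        a, b = ring_ids(i), ring_ids(i + 1)
        for k in range(n_around):
            k2 = (k + 1) % n_around
            faces.append((a[k], b[k], b[k2]))
            faces.append((a[k], b[k2], a[k2]))
    # cap rim to first shaft ring, then shaft strips
    shaft0 = n_cap_verts
    rim = ring_ids(n_cap)
    first = shaft0 + np.arange(n_around)
    for k in range(n_around):
        k2 = (k + 1) % n_around
        faces.append((rim[k], first[k], first[k2]))
        faces.append((rim[k], first[k2], rim[k2]))
    for i in range(n_shaft - 1):
        a = shaft0 + i * n_around + np.arange(n_around)
        b = a + n_around
        for k in range(n_around):
            k2 = (k + 1) % n_around
            faces.append((a[k], b[k], b[k2]))
            faces.append((a[k], b[k2], a[k2]))

    F = np.asarray(faces, dtype=np.int64)
    cap_ids = np.arange(n_cap_verts)
    uv = np.vstack([u if u.ndim == 2 else u[None, :] for u in cap_uv])
    return V, F, cap_ids, uv


def _smooth_shape_noise(
    vertices: np.ndarray, length: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth radial perturbation giving each bone individual character.

    The perturbation is tapered to zero at the articular cap: individual
    variation lives in the shaft and metaphysis, while the articulating
    surfaces stay congruent across the cohort (so the joint-space map is
    not dominated by per-case surface congruence differences).
    """
    if amplitude <= 0:
        return np.zeros_like(vertices)
    x, y, z = vertices.T
    r = np.hypot(x, y)
    th = np.arctan2(y, x)
    t = np.abs(z) / max(length, 1e-9)
    taper = np.clip((t - 0.05) / 0.20, 0.0, 1.0)
    taper = taper * taper * (3.0 - 2.0 * taper)
    offs = np.zeros_like(r)
    for _ in range(4):
        a = rng.normal(0.0, amplitude / 2.0)
        fz = rng.integers(1, 4)
        m = rng.integers(0, 3)
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        offs += a * np.sin(fz * np.pi * t + p1) * np.cos(m * th + p2)
    offs = offs * taper
    safe = r > 1e-9
    disp = np.zeros_like(vertices)
    disp[safe, 0] = offs[safe] * np.cos(th[safe])
    disp[safe, 1] = offs[safe] * np.sin(th[safe])
    return disp


def generate_limb(
    params: LimbParams,
    resolution: int = 600,
    seed: int = 0,
    shape_noise_mm: float = 0.6,
) -> ArticulatedLimb:
    """Generate a femur+tibia limb in canonical pose.

    All limbs at the same ``resolution`` share the template topology, so
    vertex *i* corresponds anatomically across limbs.  The measured HKA
    of the output equals ``params.hka_deg`` to well within 0.1° because
    the coronal deviation is imposed as exact rotations of the two bones
    about the knee centre.  ``seed`` drives a smooth per-individual
    surface perturbation (amplitude ``shape_noise_mm``) that leaves the
    landmarks untouched.
    """
    params.validate()
    if resolution < 200:
        raise ValueError("resolution must be at least 200 vertices per bone")
    rng = np.random.default_rng(seed)

    s = params.scale_mm / 420.0
    Lf = params.scale_mm
    Lt = _TIBIA_LENGTH_FRACTION * params.scale_mm
    gap = _JOINT_GAP_FRACTION * params.scale_mm
    n_around, n_shaft, n_cap = _grid_counts(resolution)

    # femur: condylar flare at the knee, head bulge near the hip
    def fem_radius(t: float) -> float:
        shaft = 14.0
        condyle = 16.0 * np.exp(-((t / 0.12) ** 2))
        head = 8.0 * np.exp(-(((t - 1.0) / 0.10) ** 2))
        return s * (shaft + condyle + head)

    def fem_cap_height(rho, theta):
        # convex bi-lobed condylar surface bulging towards the tibia
        lobes = 1.0 + 0.25 * np.cos(2.0 * np.asarray(theta))
        return -s * 5.0 * (1.0 - np.asarray(rho) ** 2) * lobes

    fem_V, fem_F, fem_cap, cap_uv = _bone_template(
        n_around, n_shaft, n_cap, Lf, fem_radius, fem_radius(0.0), fem_cap_height, upward=True
    )

    def tib_radius(t: float) -> float:
        shaft = 12.0
        plateau = 18.0 * np.exp(-((t / 0.10) ** 2))
        ankle = 6.0 * np.exp(-(((t - 1.0) / 0.12) ** 2))
        return s * (shaft + plateau + ankle)

    def tib_cap_height(rho, theta):
        # shallow concave plateau (dips away from the femur at its centre)
        return s * 0.8 * (1.0 - np.asarray(rho) ** 2) * np.ones_like(
            np.asarray(theta, dtype=float) * np.asarray(rho, dtype=float)
        )

    tib_V, tib_F, tib_cap, _ = _bone_template(
        n_around, n_shaft, n_cap, Lt, tib_radius, s * 30.0, tib_cap_height, upward=False
    )

    # individual (non-parametric) shape variation
    fem_V = fem_V + _smooth_shape_noise(fem_V, Lf, shape_noise_mm, rng)
    tib_V = tib_V + _smooth_shape_noise(tib_V, Lt, shape_noise_mm, rng)

    # femoral bowing: lateral (−x) bow of the shaft, end points fixed
    if params.femoral_bowing_deg != 0.0:
        amp = Lf * np.sin(np.deg2rad(params.femoral_bowing_deg)) / 4.0
        t = np.clip(fem_V[:, 2] / Lf, 0.0, 1.0)
        fem_V[:, 0] -= amp * np.sin(np.pi * t)

    # torsion: twist the far end relative to the knee about the long axis
    def _twist(V: np.ndarray, L: float, angle_deg: float) -> np.ndarray:
        t = np.clip(np.abs(V[:, 2]) / L, 0.0, 1.0)
        a = np.deg2rad(angle_deg) * t
        c, sn = np.cos(a), np.sin(a)
        out = V.copy()
        out[:, 0] = c * V[:, 0] - sn * V[:, 1]
        out[:, 1] = sn * V[:, 0] + c * V[:, 1]
        return out

    neck_axis = np.array([1.0, 0.0, 0.0])
    if params.femoral_torsion_deg != 0.0:
        fem_V = _twist(fem_V, Lf, params.femoral_torsion_deg)
        neck_axis = _rotation([0, 0, 1], params.femoral_torsion_deg) @ neck_axis
    ankle_axis = np.array([1.0, 0.0, 0.0])
    if params.tibial_torsion_deg != 0.0:
        tib_V = _twist(tib_V, Lt, params.tibial_torsion_deg)
        ankle_axis = _rotation([0, 0, 1], params.tibial_torsion_deg) @ ankle_axis

    # tibial slope: tilt the plateau cap about the medial axis
    plateau_normal = np.array([0.0, 0.0, 1.0])
    if params.tibial_slope_deg != 0.0:
        Rs = _rotation([1, 0, 0], params.tibial_slope_deg)
        tib_V[tib_cap] = tib_V[tib_cap] @ Rs.T
        plateau_normal = Rs @ plateau_normal

    # place bones either side of the joint gap (measured as the vertical
    # clearance between the deepest femoral condyle point and the highest
    # tibial plateau point)
    off_f = gap / 2.0 - np.min(fem_V[fem_cap, 2])
    off_t = -gap / 2.0 - np.max(tib_V[tib_cap, 2])
    fem_V[:, 2] += off_f
    tib_V[:, 2] += off_t
    actual_gap = float(np.min(fem_V[fem_cap, 2]) - np.max(tib_V[tib_cap, 2]))

    hip = np.array([0.0, 0.0, Lf + off_f])
    knee = np.zeros(3)
    ankle = np.array([0.0, 0.0, -Lt + off_t])

    # coronal alignment: the HKA deviation is built into the bone geometry
    # as a smooth coronal bend of each shaft relative to its articular cap
    # (as in constitutional varus/valgus, where the deformity lives in the
    # distal femur / proximal tibia), split evenly over the two bones.
    # Positive deviation (varus) sends hip and ankle towards medial +x;
    # the articular caps (bend weight 0) keep articulating horizontally.
    delta = params.hka_deg - 180.0

    def _smoothstep(t, a, b):
        x = np.clip((t - a) / (b - a), 0.0, 1.0)
        return x * x * (3.0 - 2.0 * x)

    def _bend_about_y(V, angles_rad):
        c, sn = np.cos(angles_rad), np.sin(angles_rad)
        out = V.copy()
        out[:, 0] = c * V[:, 0] + sn * V[:, 2]  # +angle sends +z towards +x
        out[:, 2] = -sn * V[:, 0] + c * V[:, 2]
        return out

    if delta != 0.0:
        wf = _smoothstep(fem_V[:, 2] / Lf, 0.08, 0.35)
        fem_V = _bend_about_y(fem_V, np.deg2rad(delta / 2.0) * wf)
        wt = _smoothstep(-tib_V[:, 2] / Lt, 0.08, 0.35)
        tib_V = _bend_about_y(tib_V, np.deg2rad(-delta / 2.0) * wt)
        Rf = _rotation([0, 1, 0], delta / 2.0)  # full bend, reached at the hip
        Rt = _rotation([0, 1, 0], -delta / 2.0)
        hip = Rf @ hip
        ankle = Rt @ ankle
        neck_axis = Rf @ neck_axis
    condylar_axis = np.array([1.0, 0.0, 0.0])

    femur = trimesh.Trimesh(vertices=fem_V, faces=fem_F, process=False)
    tibia = trimesh.Trimesh(vertices=tib_V, faces=tib_F, process=False)
    return ArticulatedLimb(
        femur=femur,
        tibia=tibia,
        landmarks={"hip": hip, "knee": knee, "ankle": ankle},
        axes={
            "medial": np.array([1.0, 0.0, 0.0]),
            "femoral_neck": neck_axis,
            "femoral_condylar": condylar_axis,
            "tibial_ankle": ankle_axis,
            "tibial_plateau_normal": plateau_normal,
        },
        params=params,
        joint_gap_mm=actual_gap,
        femur_cap_ids=fem_cap,
        tibia_cap_ids=tib_cap,
        cap_uv=cap_uv,
    )


def sample_limb_params(
    rng: np.random.Generator,
    hka_mean: float = 180.0,
    hka_sd: float = 2.5,
    torsion_sd: float = 5.0,
    slope_mean: float = 7.0,
    slope_sd: float = 2.5,
    bowing_sd: float = 1.5,
    scale_mean: float = 420.0,
    scale_sd: float = 20.0,
) -> LimbParams:
    """Draw plausible healthy-population limb parameters.

    Defaults reflect adult reference ranges: HKA 180 ± 2.5°, femoral and
    tibial torsion SD 5°, posterior tibial slope 7 ± 2.5°, femoral length
    420 ± 20 mm.
    """
    return LimbParams(
        hka_deg=float(np.clip(rng.normal(hka_mean, hka_sd), 160.0, 200.0)),
        femoral_torsion_deg=float(rng.normal(10.0, torsion_sd)),
        tibial_torsion_deg=float(rng.normal(20.0, torsion_sd)),
        tibial_slope_deg=float(rng.normal(slope_mean, slope_sd)),
        femoral_bowing_deg=float(rng.normal(0.0, bowing_sd)),
        scale_mm=float(max(rng.normal(scale_mean, scale_sd), 300.0)),
    )


# ---------------------------------------------------------------------------
# Arthritic degradation
# ---------------------------------------------------------------------------


def random_outlier_map(
    limb: ArticulatedLimb,
    fraction: float = 0.05,
    magnitude_mm: float = 3.0,
    seed: int = 0,
    knee_region_mm: float | None = None,
) -> np.ndarray:
    """Offset magnitudes for osteophyte-like bumps near the knee joint.

    Selects ``fraction`` of the vertices lying within ``knee_region_mm``
    of the knee centre (default: 15% of femoral length) and assigns them
    offset ``magnitude_mm``; all other vertices get 0.  Articular-cap
    vertices are excluded — osteophytes form at the joint margins, not
    on the articulating surface itself.  Returned array covers femur
    followed by tibia vertices.
    """
    rng = np.random.default_rng(seed)
    V = limb.all_vertices
    if knee_region_mm is None:
        knee_region_mm = 0.15 * (limb.params.scale_mm if limb.params else 420.0)
    near = np.linalg.norm(V - limb.landmarks["knee"], axis=1) < knee_region_mm
    if limb.femur_cap_ids is not None:
        near[limb.femur_cap_ids] = False
    if limb.tibia_cap_ids is not None:
        near[len(limb.femur.vertices) + limb.tibia_cap_ids] = False
    candidates = np.flatnonzero(near)
    n_pick = max(1, int(round(fraction * len(V))))
    n_pick = min(n_pick, len(candidates))
    picked = rng.choice(candidates, size=n_pick, replace=False)
    offsets = np.zeros(len(V))
    offsets[picked] = magnitude_mm
    return offsets


def impose_arthritis(
    limb: ArticulatedLimb,
    outlier_map: np.ndarray | None = None,
    narrowing_mm: float = 0.0,
    extra_varus_deg: float = 0.0,
    seed: int = 0,
    wear_depth_mm: np.ndarray | None = None,
) -> tuple[ArticulatedLimb, ArthritisRecord]:
    """Degrade a healthy limb into an arthritic one, recording the truth.

    * ``outlier_map`` — per-vertex outward offsets (femur then tibia
      vertices) modelling osteophytes; applied along vertex normals.
    * ``narrowing_mm`` — uniform joint-space narrowing, imposed by
      translating the femur towards the tibia along the joint axis.
    * ``extra_varus_deg`` — additional coronal misalignment, imposed as
      a rotation of the femur about the knee centre (positive = varus).
    * ``wear_depth_mm`` — optional per-ROI-vertex extra narrowing carved
      into the femoral articular cap, for patterned cartilage wear.

    Returns the deformed limb and an :class:`ArthritisRecord` holding
    the exact per-vertex displacements, so ``deformed − record`` equals
    the input to machine precision.
    """
    nF = len(limb.femur.vertices)
    nT = len(limb.tibia.vertices)
    if outlier_map is None:
        outlier_map = np.zeros(nF + nT)
    outlier_map = np.asarray(outlier_map, dtype=float)
    if outlier_map.shape != (nF + nT,):
        raise ValueError("outlier_map must have one entry per femur+tibia vertex")
    if np.any(outlier_map < 0):
        raise ValueError("outlier offsets must be non-negative")
    if narrowing_mm < 0:
        raise ValueError("narrowing_mm must be non-negative")
    total_narrow = narrowing_mm
    if wear_depth_mm is not None:
        wear_depth_mm = np.asarray(wear_depth_mm, dtype=float)
        total_narrow = narrowing_mm + float(np.max(wear_depth_mm, initial=0.0))
    if total_narrow > limb.joint_gap_mm:
        raise ValueError(
            f"requested narrowing {total_narrow:.2f} mm exceeds the joint gap "
            f"{limb.joint_gap_mm:.2f} mm (non-physical interpenetration)"
        )

    out = limb.copy()
    fem0 = out.femur.vertices.copy()
    tib0 = out.tibia.vertices.copy()
    pre_hka = limb.params.hka_deg if limb.params is not None else 180.0

    # osteophyte bumps along outward normals
    fem_n = out.femur.vertex_normals
    tib_n = out.tibia.vertex_normals
    fem_V = out.femur.vertices + fem_n * outlier_map[:nF, None]
    tib_V = out.tibia.vertices + tib_n * outlier_map[nF:, None]

    # patterned cartilage wear: push femoral cap vertices towards the tibia
    if wear_depth_mm is not None:
        cap = out.femur_cap_ids
        if cap is None or wear_depth_mm.shape != cap.shape:
            raise ValueError("wear_depth_mm must match the femoral ROI vertex count")
        axis = _joint_axis(out)
        fem_V[cap] -= axis[None, :] * wear_depth_mm[:, None]

    # uniform joint-space narrowing: femur translated down the joint axis
    if narrowing_mm > 0:
        fem_V = fem_V - _joint_axis(out) * narrowing_mm

    # extra coronal misalignment of the femur about the knee centre
    if extra_varus_deg != 0.0:
        R = _varus_rotation(out, extra_varus_deg)
        knee = out.landmarks["knee"]
        fem_V = (fem_V - knee) @ R.T + knee
        out.landmarks["hip"] = R @ (out.landmarks["hip"] - knee) + knee
        for k in ("femoral_neck", "femoral_condylar"):
            out.axes[k] = R @ out.axes[k]

    out.femur.vertices = fem_V
    out.tibia.vertices = tib_V
    out.joint_gap_mm = limb.joint_gap_mm - narrowing_mm
    if limb.params is not None:
        out.params = replace(limb.params, hka_deg=limb.params.hka_deg + extra_varus_deg)

    rec = ArthritisRecord(
        femur_disp=fem_V - fem0,
        tibia_disp=tib_V - tib0,
        outlier_offsets=outlier_map,
        narrowing_mm=narrowing_mm,
        extra_varus_deg=extra_varus_deg,
        pre_hka_deg=pre_hka,
        wear_depth_mm=wear_depth_mm,
    )
    return out, rec


def _joint_axis(limb: ArticulatedLimb) -> np.ndarray:
    """Unit vector from knee towards hip (direction of joint opening)."""
    v = limb.landmarks["hip"] - limb.landmarks["ankle"]
    return v / np.linalg.norm(v)


def _coronal_normal(limb: ArticulatedLimb) -> np.ndarray:
    """Normal of the coronal plane (the intrinsic antero-posterior axis)."""
    z = _joint_axis(limb)
    m = limb.axes["medial"]
    n = np.cross(z, m)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("degenerate limb axes")
    return n / nn


def _varus_rotation(limb: ArticulatedLimb, angle_deg: float) -> np.ndarray:
    """Rotation about the AP axis moving the hip towards medial (varus+)."""
    y = _coronal_normal(limb)
    z = _joint_axis(limb)
    m = np.cross(y, z)  # in-plane medial direction
    # rotating about -y by angle sends +z towards +m (hip to medial)
    R = _rotation(y, -angle_deg)
    # verify direction: R @ z should tilt towards m
    if np.dot(R @ z, m) < 0:
        R = _rotation(y, angle_deg)
    return R


# ---------------------------------------------------------------------------
# Wear-pattern templates and cohorts
# ---------------------------------------------------------------------------

PATTERN_NAMES = ("medial", "lateral", "anteromedial", "posteromedial", "spine")

# (u, v) centres and radii of the smooth bump templates; u runs
# medial→lateral, v anterior→posterior.  medial/lateral are mirror
# images under u→1−u, anteromedial/posteromedial under v→1−v.
_TEMPLATE_CENTERS = {
    "medial": (0.25, 0.50),
    "lateral": (0.75, 0.50),
    "anteromedial": (0.25, 0.22),
    "posteromedial": (0.25, 0.78),
    "spine": (0.50, 0.50),
}
_TEMPLATE_WIDTHS = {
    "medial": 0.20,
    "lateral": 0.20,
    "anteromedial": 0.14,
    "posteromedial": 0.14,
    "spine": 0.09,
}


def pattern_templates(uv: np.ndarray) -> np.ndarray:
    """Evaluate the five wear-pattern templates at (u,v) points.

    Returns an array of shape (n_points, 5), columns ordered as
    :data:`PATTERN_NAMES`, each template a Gaussian bump with peak 1.
    """
    uv = np.asarray(uv, dtype=float)
    out = np.empty((len(uv), len(PATTERN_NAMES)))
    for j, name in enumerate(PATTERN_NAMES):
        cu, cv = _TEMPLATE_CENTERS[name]
        w = _TEMPLATE_WIDTHS[name]
        d2 = (uv[:, 0] - cu) ** 2 + (uv[:, 1] - cv) ** 2
        out[:, j] = np.exp(-d2 / (2 * w**2))
    return out


# Default mixture over wear classes, emulating the taxonomy observed in
# the study population: medial wear dominates, with anteromedial and
# posteromedial subtypes, followed by bicompartmental, lateral and
# tibial-spine impingement.  Probabilities normalized to sum to 1.
_raw_mix = {
    "medial": 0.331,
    "bicompartmental": 0.252,
    "anteromedial": 0.113,
    "posteromedial": 0.104,
    "lateral": 0.091,
    "spine": 0.045,
}
DEFAULT_CLASS_MIX = {k: v / sum(_raw_mix.values()) for k, v in _raw_mix.items()}

_CLASS_WEIGHTS = {
    # mean loading on (medial, lateral, anteromedial, posteromedial, spine)
    "medial": np.array([1.0, 0.0, 0.0, 0.0, 0.0]),
    "bicompartmental": np.array([0.7, 0.7, 0.0, 0.0, 0.0]),
    "anteromedial": np.array([0.35, 0.0, 0.9, 0.0, 0.0]),
    "posteromedial": np.array([0.35, 0.0, 0.0, 0.9, 0.0]),
    "lateral": np.array([0.0, 1.0, 0.0, 0.0, 0.0]),
    "spine": np.array([0.0, 0.0, 0.0, 0.0, 1.0]),
}


def default_uv_grid(n: int = 32) -> np.ndarray:
    """Regular n×n grid of (u,v) sample points over the unit square."""
    g = (np.arange(n) + 0.5) / n
    uu, vv = np.meshgrid(g, g, indexing="xy")
    return np.column_stack([uu.ravel(), vv.ravel()])


def generate_wear_cohort(
    n: int,
    class_spec: dict[str, float] | None = None,
    seed: int = 0,
    uv: np.ndarray | None = None,
    noise_sd: float = 0.05,
    weight_jitter: float = 0.15,
) -> list[WearField]:
    """Generate ``n`` wear fields as known mixtures of the 5 templates.

    ``class_spec`` maps class name → probability (default
    :data:`DEFAULT_CLASS_MIX`).  Each case draws a class, jitters that
    class's mean loading vector, evaluates the mixture on ``uv`` points
    (default 32×32 grid) and adds clipped Gaussian noise.  Ground-truth
    weights and class labels are stored on each :class:`WearField`.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if class_spec is None:
        class_spec = DEFAULT_CLASS_MIX
    names = list(class_spec)
    probs = np.array([class_spec[k] for k in names], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("class probabilities must sum to a positive value")
    probs = probs / probs.sum()
    if uv is None:
        uv = default_uv_grid()
    T = pattern_templates(uv)
    rng = np.random.default_rng(seed)
    if weight_jitter == 0 and noise_sd == 0:
        warnings.warn("degenerate class_spec: zero variance in all patterns")
    fields = []
    for i in range(n):
        cls = names[rng.choice(len(names), p=probs)]
        w = np.clip(_CLASS_WEIGHTS[cls] + rng.normal(0, weight_jitter, 5), 0, None)
        f = T @ w + rng.normal(0, noise_sd, len(uv))
        fields.append(
            WearField(
                weights=w,
                noise_sd=noise_sd,
                field=np.clip(f, 0.0, 1.0),
                label=cls,
                seed=seed,
            )
        )
    return fields


def wear_field_from_weights(
    weights: np.ndarray,
    uv: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Deterministic wear field for explicit pattern loadings."""
    f = pattern_templates(uv) @ np.asarray(weights, dtype=float)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        f = f + rng.normal(0, noise_sd, len(uv))
    return np.clip(f, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Cohort roster and exclusions
# ---------------------------------------------------------------------------

# printed inclusion/exclusion tallies of the study database
_ROSTER_SPEC = {
    "female": {"total": 460, "hip": 40, "knee": 5, "osteo": 2, "segm": 14},
    "male": {"total": 473, "hip": 42, "knee": 5, "osteo": 15, "segm": 12},
}


def generate_roster() -> list[CohortRecord]:
    """The 933-subject retrospective cohort with per-reason exclusion flags.

    460 females and 473 males; per sex, the printed numbers of hip
    prostheses, knee prostheses, osteosynthesis material and
    segmentation/registration errors are flagged on distinct records
    (reasons disjoint), the remainder clean.
    """
    roster: list[CohortRecord] = []
    for sex, spec in _ROSTER_SPEC.items():
        i = 0
        counts = [
            ("has_hip_prosthesis", spec["hip"]),
            ("has_knee_prosthesis", spec["knee"]),
            ("has_osteosynthesis", spec["osteo"]),
            ("has_segmentation_error", spec["segm"]),
        ]
        for flag_name, k in counts:
            for _ in range(k):
                roster.append(
                    CohortRecord(case_id=f"{sex[0].upper()}{i:04d}", sex=sex, **{flag_name: True})
                )
                i += 1
        while i < spec["total"]:
            roster.append(CohortRecord(case_id=f"{sex[0].upper()}{i:04d}", sex=sex))
            i += 1
    return roster


def apply_exclusions(
    roster: Sequence[CohortRecord],
) -> tuple[list[CohortRecord], dict[str, dict[str, int]]]:
    """Drop records with any exclusion flag; tally reasons per sex.

    Returns (included records, counts) where ``counts[sex]`` maps each
    reason plus ``included``/``excluded`` to its tally.
    """
    ids = [r.case_id for r in roster]
    if len(set(ids)) != len(ids):
        raise ValueError("case_id values must be unique")
    reasons = {
        "hip_prosthesis": "has_hip_prosthesis",
        "knee_prosthesis": "has_knee_prosthesis",
        "osteosynthesis": "has_osteosynthesis",
        "segmentation_error": "has_segmentation_error",
    }
    counts: dict[str, dict[str, int]] = {}
    included: list[CohortRecord] = []
    for r in roster:
        c = counts.setdefault(
            r.sex, {k: 0 for k in list(reasons) + ["included", "excluded", "total"]}
        )
        c["total"] += 1
        if r.excluded:
            c["excluded"] += 1
            for label, attr in reasons.items():
                if getattr(r, attr):
                    c[label] += 1
        else:
            c["included"] += 1
            included.append(r)
    return included, counts


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_ROSTER_HEADER = [
    "case_id",
    "sex",
    "hip_prosthesis",
    "knee_prosthesis",
    "osteosynthesis",
    "segmentation_error",
]


def write_roster_csv(roster: Sequence[CohortRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_ROSTER_HEADER)
        for r in roster:
            w.writerow(
                [
                    r.case_id,
                    r.sex,
                    int(r.has_hip_prosthesis),
                    int(r.has_knee_prosthesis),
                    int(r.has_osteosynthesis),
                    int(r.has_segmentation_error),
                ]
            )


def read_roster_csv(path) -> list[CohortRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                CohortRecord(
                    case_id=row["case_id"],
                    sex=row["sex"],
                    has_hip_prosthesis=bool(int(row["hip_prosthesis"])),
                    has_knee_prosthesis=bool(int(row["knee_prosthesis"])),
                    has_osteosynthesis=bool(int(row["osteosynthesis"])),
                    has_segmentation_error=bool(int(row["segmentation_error"])),
                )
            )
    return out


def save_wear_fields(fields: Sequence[WearField], path) -> None:
    np.savez(
        path,
        field=np.vstack([f.field for f in fields]),
        weights=np.vstack([f.weights for f in fields]),
        seed=np.array([f.seed for f in fields]),
        noise_sd=np.array([f.noise_sd for f in fields]),
        label=np.array([f.label for f in fields]),
    )


def load_wear_fields(path) -> list[WearField]:
    z = np.load(path, allow_pickle=False)
    return [
        WearField(
            weights=z["weights"][i],
            noise_sd=float(z["noise_sd"][i]),
            field=z["field"][i],
            label=str(z["label"][i]),
            seed=int(z["seed"][i]),
        )
        for i in range(len(z["field"]))
    ]


def export_limb(limb: ArticulatedLimb, prefix, fmt: str = "ply") -> list[str]:
    """Write femur/tibia meshes as binary PLY or STL; returns paths."""
    paths = []
    for name, mesh in (("femur", limb.femur), ("tibia", limb.tibia)):
        p = f"{prefix}_{name}.{fmt}"
        mesh.export(p)
        paths.append(p)
    return paths
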