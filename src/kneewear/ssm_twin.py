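"""Statistical shape modelling and virtual-healthy-twin reconstruction.

A statistical shape model (SSM) is a mean shape plus orthonormal modes
of variation learned from corresponded training shapes.  Fitting a
*healthy* SSM to an arthritic bone while iteratively excluding outlier
correspondences (osteophytes, eroded regions) yields an estimate of the
bone's pre-disease geometry; reassembling femur and tibia through a
healthy *articulated* whole-limb model additionally restores their
relative pose (alignment), producing the virtual healthy twin.

Pipeline order: :func:`build_ssm` → :func:`robust_fit` (per bone) →
:func:`reconstruct_twin` → :func:`measure_alignment` /
:func:`mahalanobis_normalize`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .synthetic_cohort import ArticulatedLimb, _rotation

__all__ = [
    "ShapeModel",
    "ArticulatedSSM",
    "FitResult",
    "AlignmentProfile",
    "generalized_procrustes",
    "build_ssm",
    "build_bone_ssm",
    "build_articulated_ssm",
    "robust_fit",
    "project_shape",
    "reconstruct_twin",
    "measure_alignment",
    "classify_alignment",
    "mahalanobis_normalize",
    "sample_model",
    "save_model",
    "load_model",
]

# varus/valgus classification thresholds (degrees, boundaries inclusive)
VALGUS_MAX_DEG = 177.0
VARUS_MIN_DEG = 183.0


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------


@dataclass
class ShapeModel:
    """Mean shape + orthonormal variation modes.

    ``mean_shape`` is (V, 3) in mm; ``modes`` is (3V, k) with orthonormal
    columns sorted by decreasing ``mode_variances`` (mm²).
    ``total_variance`` is the full training variance including any modes
    truncated away, so explained-variance fractions stay meaningful.
    """

    mean_shape: np.ndarray
    modes: np.ndarray
    mode_variances: np.ndarray
    n_training: int
    total_variance: float = 0.0
    # trailing pseudo-vertices (e.g. joint centres) are synthesized from the
    # loadings but take no part in surface correspondence during fitting
    pseudo_names: tuple[str, ...] = ()

    @property
    def n_vertices(self) -> int:
        return self.mean_shape.shape[0]

    @property
    def n_surface(self) -> int:
        return self.mean_shape.shape[0] - len(self.pseudo_names)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def synthesize(self, coefficients: np.ndarray) -> np.ndarray:
        """Shape (V, 3) for a loading vector."""
        c = np.zeros(self.n_modes)
        c[: len(coefficients)] = coefficients
        return self.mean_shape + (self.modes @ c).reshape(-1, 3)

    def explained_fraction(self) -> np.ndarray:
        if self.total_variance <= 0:
            return np.zeros(self.n_modes)
        return self.mode_variances / self.total_variance


@dataclass
class ArticulatedSSM(ShapeModel):
    """Whole-limb model over stacked femur + tibia vertices + landmarks.

    Rows of the stacked shape are: femur vertices, tibia vertices, then
    the hip/knee/ankle landmark points, all expressed in one canonical
    limb frame so relative bone pose is part of the model.
    """

    n_femur: int = 0
    n_tibia: int = 0
    landmark_names: tuple[str, ...] = ("hip", "knee", "ankle")
    femur_faces: np.ndarray | None = None
    tibia_faces: np.ndarray | None = None
    axes: dict[str, np.ndarray] = field(default_factory=dict)
    femur_cap_ids: np.ndarray | None = None
    tibia_cap_ids: np.ndarray | None = None
    cap_uv: np.ndarray | None = None
    # reassembly regression: maps [femur loadings, tibia loadings, 1] to
    # articulated loadings, learned from the training limbs
    assembly_weights: np.ndarray | None = None
    n_femur_modes: int = 0
    n_tibia_modes: int = 0

    def split_blocks(self, shape: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        f = shape[: self.n_femur]
        t = shape[self.n_femur : self.n_femur + self.n_tibia]
        lm = shape[self.n_femur + self.n_tibia :]
        return f, t, lm


@dataclass
class FitResult:
    """Converged state of :func:`robust_fit`."""

    coefficients: np.ndarray
    correspondence: np.ndarray  # target-vertex index per model vertex
    outlier_mask: np.ndarray  # True where the pair was excluded
    residuals: np.ndarray  # per-model-vertex distance (mm)
    n_iterations: int
    converged: bool
    fitted_vertices: np.ndarray  # model-space reconstruction (V, 3)
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rms_history: list[float] = field(default_factory=list)
    pseudo_names: tuple[str, ...] = ()

    @property
    def surface_vertices(self) -> np.ndarray:
        n = len(self.fitted_vertices) - len(self.pseudo_names)
        return self.fitted_vertices[:n]

    def pseudo_point(self, name: str) -> np.ndarray:
        i = self.pseudo_names.index(name)
        return self.fitted_vertices[len(self.fitted_vertices) - len(self.pseudo_names) + i]


@dataclass
class AlignmentProfile:
    hka_deg: float
    femoral_torsion_deg: float
    tibial_torsion_deg: float
    tibial_slope_deg: float
    bowing_deg: float
    varus_valgus_class: str

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.hka_deg,
                self.femoral_torsion_deg,
                self.tibial_torsion_deg,
                self.tibial_slope_deg,
                self.bowing_deg,
            ]
        )


# ---------------------------------------------------------------------------
# Procrustes and model construction
# ---------------------------------------------------------------------------


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid (R, t) minimizing ||src @ R.T + t − dst||, no scaling."""
    cs, cd = src.mean(0), dst.mean(0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cd - R @ cs
    return R, t


def generalized_procrustes(
    shapes: list[np.ndarray], max_iter: int = 10, tol: float = 1e-10
) -> list[np.ndarray]:
    """Rigidly align corresponded shapes to their evolving mean (no scaling)."""
    aligned = [s - s.mean(0) for s in shapes]
    mean = aligned[0].copy()
    for _ in range(max_iter):
        new = []
        for s in aligned:
            R, t = _kabsch(s, mean)
            new.append(s @ R.T + t)
        new_mean = np.mean(new, axis=0)
        shift = np.linalg.norm(new_mean - mean) / max(np.linalg.norm(mean), 1e-12)
        aligned, mean = new, new_mean
        if shift < tol:
            break
    return aligned


def build_ssm(
    training_shapes: list[np.ndarray],
    variance_kept: float = 0.98,
    align: bool = True,
) -> ShapeModel:
    """Principal-component shape model from corresponded training shapes.

    Shapes are generalized-Procrustes aligned (rigid), then the vertex
    coordinate covariance is eigen-decomposed; the smallest mode count
    explaining at least ``variance_kept`` of total variance is retained.
    """
    if len(training_shapes) < 3:
        raise ValueError("at least 3 training shapes are required")
    V = training_shapes[0].shape
    for s in training_shapes[1:]:
        if s.shape != V:
            raise ValueError("all training shapes must share vertex count and ordering")
    shapes = [np.asarray(s, dtype=float) for s in training_shapes]
    if align:
        shapes = generalized_procrustes(shapes)
    X = np.stack([s.ravel() for s in shapes])
    mean = X.mean(0)
    Xc = X - mean
    U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = svals**2 / (len(shapes) - 1)
    total = float(variances.sum())
    nonzero = variances > max(total, 1e-30) * 1e-12
    variances, Vt = variances[nonzero], Vt[nonzero]
    if total > 0:
        cum = np.cumsum(variances) / total
        k = int(np.searchsorted(cum, min(variance_kept, cum[-1]) - 1e-12) + 1)
    else:
        k = len(variances)
    return ShapeModel(
        mean_shape=mean.reshape(-1, 3),
        modes=Vt[:k].T.copy(),
        mode_variances=variances[:k].copy(),
        n_training=len(shapes),
        total_variance=total,
    )


def build_bone_ssm(
    limbs: list[ArticulatedLimb], bone: str, variance_kept: float = 0.98
) -> ShapeModel:
    """Per-bone SSM (``bone`` in {"femur", "tibia"}) from generated limbs.

    The bone's adjacent joint centres (hip+knee for the femur, knee+ankle
    for the tibia) are appended as pseudo-vertices: a fitted bone then
    carries model-regressed joint-centre estimates, which is what allows
    the articulated reassembly to recover relative bone pose.
    """
    if bone == "femur":
        names = ("hip", "knee")
    elif bone == "tibia":
        names = ("knee", "ankle")
    else:
        raise ValueError("bone must be 'femur' or 'tibia'")
    shapes = [_bone_stack(l, bone) for l in limbs]
    model = build_ssm(shapes, variance_kept=variance_kept)
    model.pseudo_names = names
    return model


def _bone_stack(limb: ArticulatedLimb, bone: str) -> np.ndarray:
    names = ("hip", "knee") if bone == "femur" else ("knee", "ankle")
    return np.vstack(
        [np.asarray(getattr(limb, bone).vertices)]
        + [limb.landmarks[n][None, :] for n in names]
    )


def build_articulated_ssm(
    limbs: list[ArticulatedLimb], variance_kept: float = 0.98
) -> ArticulatedSSM:
    """Whole-limb articulated model: femur + tibia + landmark points.

    Landmarks ride along as pseudo-vertices so a twin's joint centres —
    and hence its alignment — are part of the model-predicted shape.
    """
    ref = limbs[0]
    names = ("hip", "knee", "ankle")
    shapes = []
    for l in limbs:
        lm = np.vstack([l.landmarks[n] for n in names])
        shapes.append(np.vstack([l.femur.vertices, l.tibia.vertices, lm]))
    base = build_ssm(shapes, variance_kept=variance_kept)
    return ArticulatedSSM(
        mean_shape=base.mean_shape,
        modes=base.modes,
        mode_variances=base.mode_variances,
        n_training=base.n_training,
        total_variance=base.total_variance,
        n_femur=len(ref.femur.vertices),
        n_tibia=len(ref.tibia.vertices),
        landmark_names=names,
        femur_faces=np.asarray(ref.femur.faces),
        tibia_faces=np.asarray(ref.tibia.faces),
        axes={k: v.copy() for k, v in ref.axes.items()},
        femur_cap_ids=ref.femur_cap_ids,
        tibia_cap_ids=ref.tibia_cap_ids,
        cap_uv=ref.cap_uv,
    )


def build_twin_models(
    limbs: list[ArticulatedLimb], variance_kept: float = 0.98
) -> tuple[ShapeModel, ShapeModel, ArticulatedSSM]:
    """Build per-bone and articulated models plus the reassembly map.

    The reassembly map is a least-squares regression, over the training
    limbs, from the concatenated per-bone loading vectors (plus an
    intercept) onto the articulated loadings.  It encodes how relative
    bone pose co-varies with bone shape in the healthy population, which
    is what lets :func:`reconstruct_twin` restore a twin's alignment
    from the two individually fitted bones.
    """
    femur_model = build_bone_ssm(limbs, "femur", variance_kept)
    tibia_model = build_bone_ssm(limbs, "tibia", variance_kept)
    articulated = build_articulated_ssm(limbs, variance_kept)
    CF = np.vstack([project_shape(femur_model, _bone_stack(l, "femur")) for l in limbs])
    CT = np.vstack([project_shape(tibia_model, _bone_stack(l, "tibia")) for l in limbs])
    names = articulated.landmark_names
    CA = np.vstack(
        [
            project_shape(
                articulated,
                np.vstack(
                    [l.femur.vertices, l.tibia.vertices]
                    + [l.landmarks[n][None, :] for n in names]
                ),
            )
            for l in limbs
        ]
    )
    X = np.column_stack([CF, CT, np.ones(len(limbs))])
    W, *_ = np.linalg.lstsq(X, CA, rcond=None)
    articulated.assembly_weights = W
    articulated.n_femur_modes = femur_model.n_modes
    articulated.n_tibia_modes = tibia_model.n_modes
    return femur_model, tibia_model, articulated


# ---------------------------------------------------------------------------
# Robust fitting
# ---------------------------------------------------------------------------


def robust_fit(
    model: ShapeModel,
    target,
    outlier_sd: float = 2.0,
    max_iter: int = 50,
    tol: float = 1e-4,
    rigid: bool = True,
    coeff_limit_sd: float = 3.0,
    burn_in: int = 3,
) -> FitResult:
    """Fit the SSM to a target surface with iterative outlier exclusion.

    Each iteration: (1) closest-point correspondence from every model
    vertex to the target, (2) flag pairs whose residual exceeds
    mean + ``outlier_sd``·SD of the residuals (one-sided: only
    protruding/distant pairs — disease artifacts — are excluded),
    (3) optional rigid re-alignment of the target into model space on
    the inlier pairs, (4) least-squares mode-coefficient update on the
    inliers, with loadings clamped to ±``coeff_limit_sd`` SD.  Stops
    when the relative coefficient change drops below ``tol``.

    Coefficients start from an isotropic size match (overall scale is
    typically the dominant mode, and closest-point correspondence alone
    carries a weak stretch signal), and outlier trimming is suspended
    for the first ``burn_in`` iterations so that large-but-genuine
    shape discrepancies are not discarded before the fit can absorb
    them.
    """
    if outlier_sd <= 0:
        raise ValueError("outlier_sd must be positive")
    pts = np.asarray(target.vertices if hasattr(target, "vertices") else target, dtype=float)
    if pts.size == 0:
        raise ValueError("empty target")

    k = model.n_modes
    ns = model.n_surface
    sd = np.sqrt(model.mode_variances)
    # initialize loadings with the best isotropic rescaling of the mean
    mean_s = model.mean_shape[:ns]
    mean_c = mean_s - mean_s.mean(0)
    rms_model = np.sqrt(np.mean(np.sum(mean_c**2, axis=1)))
    rms_target = np.sqrt(np.mean(np.sum((pts - pts.mean(0)) ** 2, axis=1)))
    s0 = rms_target / max(rms_model, 1e-12)
    c = model.modes[: 3 * ns].T @ ((s0 - 1.0) * mean_c).ravel()
    c = np.clip(c, -coeff_limit_sd * sd, coeff_limit_sd * sd)
    # initial rigid guess: centroid match
    R = np.eye(3)
    t = mean_s.mean(0) - pts.mean(0)

    idx = np.zeros(ns, dtype=int)
    mask = np.zeros(ns, dtype=bool)
    res = np.zeros(ns)
    rms_history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pred = model.synthesize(c)[:ns]
        tgt = pts @ R.T + t
        tree = cKDTree(tgt)
        res, idx = tree.query(pred)
        y = tgt[idx]
        mu, sig = float(res.mean()), float(res.std())
        if sig < 1e-12 or it <= burn_in:
            mask = np.zeros_like(mask)
        else:
            mask = res > mu + outlier_sd * sig
        inl = ~mask
        if not inl.any():
            raise RuntimeError("robust_fit failed: every vertex flagged as outlier")
        rms_history.append(float(np.sqrt(np.mean(res[inl] ** 2))))

        if rigid:
            Rn, tn = _kabsch(pts[idx[inl]], pred[inl])
            R, t = Rn, tn
            tgt = pts @ R.T + t
            y = tgt[idx]

        rows = np.repeat(inl, 3)
        A = model.modes[: 3 * ns][rows]
        b = (y - mean_s)[inl].ravel()
        c_new, *_ = np.linalg.lstsq(A, b, rcond=None)
        c_new = np.clip(c_new, -coeff_limit_sd * sd, coeff_limit_sd * sd)
        change = np.linalg.norm(c_new - c) / (np.linalg.norm(c) + 1e-9)
        c = c_new
        if change < tol and it > burn_in + 1:  # require ≥1 robust update
            converged = True
            break
    if not converged:
        warnings.warn("robust_fit did not converge within max_iter")

    pred = model.synthesize(c)
    return FitResult(
        coefficients=c,
        correspondence=idx,
        outlier_mask=mask,
        residuals=res,
        n_iterations=it,
        converged=converged,
        fitted_vertices=pred,
        rotation=R,
        translation=t,
        rms_history=rms_history,
        pseudo_names=model.pseudo_names,
    )


def project_shape(model: ShapeModel, shape: np.ndarray, align: bool = True) -> np.ndarray:
    """Non-robust loading vector of a corresponded shape (direct projection)."""
    x = np.asarray(shape, dtype=float)
    if align:
        R, t = _kabsch(x, model.mean_shape)
        x = x @ R.T + t
    return model.modes.T @ (x - model.mean_shape).ravel()


# ---------------------------------------------------------------------------
# Twin reassembly
# ---------------------------------------------------------------------------


def reconstruct_twin(
    femur_fit: FitResult,
    tibia_fit: FitResult,
    articulated_model: ArticulatedSSM,
) -> ArticulatedLimb:
    """Reassemble fitted femur and tibia via the articulated limb model.

    The articulated loadings of the twin are predicted from the two
    per-bone fit loadings through the reassembly regression learned on
    the articulated model's training limbs (see
    :func:`build_twin_models`).  The combined configuration is therefore
    the articulated-model shape whose per-bone components best match the
    individually fitted bones, and the relative bone pose comes from the
    healthy articulated model — pose/shape covariation in the healthy
    population — not from the diseased input.
    """
    if not (femur_fit.converged and tibia_fit.converged):
        warnings.warn("twin reconstruction from non-converged bone fits")
    am = articulated_model
    if am.assembly_weights is None:
        raise ValueError(
            "articulated model has no reassembly map; build it with build_twin_models"
        )
    kf, kt = am.n_femur_modes, am.n_tibia_modes
    if len(femur_fit.coefficients) != kf or len(tibia_fit.coefficients) != kt:
        raise ValueError("bone fits inconsistent with articulated model dimensions")
    x = np.concatenate([femur_fit.coefficients, tibia_fit.coefficients, [1.0]])
    c = x @ am.assembly_weights
    return limb_from_articulated(am, c)


def _gap_along_axis(limb: ArticulatedLimb) -> float:
    """Joint clearance projected on the hip-ankle axis (mm)."""
    if limb.femur_cap_ids is None or limb.tibia_cap_ids is None:
        return float("nan")
    axis = limb.landmarks["hip"] - limb.landmarks["ankle"]
    axis = axis / np.linalg.norm(axis)
    f = np.asarray(limb.femur.vertices)[limb.femur_cap_ids] @ axis
    t = np.asarray(limb.tibia.vertices)[limb.tibia_cap_ids] @ axis
    return float(f.min() - t.max())


def limb_from_articulated(
    model: ArticulatedSSM, coefficients: np.ndarray
) -> ArticulatedLimb:
    """Instantiate an :class:`ArticulatedLimb` from model loadings.

    Used to draw model-representable healthy cases (e.g. validation
    inputs) and to materialize reconstructed twins.
    """
    shape = model.synthesize(np.asarray(coefficients, dtype=float))
    f, t, lm = model.split_blocks(shape)
    limb = ArticulatedLimb(
        femur=trimesh.Trimesh(vertices=f, faces=model.femur_faces, process=False),
        tibia=trimesh.Trimesh(vertices=t, faces=model.tibia_faces, process=False),
        landmarks={n: lm[i].copy() for i, n in enumerate(model.landmark_names)},
        axes={k: v.copy() for k, v in model.axes.items()},
        params=None,
        joint_gap_mm=float("nan"),
        femur_cap_ids=model.femur_cap_ids,
        tibia_cap_ids=model.tibia_cap_ids,
        cap_uv=model.cap_uv,
    )
    limb.joint_gap_mm = _gap_along_axis(limb)
    return limb


def project_limb(model: ArticulatedSSM, limb: ArticulatedLimb) -> np.ndarray:
    """Articulated-model loadings of a corresponded limb (with landmarks)."""
    lm = np.vstack([limb.landmarks[n] for n in model.landmark_names])
    stack = np.vstack([limb.femur.vertices, limb.tibia.vertices, lm])
    return project_shape(model, stack, align=True)


# ---------------------------------------------------------------------------
# Alignment measurement
# ---------------------------------------------------------------------------


def classify_alignment(hka_deg: float) -> str:
    """Varus iff HKA ≥ 183°, valgus iff ≤ 177°, else neutral (inclusive)."""
    if hka_deg >= VARUS_MIN_DEG:
        return "varus"
    if hka_deg <= VALGUS_MAX_DEG:
        return "valgus"
    return "neutral"


def _limb_frame(limb: ArticulatedLimb) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intrinsic (medial m, posterior y, superior z) orthonormal frame."""
    h, a = limb.landmarks["hip"], limb.landmarks["ankle"]
    z = h - a
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ValueError("coincident hip/ankle landmarks")
    z = z / nz
    y = np.cross(z, limb.axes["medial"])
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ValueError("medial axis parallel to mechanical axis")
    y = y / ny
    m = np.cross(y, z)
    return m, y, z


def measure_alignment(limb: ArticulatedLimb) -> AlignmentProfile:
    """Alignment profile from landmarks and anatomical axes.

    The HKA angle is measured at the knee centre between the rays to the
    hip and ankle centres, projected onto the coronal plane (spanned by
    the mechanical axis and the medio-lateral axis); deviations towards
    varus are reported as HKA > 180°.  All quantities are intrinsic, so
    the profile is invariant to rigid transformation of the whole limb.
    """
    m, y, z = _limb_frame(limb)
    h, k, a = (limb.landmarks[n] for n in ("hip", "knee", "ankle"))
    if np.linalg.norm(h - k) < 1e-9 or np.linalg.norm(a - k) < 1e-9:
        raise ValueError("coincident landmarks")

    def proj(v):
        v = v - np.dot(v, y) * y
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise ValueError("degenerate coronal projection")
        return v / n

    u, w = proj(h - k), proj(a - k)
    ang = np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0)))
    bis = u + w
    sign = 1.0 if np.dot(bis, m) > 0 else -1.0
    hka = 180.0 + sign * (180.0 - ang)

    def transverse_angle(v_from, v_to):
        pf = v_from - np.dot(v_from, z) * z
        pt = v_to - np.dot(v_to, z) * z
        if np.linalg.norm(pf) < 1e-12 or np.linalg.norm(pt) < 1e-12:
            return 0.0
        pf, pt = pf / np.linalg.norm(pf), pt / np.linalg.norm(pt)
        s = np.dot(np.cross(pf, pt), z)
        cang = np.clip(np.dot(pf, pt), -1.0, 1.0)
        return float(np.degrees(np.arctan2(s, cang)))

    fem_tor = transverse_angle(limb.axes["femoral_condylar"], limb.axes["femoral_neck"])
    tib_tor = transverse_angle(m, limb.axes["tibial_ankle"])
    n = limb.axes["tibial_plateau_normal"]
    slope = float(np.degrees(np.arctan2(-np.dot(n, y), np.dot(n, z))))
    bow = _measure_bowing(limb, m, z)
    return AlignmentProfile(
        hka_deg=float(hka),
        femoral_torsion_deg=fem_tor,
        tibial_torsion_deg=tib_tor,
        tibial_slope_deg=slope,
        bowing_deg=bow,
        varus_valgus_class=classify_alignment(float(hka)),
    )


def _measure_bowing(limb: ArticulatedLimb, m: np.ndarray, z: np.ndarray) -> float:
    """Coronal femoral shaft bow from the mid-shaft chord deviation."""
    h, k = limb.landmarks["hip"], limb.landmarks["knee"]
    chord = h - k
    L = np.linalg.norm(chord)
    if L < 1e-9:
        return 0.0
    d = chord / L
    V = np.asarray(limb.femur.vertices) - k
    s = V @ d
    lateral = V @ m - (s * np.dot(d, m))
    mid = (s > 0.35 * L) & (s < 0.65 * L)
    if not mid.any():
        return 0.0
    dev = -float(np.mean(lateral[mid]))  # lateral = −medial direction
    return float(np.degrees(np.arcsin(np.clip(4.0 * dev / L, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Score normalization and sampling
# ---------------------------------------------------------------------------


def mahalanobis_normalize(scores: np.ndarray, model: ShapeModel) -> np.ndarray:
    """Divide each mode loading by that mode's standard deviation.

    Damps dominant unrelated variance (size) so modes contribute on a
    comparable scale.  Scores drawn from the model become unit-variance
    per mode.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    k = scores.shape[1]
    var = model.mode_variances[:k]
    if np.any(var <= 0):
        raise ValueError("zero-variance mode requested in Mahalanobis normalization")
    out = scores / np.sqrt(var)
    return out[0] if out.shape[0] == 1 and np.asarray(scores).ndim == 1 else out


def sample_model(
    model: ShapeModel, n: int, rng: np.random.Generator, sd_clip: float = 3.0
) -> np.ndarray:
    """Draw n loading vectors from the model's Gaussian, clipped at ±sd_clip SD."""
    sd = np.sqrt(model.mode_variances)
    c = rng.normal(0.0, 1.0, size=(n, model.n_modes)) * sd
    return np.clip(c, -sd_clip * sd, sd_clip * sd)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: ShapeModel, path) -> None:
    extra = {}
    if isinstance(model, ArticulatedSSM):
        extra = dict(
            n_femur=model.n_femur,
            n_tibia=model.n_tibia,
            femur_faces=model.femur_faces,
            tibia_faces=model.tibia_faces,
            femur_cap_ids=model.femur_cap_ids,
            tibia_cap_ids=model.tibia_cap_ids,
            cap_uv=model.cap_uv,
            axes_names=np.array(list(model.axes)),
            axes_vectors=np.vstack(list(model.axes.values())) if model.axes else np.zeros((0, 3)),
        )
        if model.assembly_weights is not None:
            extra.update(
                assembly_weights=model.assembly_weights,
                n_femur_modes=model.n_femur_modes,
                n_tibia_modes=model.n_tibia_modes,
            )
    np.savez(
        path,
        mean=model.mean_shape,
        modes=model.modes,
        variances=model.mode_variances,
        n_training=model.n_training,
        total_variance=model.total_variance,
        pseudo_names=np.array(model.pseudo_names),
        **extra,
    )


def load_model(path) -> ShapeModel:
    z = np.load(path, allow_pickle=False)
    base = dict(
        mean_shape=z["mean"],
        modes=z["modes"],
        mode_variances=z["variances"],
        n_training=int(z["n_training"]),
        total_variance=float(z["total_variance"]),
        pseudo_names=tuple(str(n) for n in z["pseudo_names"]) if "pseudo_names" in z else (),
    )
    if "n_femur" in z:
        axes = {
            str(n): v for n, v in zip(z["axes_names"], z["axes_vectors"])
        }
        model = ArticulatedSSM(
            **base,
            n_femur=int(z["n_femur"]),
            n_tibia=int(z["n_tibia"]),
            femur_faces=z["femur_faces"],
            tibia_faces=z["tibia_faces"],
            femur_cap_ids=z["femur_cap_ids"],
            tibia_cap_ids=z["tibia_cap_ids"],
            cap_uv=z["cap_uv"],
            axes=axes,
        )
        if "assembly_weights" in z:
            model.assembly_weights = z["assembly_weights"]
            model.n_femur_modes = int(z["n_femur_modes"])
            model.n_tibia_modes = int(z["n_tibia_modes"])
        return model
    return ShapeModel(**base)


def fit_summary_json(fit: FitResult, path) -> None:
    """JSON summary of a fit (counts and error statistics, not arrays)."""
    with open(path, "w") as fh:
        json.dump(
            {
                "n_modes": int(len(fit.coefficients)),
                "n_iterations": fit.n_iterations,
                "converged": bool(fit.converged),
                "n_outliers": int(fit.outlier_mask.sum()),
                "rms_inlier_mm": fit.rms_history[-1] if fit.rms_history else None,
                "coefficients": fit.coefficients.tolist(),
            },
            fh,
            indent=2,
        )
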