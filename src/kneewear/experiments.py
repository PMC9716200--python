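"""End-to-end experiment harnesses on synthetic cohorts.

Four studies mirror the analysis workflow on generated data with known
ground truth:

1. **Synthetic validation** — healthy limbs are artificially given
   osteophyte-like outliers, joint-space narrowing and coronal
   misalignment; the twin-reconstruction pipeline is run and scored
   against the pre-deformation geometry (RMS vertex error, coronal
   angular error).
2. **Wear–geometry study** — wear patterns are planted with a known
   correlation to limb alignment; the full chain (arthritis → twin →
   wear map → PPAE → CCA against twin shape loadings) must recover the
   planted association.
3. **Morphology risk benchmark** — an "at-risk" phenotype population is
   generated with shifted limb parameters; twins of its arthritic limbs
   are classified against healthy controls with LOOCV-LDA.
4. **Negative control** — healthy controls are randomly deformed and
   reconstructed; the classifier comparing their twins with untouched
   controls must find no signal, establishing that the reconstruction
   pipeline itself injects no phenotype information.

Problem sizes default to desk scale (hundreds of vertices per bone,
tens-to-hundreds of cases) so each harness completes in seconds to a
few minutes on one CPU.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import jsw_mapping as jm
from . import morpho_stats as ms
from . import ppae as pp
from . import synthetic_cohort as sc
from . import ssm_twin as st

__all__ = [
    "ExperimentConfig",
    "ValidationReport",
    "run_synthetic_validation",
    "run_wear_geometry_study",
    "run_risk_benchmark",
    "run_negative_control",
]


@dataclass
class ExperimentConfig:
    """Shared configuration of the four harnesses (fully serializable)."""

    seed: int = 0
    n_train: int = 25  # healthy limbs underpinning the SSMs
    n_cases: int = 50
    resolution: int = 350  # vertex budget per bone
    variance_kept: float = 1.0
    # arthritic degradation
    osteophyte_fraction: float = 0.05
    osteophyte_mm: float = 3.0
    narrowing_mm: float = 1.5
    misalignment_max_deg: float = 5.0
    # wear study
    planted_r: float = 0.5
    wear_depth_mm: float = 3.5
    wear_noise_sd: float = 0.02
    # size and tibial slope are standardized in the wear-study cohort so
    # that the planted wear↔alignment link is the only systematic
    # geometry↔wear association (both otherwise shape the baseline
    # joint-space map and would confound the recovery measurement)
    wear_study_scale_sd: float = 0.0
    wear_study_slope_sd: float = 0.0
    image_size: int = 32
    latent_dim: int = 15
    poly_degree: int = 2
    ae_hidden: int = 128
    ae_epochs: int = 200
    # risk benchmark phenotype shift (in SD units of the healthy spread)
    phenotype_shift_sd: float = 2.0
    # statistics
    n_permutations: int = 200
    n_shape_features: int = 8
    reference_mm: float = jm.DEFAULT_REFERENCE_MM

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ValidationReport:
    rms_mm: float
    rms_femur_mm: float
    rms_tibia_mm: float
    coronal_abs_err_deg: float
    per_case: pd.DataFrame
    n_failed: int = 0
    config_hash: str = ""

    def to_dict(self) -> dict:
        return {
            "rms_mm": self.rms_mm,
            "rms_femur_mm": self.rms_femur_mm,
            "rms_tibia_mm": self.rms_tibia_mm,
            "coronal_abs_err_deg": self.coronal_abs_err_deg,
            "n_cases": int(len(self.per_case)),
            "n_failed": self.n_failed,
            "config_hash": self.config_hash,
        }


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------


def _seed_ladder(seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds below 2^31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def build_models(cfg: ExperimentConfig, seed: int):
    """Healthy per-bone and articulated SSMs from generated training limbs."""
    seeds = _seed_ladder(seed, cfg.n_train + 1)
    rng = np.random.default_rng(seeds[0])
    limbs = [
        sc.generate_limb(sc.sample_limb_params(rng), cfg.resolution, seed=s)
        for s in seeds[1:]
    ]
    femur_model, tibia_model, articulated = st.build_twin_models(
        limbs, cfg.variance_kept
    )
    return femur_model, tibia_model, articulated, limbs


def reconstruct_case(
    arthritic: sc.ArticulatedLimb,
    femur_model: st.ShapeModel,
    tibia_model: st.ShapeModel,
    articulated: st.ArticulatedSSM,
) -> tuple[sc.ArticulatedLimb, st.FitResult, st.FitResult]:
    """Robust per-bone fit followed by articulated reassembly."""
    ffit = st.robust_fit(femur_model, arthritic.femur)
    tfit = st.robust_fit(tibia_model, arthritic.tibia)
    twin = st.reconstruct_twin(ffit, tfit, articulated)
    return twin, ffit, tfit


def _aligned_rms(a: np.ndarray, b: np.ndarray) -> float:
    """RMS vertex distance after rigid alignment (shape error only)."""
    R, t = st._kabsch(a, b)
    d = a @ R.T + t - b
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))


# ---------------------------------------------------------------------------
# 1. Synthetic validation of twin reconstruction
# ---------------------------------------------------------------------------


def run_synthetic_validation(cfg: ExperimentConfig) -> ValidationReport:
    """Deform model-representable healthy limbs, reconstruct, score.

    Validation cases are fresh draws from the healthy articulated model
    (new loading vectors, not training samples), so with zero imposed
    deformity the pipeline must return them near-exactly; with imposed
    osteophytes/narrowing/misalignment the report quantifies the
    residual RMS and coronal angular error against ground truth.
    """
    femur_model, tibia_model, articulated, _ = build_models(cfg, cfg.seed)
    seeds = _seed_ladder(cfg.seed + 1, 2)
    rng = np.random.default_rng(seeds[0])
    rows = []
    n_failed = 0
    for i in range(cfg.n_cases):
        coeffs = st.sample_model(articulated, 1, rng)[0]
        healthy = st.limb_from_articulated(articulated, coeffs)
        true_hka = st.measure_alignment(healthy).hka_deg
        angle = (
            rng.uniform(-cfg.misalignment_max_deg, cfg.misalignment_max_deg)
            if cfg.misalignment_max_deg > 0
            else 0.0
        )
        omap = (
            sc.random_outlier_map(
                healthy, cfg.osteophyte_fraction, cfg.osteophyte_mm,
                seed=int(rng.integers(2**31 - 1)),
            )
            if cfg.osteophyte_mm > 0 and cfg.osteophyte_fraction > 0
            else None
        )
        narrow = min(cfg.narrowing_mm, max(healthy.joint_gap_mm - 0.5, 0.0))
        arthritic, _rec = sc.impose_arthritis(
            healthy, omap, narrowing_mm=narrow, extra_varus_deg=angle
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                twin, ffit, tfit = reconstruct_case(
                    arthritic, femur_model, tibia_model, articulated
                )
        except RuntimeError:
            n_failed += 1
            continue
        twin_hka = st.measure_alignment(twin).hka_deg
        rms_f = _aligned_rms(np.asarray(twin.femur.vertices), np.asarray(healthy.femur.vertices))
        rms_t = _aligned_rms(np.asarray(twin.tibia.vertices), np.asarray(healthy.tibia.vertices))
        rows.append(
            dict(
                case=i,
                rms_femur_mm=rms_f,
                rms_tibia_mm=rms_t,
                true_hka_deg=true_hka,
                imposed_misalignment_deg=angle,
                twin_hka_deg=twin_hka,
                coronal_err_deg=twin_hka - true_hka,
                n_outliers_femur=int(ffit.outlier_mask.sum()),
                n_outliers_tibia=int(tfit.outlier_mask.sum()),
            )
        )
    per_case = pd.DataFrame(rows)
    if per_case.empty:
        raise RuntimeError("all validation cases failed to fit")
    rms_f = float(np.sqrt(np.mean(per_case.rms_femur_mm**2)))
    rms_t = float(np.sqrt(np.mean(per_case.rms_tibia_mm**2)))
    return ValidationReport(
        rms_mm=float(np.sqrt((rms_f**2 + rms_t**2) / 2.0)),
        rms_femur_mm=rms_f,
        rms_tibia_mm=rms_t,
        coronal_abs_err_deg=float(per_case.coronal_err_deg.abs().mean()),
        per_case=per_case,
        n_failed=n_failed,
        config_hash=cfg.config_hash(),
    )


# ---------------------------------------------------------------------------
# 2. Wear-pattern / geometry correlation study
# ---------------------------------------------------------------------------


def _template_cap_param(articulated: st.ArticulatedSSM) -> jm.SquareParam:
    """Flatten the mean femoral articular cap once for the whole cohort."""
    mean_f, _, _ = articulated.split_blocks(articulated.mean_shape)
    cap = articulated.femur_cap_ids
    faces = articulated.femur_faces
    fmask = np.all(np.isin(faces, cap), axis=1)
    remap = -np.ones(int(faces.max()) + 1, dtype=int)
    remap[cap] = np.arange(len(cap))
    sub_faces = remap[faces[fmask]]
    return jm.conformal_flatten(mean_f[cap], sub_faces)


def run_wear_geometry_study(cfg: ExperimentConfig) -> dict:
    """Recover a planted wear↔alignment correlation through the full chain.

    Medial-wear loading is generated with correlation ``planted_r`` to
    the (standardized) HKA angle; wear is carved into the femoral
    articular surface, the limb is additionally degraded and the twin
    reconstructed; the PPAE component scores of the resulting wear
    images are canonically correlated against the twin's
    Mahalanobis-normalized shape loadings.
    """
    femur_model, tibia_model, articulated, _ = build_models(cfg, cfg.seed)
    param = _template_cap_param(articulated)
    seeds = _seed_ladder(cfg.seed + 2, 2)
    rng = np.random.default_rng(seeds[0])
    hka_sd = 2.5
    rho = cfg.planted_r

    images, loadings, planted_z, planted_noise = [], [], [], []
    for i in range(cfg.n_cases):
        params = sc.sample_limb_params(
            rng, slope_sd=cfg.wear_study_slope_sd, scale_sd=cfg.wear_study_scale_sd
        )
        limb = sc.generate_limb(params, cfg.resolution, seed=int(rng.integers(2**31 - 1)))
        z = (params.hka_deg - 180.0) / hka_sd
        eps = rng.normal()
        w_med = np.clip(0.55 + 0.22 * (rho * z + np.sqrt(max(1 - rho**2, 0.0)) * eps), 0.0, 1.2)
        weights = np.array([w_med, 0.15, 0.0, 0.0, 0.1])
        wear = sc.wear_field_from_weights(
            weights, limb.cap_uv, noise_sd=cfg.wear_noise_sd, rng=rng
        )
        depth = wear * cfg.wear_depth_mm
        angle = rng.uniform(-cfg.misalignment_max_deg, cfg.misalignment_max_deg)
        omap = sc.random_outlier_map(
            limb, cfg.osteophyte_fraction, cfg.osteophyte_mm,
            seed=int(rng.integers(2**31 - 1)),
        )
        narrow = min(cfg.narrowing_mm, max(limb.joint_gap_mm - cfg.wear_depth_mm - 0.5, 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arthritic, _ = sc.impose_arthritis(
                limb, omap, narrowing_mm=narrow, extra_varus_deg=angle,
                wear_depth_mm=depth,
            )
            twin, ffit, tfit = reconstruct_case(
                arthritic, femur_model, tibia_model, articulated
            )
            img = jm.wear_image_pipeline(
                arthritic, param, cfg.reference_mm, cfg.image_size
            )
        images.append(img)
        loadings.append(st.project_limb(articulated, twin))
        planted_z.append(z)
        planted_noise.append(eps)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = pp.train(
            pp.augment(images),
            latent_dim=cfg.latent_dim,
            hidden=cfg.ae_hidden,
            epochs=cfg.ae_epochs,
            seed=seeds[1],
        )
        comps, model = pp.fit_polynomial_bottleneck(model, images, cfg.poly_degree)

    x = comps.scores  # all decorrelated components enter the CCA block
    y = st.mahalanobis_normalize(
        np.vstack(loadings)[:, : cfg.n_shape_features], articulated
    )
    res = ms.cca(x, y, n_permutations=cfg.n_permutations, seed=seeds[1])
    return {
        "planted_r": rho,
        "recovered_r": float(res.r1),
        "canonical_correlations": res.canonical_correlations.tolist(),
        "p_value": None if res.p_values is None else float(res.p_values[0]),
        "variance_fraction": comps.variance_fraction.tolist(),
        "cumulative_fraction_4": float(comps.cumulative_fraction[min(3, comps.n_components - 1)]),
        "config_hash": cfg.config_hash(),
        "cca": res,
        "components": comps,
    }


# ---------------------------------------------------------------------------
# 3. Morphology-based risk benchmark
# ---------------------------------------------------------------------------


def _risk_populations(cfg: ExperimentConfig, rng: np.random.Generator):
    """Per-case (params, sex) for control and at-risk populations.

    The at-risk phenotype shifts HKA towards varus and increases tibial
    slope by ``phenotype_shift_sd`` SDs (split over the two features),
    the morphotype the wear analysis associates with medial OA; effect
    is applied identically for both sexes unless stratified downstream.
    """
    shift = cfg.phenotype_shift_sd / np.sqrt(2.0)
    controls, risks = [], []
    for _ in range(cfg.n_cases):
        sex = "female" if rng.random() < 0.5 else "male"
        controls.append((sc.sample_limb_params(rng), sex))
        sex2 = "female" if rng.random() < 0.5 else "male"
        p = sc.sample_limb_params(rng, hka_mean=180.0 + shift * 2.5, slope_mean=7.0 + shift * 2.5)
        risks.append((p, sex2))
    return controls, risks


def run_risk_benchmark(cfg: ExperimentConfig) -> ms.ClassifierReport:
    """LOOCV-LDA of twin shape loadings: at-risk twins vs healthy controls.

    Controls are healthy limbs whose loadings are obtained by direct
    projection on the articulated model; the at-risk population is
    degraded arthritically and passed through the full twin pipeline, so
    the classifier sees only reconstructed pre-disease geometry.
    """
    femur_model, tibia_model, articulated, _ = build_models(cfg, cfg.seed)
    seeds = _seed_ladder(cfg.seed + 3, 2)
    rng = np.random.default_rng(seeds[0])
    controls, risks = _risk_populations(cfg, rng)

    feats, labels, sexes = [], [], []
    for params, sex in controls:
        limb = sc.generate_limb(params, cfg.resolution, seed=int(rng.integers(2**31 - 1)))
        feats.append(st.project_limb(articulated, limb))
        labels.append(0)
        sexes.append(sex)
    for params, sex in risks:
        limb = sc.generate_limb(params, cfg.resolution, seed=int(rng.integers(2**31 - 1)))
        angle = rng.uniform(-cfg.misalignment_max_deg, cfg.misalignment_max_deg)
        omap = sc.random_outlier_map(
            limb, cfg.osteophyte_fraction, cfg.osteophyte_mm,
            seed=int(rng.integers(2**31 - 1)),
        )
        narrow = min(cfg.narrowing_mm, max(limb.joint_gap_mm - 0.5, 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arthritic, _ = sc.impose_arthritis(
                limb, omap, narrowing_mm=narrow, extra_varus_deg=angle
            )
            twin, _, _ = reconstruct_case(
                arthritic, femur_model, tibia_model, articulated
            )
        feats.append(st.project_limb(articulated, twin))
        labels.append(1)
        sexes.append(sex)

    X = st.mahalanobis_normalize(
        np.vstack(feats)[:, : cfg.n_shape_features], articulated
    )
    return ms.lda_risk(X, np.asarray(labels), sex=np.asarray(sexes))


# ---------------------------------------------------------------------------
# 4. Negative control
# ---------------------------------------------------------------------------


def run_negative_control(cfg: ExperimentConfig) -> ms.ClassifierReport:
    """Twins of randomly deformed healthy limbs vs untouched controls.

    Both groups are drawn from the same healthy distribution and the
    deformities are independent of morphotype, so any detectable signal
    would be an artifact of the reconstruction pipeline.
    """
    femur_model, tibia_model, articulated, _ = build_models(cfg, cfg.seed)
    seeds = _seed_ladder(cfg.seed + 4, 2)
    rng = np.random.default_rng(seeds[0])

    feats, labels = [], []
    for _ in range(cfg.n_cases):
        limb = sc.generate_limb(
            sc.sample_limb_params(rng), cfg.resolution, seed=int(rng.integers(2**31 - 1))
        )
        feats.append(st.project_limb(articulated, limb))
        labels.append(0)
    for _ in range(cfg.n_cases):
        limb = sc.generate_limb(
            sc.sample_limb_params(rng), cfg.resolution, seed=int(rng.integers(2**31 - 1))
        )
        angle = rng.uniform(-cfg.misalignment_max_deg, cfg.misalignment_max_deg)
        omap = sc.random_outlier_map(
            limb, cfg.osteophyte_fraction, cfg.osteophyte_mm,
            seed=int(rng.integers(2**31 - 1)),
        )
        narrow = min(cfg.narrowing_mm, max(limb.joint_gap_mm - 0.5, 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arthritic, _ = sc.impose_arthritis(
                limb, omap, narrowing_mm=narrow, extra_varus_deg=angle
            )
            twin, _, _ = reconstruct_case(
                arthritic, femur_model, tibia_model, articulated
            )
        feats.append(st.project_limb(articulated, twin))
        labels.append(1)

    X = st.mahalanobis_normalize(
        np.vstack(feats)[:, : cfg.n_shape_features], articulated
    )
    return ms.lda_risk(X, np.asarray(labels))
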