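import warnings

import numpy as np
import pytest

from kneewear import experiments as ex
from kneewear import synthetic_cohort as sc
from kneewear import ssm_twin as st


def _aligned_rms(a, b):
    R, t = st._kabsch(np.asarray(a), np.asarray(b))
    return float(np.sqrt(np.mean(np.sum((np.asarray(a) @ R.T + t - b) ** 2, axis=1))))


class TestBuildSSM:
    def test_rank_with_two_identical_shapes(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(40, 3))
        other = base + rng.normal(0, 0.5, size=(40, 3))
        model = st.build_ssm([base, base.copy(), other], variance_kept=1.0, align=False)
        assert model.n_modes == 1

    def test_known_linear_subspace_recovered(self):
        # oracle: shapes built from an explicit 4-mode linear generator
        rng = np.random.default_rng(1)
        V = 60
        mean = rng.normal(size=3 * V)
        basis, _ = np.linalg.qr(rng.normal(size=(3 * V, 4)))
        shapes = [
            (mean + basis @ rng.normal(0, [8, 4, 2, 1])).reshape(V, 3) for _ in range(30)
        ]
        model = st.build_ssm(shapes, variance_kept=1.0, align=False)
        assert model.n_modes == 4
        from scipy.linalg import subspace_angles

        ang = subspace_angles(model.modes, basis).max()
        assert ang < 1e-6

    def test_full_variance_kept_sums_to_one(self):
        rng = np.random.default_rng(2)
        shapes = [rng.normal(size=(30, 3)) for _ in range(8)]
        model = st.build_ssm(shapes, variance_kept=1.0, align=False)
        assert abs(model.explained_fraction().sum() - 1.0) < 1e-12

    def test_training_shape_reconstructed_exactly(self):
        rng = np.random.default_rng(3)
        shapes = [rng.normal(scale=5.0, size=(25, 3)) for _ in range(6)]
        model = st.build_ssm(shapes, variance_kept=1.0, align=True)
        aligned = st.generalized_procrustes([s - s.mean(0) for s in shapes])
        x = aligned[2]
        c = model.modes.T @ (x - model.mean_shape).ravel()
        assert np.allclose(model.synthesize(c), x, atol=1e-9)

    def test_modes_orthonormal(self, models_bundle):
        fm, tm, am, _ = models_bundle
        for m in (fm, tm, am):
            G = m.modes.T @ m.modes
            assert np.allclose(G, np.eye(m.n_modes), atol=1e-8)
            assert np.all(np.diff(m.mode_variances) <= 1e-12)

    def test_mismatched_vertex_counts_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="vertex count"):
            st.build_ssm([rng.normal(size=(10, 3)), rng.normal(size=(11, 3)), rng.normal(size=(10, 3))])
        with pytest.raises(ValueError, match="at least 3"):
            st.build_ssm([rng.normal(size=(10, 3))] * 2)


class TestRobustFit:
    def test_mean_shape_target_gives_null_fit(self, models_bundle):
        fm, _, _, _ = models_bundle
        target = fm.mean_shape[: fm.n_surface]
        fit = st.robust_fit(fm, target, rigid=False)
        sd = np.sqrt(fm.mode_variances)
        assert np.all(np.abs(fit.coefficients) < 0.02 * sd + 1e-6)
        assert fit.outlier_mask.sum() == 0

    def test_known_sample_coefficients_recovered(self, models_bundle):
        fm, _, am, _ = models_bundle
        rng = np.random.default_rng(5)
        c_true = st.sample_model(fm, 1, rng)[0]
        target = fm.synthesize(c_true)[: fm.n_surface]
        fit = st.robust_fit(fm, target)
        big = np.abs(c_true) > 0.5 * np.sqrt(fm.mode_variances)
        rel = np.abs(fit.coefficients[big] - c_true[big]) / np.abs(c_true[big])
        assert np.all(rel < 0.01)

    def test_outlier_vertices_flagged_and_robustness(self, models_bundle):
        fm, tm, am, _ = models_bundle
        rng = np.random.default_rng(6)
        flagged = total = 0
        for trial in range(3):
            healthy = st.limb_from_articulated(am, st.sample_model(am, 1, rng)[0])
            omap = sc.random_outlier_map(healthy, 0.05, 3.0, seed=trial)
            art, _ = sc.impose_arthritis(healthy, omap)
            nF = len(healthy.femur.vertices)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ffit = st.robust_fit(fm, art.femur)
                tfit = st.robust_fit(tm, art.tibia)
            bf = np.flatnonzero(omap[:nF] > 0)
            bt = np.flatnonzero(omap[nF:] > 0)
            flagged += ffit.outlier_mask[bf].sum() + tfit.outlier_mask[bt].sum()
            total += len(bf) + len(bt)
            # robust recovery beats the non-robust fit (outlier_sd -> inf)
            c_true = st.project_shape(fm, st._bone_stack(healthy, "femur"))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c_plain = st.robust_fit(fm, art.femur, outlier_sd=1e9).coefficients
            assert np.linalg.norm(ffit.coefficients - c_true) < np.linalg.norm(
                c_plain - c_true
            )
        assert flagged / total >= 0.9

    def test_inlier_rms_monotone_after_burn_in(self, models_bundle):
        fm, _, am, _ = models_bundle
        rng = np.random.default_rng(7)
        for trial in range(4):
            healthy = st.limb_from_articulated(am, st.sample_model(am, 1, rng)[0])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = st.robust_fit(fm, healthy.femur)
            h = np.asarray(fit.rms_history)
            assert np.all(np.diff(h) <= 1e-6 + 0.02 * h[:-1])

    def test_outlier_sd_infinite_matches_projection(self, models_bundle):
        fm, _, _, _ = models_bundle
        rng = np.random.default_rng(8)
        for _ in range(5):
            c_true = st.sample_model(fm, 1, rng)[0]
            target = fm.synthesize(c_true)[: fm.n_surface]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = st.robust_fit(fm, target, outlier_sd=1e9, rigid=False)
            # oracle: direct least-squares projection with index correspondence
            c_proj = fm.modes[: 3 * fm.n_surface].T @ (target - fm.mean_shape[: fm.n_surface]).ravel()
            assert np.linalg.norm(fit.coefficients - c_proj) < 5e-2 * (
                1 + np.linalg.norm(c_proj)
            )
            # and shape-space equivalence to well below a millimetre
            assert _aligned_rms(fm.synthesize(fit.coefficients)[: fm.n_surface], target) < 0.2

    def test_all_outliers_is_error(self, models_bundle):
        fm, _, _, _ = models_bundle
        rng = np.random.default_rng(9)
        with pytest.raises((RuntimeError, ValueError)):
            st.robust_fit(fm, rng.normal(size=(0, 3)))


class TestTwinReconstruction:
    def test_identity_roundtrip(self, models_bundle):
        fm, tm, am, _ = models_bundle
        rng = np.random.default_rng(10)
        healthy = st.limb_from_articulated(am, st.sample_model(am, 1, rng)[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            twin, _, _ = ex.reconstruct_case(healthy, fm, tm, am)
        assert _aligned_rms(twin.femur.vertices, healthy.femur.vertices) < 0.3
        d_hka = st.measure_alignment(twin).hka_deg - st.measure_alignment(healthy).hka_deg
        assert abs(d_hka) < 0.3

    def test_misalignment_removed(self, models_bundle):
        fm, tm, am, _ = models_bundle
        rng = np.random.default_rng(11)
        healthy = st.limb_from_articulated(am, st.sample_model(am, 1, rng)[0])
        pre_hka = st.measure_alignment(healthy).hka_deg
        omap = sc.random_outlier_map(healthy, 0.05, 3.0, seed=2)
        art, _ = sc.impose_arthritis(healthy, omap, narrowing_mm=1.0, extra_varus_deg=5.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            twin, _, _ = ex.reconstruct_case(art, fm, tm, am)
        assert abs(st.measure_alignment(twin).hka_deg - pre_hka) < 2.0

    def test_missing_assembly_map_rejected(self, models_bundle):
        fm, tm, am, limbs = models_bundle
        bare = st.build_articulated_ssm(limbs, 1.0)
        rng = np.random.default_rng(12)
        healthy = st.limb_from_articulated(am, st.sample_model(am, 1, rng)[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ffit = st.robust_fit(fm, healthy.femur)
            tfit = st.robust_fit(tm, healthy.tibia)
        with pytest.raises(ValueError, match="reassembly"):
            st.reconstruct_twin(ffit, tfit, bare)


class TestAlignment:
    def test_collinear_landmarks_neutral(self):
        limb = sc.generate_limb(sc.LimbParams(hka_deg=180.0), 300, seed=0)
        prof = st.measure_alignment(limb)
        assert abs(prof.hka_deg - 180.0) < 1e-6
        assert prof.varus_valgus_class == "neutral"

    @pytest.mark.parametrize(
        "hka,cls",
        [(183.0, "varus"), (177.0, "valgus"), (182.9, "neutral"), (177.1, "neutral"), (174.0, "valgus")],
    )
    def test_boundary_classification_inclusive(self, hka, cls):
        assert st.classify_alignment(hka) == cls

    def test_constructed_174_degrees(self):
        limb = sc.generate_limb(sc.LimbParams(hka_deg=174.0), 300, seed=1, shape_noise_mm=0.0)
        prof = st.measure_alignment(limb)
        assert abs(prof.hka_deg - 174.0) < 1e-6
        assert prof.varus_valgus_class == "valgus"

    def test_rigid_invariance(self):
        limb = sc.generate_limb(
            sc.LimbParams(hka_deg=184.0, tibial_slope_deg=7.0, femoral_torsion_deg=12.0),
            300,
            seed=2,
        )
        p0 = st.measure_alignment(limb)
        M = np.eye(4)
        M[:3, :3] = sc._rotation([0.3, 0.5, 0.81], 33.0)
        M[:3, 3] = [120.0, -40.0, 77.0]
        p1 = st.measure_alignment(limb.transformed(M))
        assert np.allclose(p0.as_vector(), p1.as_vector(), atol=1e-6)

    def test_coincident_landmarks_rejected(self):
        limb = sc.generate_limb(sc.LimbParams(), 300, seed=0)
        limb.landmarks["hip"] = limb.landmarks["ankle"].copy()
        with pytest.raises(ValueError):
            st.measure_alignment(limb)


class TestMahalanobis:
    def test_unit_loadings(self, models_bundle):
        fm, _, _, _ = models_bundle
        one_sd = np.sqrt(fm.mode_variances)
        out = st.mahalanobis_normalize(one_sd[None, :], fm)
        assert np.allclose(out, 1.0)
        assert np.all(st.mahalanobis_normalize(np.zeros((1, fm.n_modes)), fm) == 0)

    def test_model_sampled_variance_is_unit(self, models_bundle):
        fm, _, _, _ = models_bundle
        rng = np.random.default_rng(13)
        scores = st.sample_model(fm, 1000, rng, sd_clip=10.0)
        z = st.mahalanobis_normalize(scores, fm)
        assert np.all(np.abs(z.var(axis=0) - 1.0) < 0.1)

    def test_zero_variance_mode_rejected(self):
        m = st.ShapeModel(
            mean_shape=np.zeros((4, 3)),
            modes=np.eye(12)[:, :2],
            mode_variances=np.array([1.0, 0.0]),
            n_training=3,
        )
        with pytest.raises(ValueError):
            st.mahalanobis_normalize(np.ones((2, 2)), m)


def test_model_io_roundtrip(tmp_path, models_bundle):
    fm, _, am, _ = models_bundle
    st.save_model(fm, tmp_path / "bone.npz")
    st.save_model(am, tmp_path / "art.npz")
    fm2 = st.load_model(tmp_path / "bone.npz")
    am2 = st.load_model(tmp_path / "art.npz")
    assert np.allclose(fm2.modes, fm.modes)
    assert isinstance(am2, st.ArticulatedSSM)
    assert am2.n_femur == am.n_femur
    assert np.allclose(am2.mean_shape, am.mean_shape)
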