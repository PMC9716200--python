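import numpy as np
import pytest
from scipy.linalg import subspace_angles

from kneewear import ppae as pp
from kneewear import synthetic_cohort as sc
from kneewear.jsw_mapping import WearImage


def _images_from_fields(fields, S):
    return [
        WearImage(pixels=f.field.reshape(S, S), mask=np.ones((S, S), bool))
        for f in fields
    ]


class TestAugment:
    def test_quadruples_and_groups(self, wear_images_16):
        imgs, _ = wear_images_16
        aug = pp.augment(imgs[:12])
        assert len(aug) == 48
        # per-case contiguous groups of 4: orig, lr, ud, both
        assert np.array_equal(aug[0].pixels, imgs[0].pixels)
        assert np.array_equal(aug[1].pixels, np.fliplr(imgs[0].pixels))
        assert np.array_equal(aug[2].pixels, np.flipud(imgs[0].pixels))
        assert np.array_equal(aug[3].pixels, imgs[0].pixels[::-1, ::-1])

    def test_double_flip_is_identity(self, wear_images_16):
        imgs, _ = wear_images_16
        twice = pp.augment(pp.augment([imgs[0]])[1:2])
        assert np.array_equal(twice[1].pixels, imgs[0].pixels)  # lr of lr

    def test_symmetric_image_gives_identical_copies(self):
        S = 8
        g = (np.arange(S) + 0.5) / S
        uu, vv = np.meshgrid(g, g)
        sym = np.exp(-((uu - 0.5) ** 2 + (vv - 0.5) ** 2) / 0.05)
        img = WearImage(pixels=sym, mask=np.ones((S, S), bool))
        aug = pp.augment([img])
        for a in aug[1:]:
            assert np.allclose(a.pixels, aug[0].pixels, atol=1e-15)

    def test_mixed_sizes_rejected(self):
        a = WearImage(pixels=np.zeros((8, 8)), mask=np.ones((8, 8), bool))
        b = WearImage(pixels=np.zeros((16, 16)), mask=np.ones((16, 16), bool))
        with pytest.raises(ValueError):
            pp.augment([a, b])


class TestTraining:
    def test_reconstruction_beats_mean_baseline(self, trained_ppae):
        model, _, imgs = trained_ppae
        X = model.vectorize(imgs)
        mse = float(np.mean((model.decode_latent(model.encode(X)) - X) ** 2))
        baseline = 0.5 * float(np.var(X))  # trivial mean-image predictor / 2
        assert mse < baseline

    def test_loss_decreases(self, trained_ppae):
        model, _, _ = trained_ppae
        assert model.loss_history[-1] < model.loss_history[0]

    def test_seed_reproducibility(self, wear_images_16):
        imgs, _ = wear_images_16
        kw = dict(latent_dim=4, hidden=24, epochs=20, seed=9)
        m1 = pp.train(imgs[:40], **kw)
        m2 = pp.train(imgs[:40], **kw)
        for p in ("W1", "W2", "W3", "W4", "b4"):
            assert np.array_equal(getattr(m1, p), getattr(m2, p))

    def test_too_few_images_rejected(self, wear_images_16):
        imgs, _ = wear_images_16
        with pytest.raises(ValueError, match="2×latent_dim|2.latent_dim"):
            pp.train(imgs[:10], latent_dim=8)

    def test_divergent_training_aborts(self, wear_images_16):
        imgs, _ = wear_images_16
        with pytest.raises(RuntimeError, match="loss"):
            pp.train(imgs[:40], latent_dim=4, hidden=16, epochs=60, lr=1e200, seed=0)


class TestPolynomialBottleneck:
    def test_degree1_equals_svd_scores(self, wear_images_16):
        imgs, _ = wear_images_16
        model = pp.train(imgs, latent_dim=6, hidden=32, epochs=60, seed=2)
        comps, model = pp.fit_polynomial_bottleneck(model, imgs, degree=1)
        Z = model.encode(model.vectorize(imgs))
        Zc = Z - Z.mean(0)
        _, _, Vt = np.linalg.svd(Zc, full_matrices=False)
        raw = Zc @ Vt[: comps.n_components].T
        # degree-1 residualization of uncorrelated SVD scores removes nothing
        assert np.abs(np.abs(comps.scores[:, model.component_order.argsort()]) - np.abs(raw)).max() < 1e-8

    def test_scores_exactly_decorrelated(self, trained_ppae):
        _, comps, _ = trained_ppae
        C = np.corrcoef(comps.scores.T)
        off = np.abs(C - np.diag(np.diag(C)))
        assert off.max() < 0.05

    def test_variance_fractions_contract(self, trained_ppae):
        _, comps, _ = trained_ppae
        vf = comps.variance_fraction
        assert np.all(vf >= 0)
        assert np.all(np.diff(vf) <= 1e-12)
        assert comps.cumulative_fraction[-1] <= 1 + 1e-9
        assert np.all(np.diff(comps.cumulative_fraction) >= -1e-15)

    def test_fractions_invariant_to_case_relabeling(self, wear_images_16):
        imgs, _ = wear_images_16
        model = pp.train(imgs, latent_dim=6, hidden=32, epochs=60, seed=2)
        c1, _ = pp.fit_polynomial_bottleneck(model, imgs, degree=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(imgs))
        c2, _ = pp.fit_polynomial_bottleneck(model, [imgs[i] for i in perm], degree=2)
        assert np.allclose(c1.variance_fraction, c2.variance_fraction, atol=1e-9)

    def test_linear_ae_degree1_matches_pca(self):
        # linear activations + degree-1 bottleneck reproduce PCA (oracle)
        rng = np.random.default_rng(3)
        S, n, k = 12, 80, 3
        uv = sc.default_uv_grid(S)
        T = sc.pattern_templates(uv)
        X = np.clip(
            T[:, :3] @ (0.5 + 0.25 * rng.normal(size=(3, n))), 0, 1
        ).T  # linear mixtures of three templates
        imgs = [WearImage(pixels=x.reshape(S, S), mask=np.ones((S, S), bool)) for x in X]
        model = pp.train(
            imgs, latent_dim=k, hidden=24, activation="linear",
            l2_weight=0.0, sparsity_weight=0.0, epochs=1500, lr=3e-3,
            batch_size=80, seed=4,
        )
        comps, model = pp.fit_polynomial_bottleneck(model, imgs, degree=1)
        Xc = X - X.mean(0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        pca_scores = Xc @ Vt[:k].T
        ang = subspace_angles(comps.scores, pca_scores).max()
        assert np.degrees(ang) < 5.0

    def test_two_nonlinear_factor_recovery(self):
        rng = np.random.default_rng(5)
        S, n = 16, 300
        uv = sc.default_uv_grid(S)
        g = rng.normal(size=(n, 2))
        imgs = []
        # two non-linear factors in orthogonal symmetry channels: a
        # medio-lateral contrast and an antero-posterior contrast, both
        # intensity-neutral (distinct strengths keep the component
        # variances separated)
        for i in range(n):
            w = np.array(
                [
                    0.5 + 0.3 * np.tanh(g[i, 0]),
                    0.5 - 0.3 * np.tanh(g[i, 0]),
                    0.35 + 0.25 * np.tanh(g[i, 1]),
                    0.35 - 0.25 * np.tanh(g[i, 1]),
                    0.0,
                ]
            )
            f = sc.wear_field_from_weights(w, uv, noise_sd=0.01, rng=rng)
            imgs.append(WearImage(pixels=f.reshape(S, S), mask=np.ones((S, S), bool)))
        model = pp.train(imgs, latent_dim=6, hidden=48, epochs=200, seed=6)
        comps, model = pp.fit_polynomial_bottleneck(model, imgs, degree=2)
        C = np.abs(np.corrcoef(np.column_stack([g, comps.scores[:, :2]]).T))[:2, 2:]
        # each of the first two components aligns with one distinct factor
        best = C.argmax(axis=1)
        assert set(best) == {0, 1}
        assert C.max(axis=1).min() > 0.8
        assert C.min(axis=1).max() < 0.2


class TestTransform:
    def test_training_scores_reproduced(self, trained_ppae):
        model, comps, imgs = trained_ppae
        t = pp.transform(model, imgs)
        assert np.abs(t - comps.scores).max() < 1e-6

    def test_mean_image_scores_near_zero(self, trained_ppae):
        model, comps, imgs = trained_ppae
        X = np.mean([im.pixels for im in imgs], axis=0)
        mean_img = WearImage(pixels=X, mask=imgs[0].mask.copy())
        t = pp.transform(model, mean_img)
        # with a non-linear encoder, centering holds on the dominant
        # components; trailing near-noise components have tiny SDs
        dominant = comps.variance_fraction > 0.05
        assert np.all(np.abs(t[dominant]) < 0.6 * model.score_sd[dominant])

    def test_wrong_size_rejected(self, trained_ppae):
        model, _, _ = trained_ppae
        bad = WearImage(pixels=np.zeros((8, 8)), mask=np.ones((8, 8), bool))
        with pytest.raises(ValueError):
            pp.transform(model, bad)

    def test_medial_lateral_opposite_signs(self, trained_ppae):
        model, comps, imgs = trained_ppae
        S = imgs[0].size
        uv = sc.default_uv_grid(S)
        med = sc.wear_field_from_weights(np.array([1, 0, 0, 0, 0]), uv)
        lat = sc.wear_field_from_weights(np.array([0, 1, 0, 0, 0]), uv)
        tm = pp.transform(model, WearImage(pixels=med.reshape(S, S), mask=imgs[0].mask.copy()))
        tl = pp.transform(model, WearImage(pixels=lat.reshape(S, S), mask=imgs[0].mask.copy()))
        # component most associated with the medio-lateral contrast flips sign
        j = np.argmax(np.abs(tm - tl))
        assert tm[j] * tl[j] < 0


class TestInterpretation:
    def test_zero_range_gives_identical_decodes(self, trained_ppae):
        model, _, _ = trained_ppae
        lo, hi = pp.component_wear_interpretation(model, 0, sd_range=0.0)
        assert np.array_equal(lo.pixels, hi.pixels)

    def test_decodes_clipped(self, trained_ppae):
        model, _, _ = trained_ppae
        for j in range(min(3, model.n_components)):
            lo, hi = pp.component_wear_interpretation(model, j, sd_range=3.0)
            for im in (lo, hi):
                assert im.pixels.min() >= 0.0 and im.pixels.max() <= 1.0

    def test_medial_component_decodes_medially(self, trained_ppae):
        model, comps, imgs = trained_ppae
        S = imgs[0].size
        uv = sc.default_uv_grid(S)
        med = sc.wear_field_from_weights(np.array([1, 0, 0, 0, 0]), uv)
        t = pp.transform(model, WearImage(pixels=med.reshape(S, S), mask=imgs[0].mask.copy()))
        j = int(np.argmax(np.abs(t / model.score_sd)))
        sign = np.sign(t[j])
        lo, hi = pp.component_wear_interpretation(model, j, sd_range=2.0)
        img = hi if sign > 0 else lo
        medial_mean = img.pixels[:, : S // 2].mean()
        lateral_mean = img.pixels[:, S // 2 :].mean()
        assert medial_mean > lateral_mean

    def test_out_of_range_component_rejected(self, trained_ppae):
        model, _, _ = trained_ppae
        with pytest.raises(IndexError):
            pp.component_wear_interpretation(model, model.n_components + 3)


def test_ppae_io_roundtrip(tmp_path, trained_ppae):
    model, comps, imgs = trained_ppae
    pp.save_ppae(model, tmp_path / "m.npz", tmp_path / "m.json")
    back = pp.load_ppae(tmp_path / "m.npz")
    t0 = pp.transform(model, imgs[:5])
    t1 = pp.transform(back, imgs[:5])
    assert np.allclose(t0, t1, atol=1e-12)
    pp.export_scores_csv([f"case{i}" for i in range(len(comps.scores))], comps.scores, tmp_path / "s.csv")
    assert (tmp_path / "s.csv").read_text().startswith("case_id,comp1")
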