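import warnings

import numpy as np
import pytest

from kneewear import experiments as ex
from kneewear import ppae as pp
from kneewear import synthetic_cohort as sc
from kneewear.jsw_mapping import WearImage


@pytest.fixture(scope="session")
def models_bundle():
    """Healthy SSMs (femur, tibia, articulated) from 15 training limbs."""
    cfg = ex.ExperimentConfig(seed=11, n_train=15, resolution=300)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fm, tm, am, limbs = ex.build_models(cfg, cfg.seed)
    return fm, tm, am, limbs


@pytest.fixture(scope="session")
def wear_images_16():
    """200 wear-field images (16x16) from the default class mixture."""
    S = 16
    uv = sc.default_uv_grid(S)
    fields = sc.generate_wear_cohort(200, seed=21, uv=uv)
    imgs = [
        WearImage(pixels=f.field.reshape(S, S), mask=np.ones((S, S), bool))
        for f in fields
    ]
    return imgs, fields


@pytest.fixture(scope="session")
def trained_ppae(wear_images_16):
    """PPAE trained on the augmented 16x16 cohort, bottleneck fitted."""
    imgs, _ = wear_images_16
    model = pp.train(
        pp.augment(imgs), latent_dim=8, hidden=64, epochs=150, seed=5
    )
    comps, model = pp.fit_polynomial_bottleneck(model, imgs, degree=2)
    return model, comps, imgs


def square_patch(n=11):
    """Planar unit-square triangulated grid (vertices, faces)."""
    g = np.linspace(0.0, 1.0, n)
    uu, vv = np.meshgrid(g, g, indexing="xy")
    V = np.column_stack([uu.ravel(), vv.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append((a, a + 1, a + n + 1))
            faces.append((a, a + n + 1, a + n))
    return V, np.asarray(faces)
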