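"""Principal polynomial autoencoder (PPAE) for wear-pattern decomposition.

A conventional fully-connected autoencoder compresses each wear image
into a compact latent vector, but its latent variables are generally
correlated, which muddies variance attribution.  The PPAE keeps the
autoencoder's non-linear encoder/decoder and replaces the bottleneck —
the last encoder layer and first decoder layer — by (1) a low-rank
singular value decomposition of the centred latent activations and
(2) sequential polynomial regression: each component's scores are
residualized on polynomial functions of all previously extracted
components.  The result is an ordered set of exactly decorrelated,
non-linear wear components with per-component variance fractions over
the latent feature space.

The network itself is a compact two-layer MLP encoder with a mirrored
decoder, written directly in numpy with analytic gradients and Adam —
small wear images at desk scale do not need a GPU framework, and a
closed implementation keeps training bit-reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.preprocessing import PolynomialFeatures

from .jsw_mapping import WearImage

__all__ = [
    "TrainingConfig",
    "PPAEModel",
    "PolyComponents",
    "augment",
    "train",
    "fit_polynomial_bottleneck",
    "transform",
    "inverse_transform",
    "component_wear_interpretation",
    "save_ppae",
    "load_ppae",
]


@dataclass
class TrainingConfig:
    latent_dim: int = 15
    hidden: int = 256
    activation: str = "tanh"  # "tanh" | "linear"
    l2_weight: float = 1e-5
    sparsity_weight: float = 1e-4
    sparsity_target: float = 0.1
    lr: float = 1e-3
    epochs: int = 300
    batch_size: int = 64
    seed: int = 0


@dataclass
class PPAEModel:
    """Trained autoencoder plus (optionally) its fitted SVD+poly bottleneck."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray
    W4: np.ndarray
    b4: np.ndarray
    mask: np.ndarray  # (S, S) bool, pixels entering the loss
    config: TrainingConfig
    loss_history: list[float] = field(default_factory=list)
    # polynomial bottleneck state (set by fit_polynomial_bottleneck)
    latent_mean: np.ndarray | None = None
    svd_basis: np.ndarray | None = None  # (latent_dim, r) orthonormal
    svd_values: np.ndarray | None = None
    poly_degree: int = 0
    poly_coeffs: list[np.ndarray] = field(default_factory=list)
    component_order: np.ndarray | None = None  # permutation by residual variance
    score_sd: np.ndarray | None = None
    total_latent_variance: float = 0.0

    @property
    def image_size(self) -> int:
        return self.mask.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.W2.shape[1]

    @property
    def n_components(self) -> int:
        return 0 if self.svd_basis is None else self.svd_basis.shape[1]

    # -- network forward passes ------------------------------------------
    def _act(self, x: np.ndarray) -> np.ndarray:
        return np.tanh(x) if self.config.activation == "tanh" else x

    def encode(self, X: np.ndarray) -> np.ndarray:
        h = self._act(X @ self.W1 + self.b1)
        return h @ self.W2 + self.b2

    def decode_latent(self, Z: np.ndarray) -> np.ndarray:
        h = self._act(Z @ self.W3 + self.b3)
        return h @ self.W4 + self.b4

    def vectorize(self, images) -> np.ndarray:
        """Stack masked pixels of images into a (n, D) matrix."""
        images = _aslist(images)
        for im in images:
            if np.asarray(im.pixels).shape != self.mask.shape:
                raise ValueError(
                    f"image size {np.asarray(im.pixels).shape} does not match "
                    f"the trained model ({self.mask.shape})"
                )
        return np.stack([np.asarray(im.pixels)[self.mask] for im in images])


@dataclass
class PolyComponents:
    """Ordered, decorrelated non-linear component scores."""

    scores: np.ndarray  # (n_cases, k)
    variance_fraction: np.ndarray
    cumulative_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _aslist(images):
    if isinstance(images, WearImage):
        return [images]
    return list(images)


# ---------------------------------------------------------------------------
# Mirror augmentation
# ---------------------------------------------------------------------------


def augment(images) -> list[WearImage]:
    """Left-right and antero-posterior mirror augmentation.

    Wear incidence is asymmetric between compartments; mirroring the
    images over both axes balances the training data and quadruples it.
    Output order is per-case contiguous: original, left-right flip,
    antero-posterior flip, double flip.
    """
    images = _aslist(images)
    sizes = {im.size for im in images}
    if len(sizes) > 1:
        raise ValueError("all images must share the same size")
    out: list[WearImage] = []
    for im in images:
        p, m = im.pixels, im.mask
        out.append(WearImage(pixels=p.copy(), mask=m.copy()))
        out.append(WearImage(pixels=np.fliplr(p).copy(), mask=np.fliplr(m).copy()))
        out.append(WearImage(pixels=np.flipud(p).copy(), mask=np.flipud(m).copy()))
        out.append(WearImage(pixels=p[::-1, ::-1].copy(), mask=m[::-1, ::-1].copy()))
    return out


# ---------------------------------------------------------------------------
# Autoencoder training (numpy, Adam)
# ---------------------------------------------------------------------------


def _init_weights(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-lim, lim, size=(d_in, d_out))


def train(
    images,
    latent_dim: int = 15,
    hidden: int = 256,
    activation: str = "tanh",
    l2_weight: float = 1e-5,
    sparsity_weight: float = 1e-4,
    sparsity_target: float = 0.1,
    epochs: int = 300,
    lr: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
) -> PPAEModel:
    """Train the two-layer fully-connected autoencoder.

    Loss = masked-pixel MSE + ``l2_weight``·‖W‖² + ``sparsity_weight``·KL
    divergence between ``sparsity_target`` and the mean hidden activation
    (classic sparse-autoencoder penalty; applied for tanh activations,
    whose outputs are mapped to (0,1) first).  Fully reproducible from
    ``seed``.
    """
    images = _aslist(images)
    if len(images) < 2 * latent_dim:
        raise ValueError("need at least 2×latent_dim training images")
    mask = np.asarray(images[0].mask, dtype=bool)
    cfg = TrainingConfig(
        latent_dim=latent_dim,
        hidden=hidden,
        activation=activation,
        l2_weight=l2_weight,
        sparsity_weight=sparsity_weight,
        sparsity_target=sparsity_target,
        lr=lr,
        epochs=epochs,
        batch_size=batch_size,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    X = np.stack([np.asarray(im.pixels)[mask] for im in images])
    n, D = X.shape

    model = PPAEModel(
        W1=_init_weights(rng, D, hidden),
        b1=np.zeros(hidden),
        W2=_init_weights(rng, hidden, latent_dim),
        b2=np.zeros(latent_dim),
        W3=_init_weights(rng, latent_dim, hidden),
        b3=np.zeros(hidden),
        W4=_init_weights(rng, hidden, D),
        b4=np.zeros(D),
        mask=mask,
        config=cfg,
    )

    params = ["W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4"]
    m_adam = {p: np.zeros_like(getattr(model, p)) for p in params}
    v_adam = {p: np.zeros_like(getattr(model, p)) for p in params}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    use_tanh = activation == "tanh"
    rho = sparsity_target

    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            xb = X[order[start : start + batch_size]]
            B = len(xb)

            a1 = xb @ model.W1 + model.b1
            h1 = np.tanh(a1) if use_tanh else a1
            z = h1 @ model.W2 + model.b2
            a3 = z @ model.W3 + model.b3
            h3 = np.tanh(a3) if use_tanh else a3
            xhat = h3 @ model.W4 + model.b4

            diff = xhat - xb
            mse = float(np.mean(diff**2))
            loss = mse
            # sparsity on mean encoder-hidden activation, mapped to (0,1)
            g_sparse_h = 0.0
            if use_tanh and sparsity_weight > 0:
                ah = np.clip((h1.mean(axis=0) + 1.0) / 2.0, 1e-6, 1 - 1e-6)
                kl = rho * np.log(rho / ah) + (1 - rho) * np.log((1 - rho) / (1 - ah))
                loss += sparsity_weight * float(kl.sum())
                dkl_dah = -rho / ah + (1 - rho) / (1 - ah)
                g_sparse_h = sparsity_weight * dkl_dah / (2.0 * B)  # d ah / d h1 = 1/(2B)
            if l2_weight > 0:
                loss += l2_weight * sum(
                    float(np.sum(getattr(model, p) ** 2)) for p in ("W1", "W2", "W3", "W4")
                )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}: mse={mse}, lr={lr} — "
                    "reduce the learning rate or regularization weights"
                )
            ep_loss += loss * B

            # backprop
            g_xhat = 2.0 * diff / diff.size
            gW4 = h3.T @ g_xhat
            gb4 = g_xhat.sum(0)
            g_h3 = g_xhat @ model.W4.T
            g_a3 = g_h3 * (1 - h3**2) if use_tanh else g_h3
            gW3 = z.T @ g_a3
            gb3 = g_a3.sum(0)
            g_z = g_a3 @ model.W3.T
            gW2 = h1.T @ g_z
            gb2 = g_z.sum(0)
            g_h1 = g_z @ model.W2.T + g_sparse_h
            g_a1 = g_h1 * (1 - h1**2) if use_tanh else g_h1
            gW1 = xb.T @ g_a1
            gb1 = g_a1.sum(0)
            grads = dict(W1=gW1, b1=gb1, W2=gW2, b2=gb2, W3=gW3, b3=gb3, W4=gW4, b4=gb4)
            if l2_weight > 0:
                for p in ("W1", "W2", "W3", "W4"):
                    grads[p] = grads[p] + 2.0 * l2_weight * getattr(model, p)

            step += 1
            for p in params:
                g = grads[p]
                m_adam[p] = beta1 * m_adam[p] + (1 - beta1) * g
                v_adam[p] = beta2 * v_adam[p] + (1 - beta2) * g**2
                mhat = m_adam[p] / (1 - beta1**step)
                vhat = v_adam[p] / (1 - beta2**step)
                setattr(model, p, getattr(model, p) - lr * mhat / (np.sqrt(vhat) + eps))
        model.loss_history.append(ep_loss / n)
    return model


# ---------------------------------------------------------------------------
# SVD + polynomial bottleneck
# ---------------------------------------------------------------------------


def _poly_features(T: np.ndarray, degree: int) -> np.ndarray:
    pf = PolynomialFeatures(degree=degree, include_bias=True)
    return pf.fit_transform(T)


def fit_polynomial_bottleneck(
    model: PPAEModel, images, degree: int = 2
) -> tuple[PolyComponents, PPAEModel]:
    """Replace the latent layer by SVD + sequential polynomial regression.

    The centred latent activations of ``images`` are decomposed by SVD
    into ordered orthogonal directions.  Component scores are then
    residualized sequentially: component j's raw SVD scores are
    regressed (polynomial of ``degree`` with intercept) on the final
    scores of components 1..j−1, and only the residual is kept.  Every
    pair of final scores is therefore exactly uncorrelated.  Components
    are reported in order of decreasing residual variance; fractions are
    over total latent variance.
    """
    if degree < 1:
        raise ValueError("polynomial degree must be ≥ 1")
    X = model.vectorize(images)
    Z = model.encode(X)
    n = len(Z)
    zmean = Z.mean(axis=0)
    Zc = Z - zmean
    U, svals, Vt = np.linalg.svd(Zc, full_matrices=False)
    rank = int(np.sum(svals > max(svals[0], 1e-30) * 1e-9))
    if rank < len(svals):
        import warnings

        warnings.warn(f"rank-deficient latent activations: keeping {rank} components")
    basis = Vt[:rank].T
    raw = Zc @ basis  # (n, rank), SVD order
    total_var = float(np.sum(Zc.var(axis=0)))

    T = np.zeros_like(raw)
    coeffs: list[np.ndarray] = []
    T[:, 0] = raw[:, 0]
    coeffs.append(np.zeros(1))
    for j in range(1, rank):
        feats = _poly_features(T[:, :j], degree)
        beta, *_ = np.linalg.lstsq(feats, raw[:, j], rcond=None)
        T[:, j] = raw[:, j] - feats @ beta
        coeffs.append(beta)

    resid_var = T.var(axis=0)
    order = np.argsort(-resid_var, kind="stable")
    T_ord = T[:, order]
    vf = resid_var[order] / max(total_var, 1e-30)

    model.latent_mean = zmean
    model.svd_basis = basis
    model.svd_values = svals[:rank]
    model.poly_degree = degree
    model.poly_coeffs = coeffs
    model.component_order = order
    model.score_sd = T_ord.std(axis=0)
    model.total_latent_variance = total_var
    comps = PolyComponents(
        scores=T_ord,
        variance_fraction=vf,
        cumulative_fraction=np.cumsum(vf),
    )
    return comps, model


def transform(model: PPAEModel, images) -> np.ndarray:
    """Component scores for one image or a batch (n, k)."""
    if model.svd_basis is None:
        raise ValueError("polynomial bottleneck not fitted")
    single = isinstance(images, WearImage)
    X = model.vectorize(images)
    if X.shape[1] != int(model.mask.sum()):
        raise ValueError("image size does not match the trained model")
    Z = model.encode(X)
    raw = (Z - model.latent_mean) @ model.svd_basis
    k = raw.shape[1]
    T = np.zeros_like(raw)
    T[:, 0] = raw[:, 0]
    for j in range(1, k):
        feats = _poly_features(T[:, :j], model.poly_degree)
        T[:, j] = raw[:, j] - feats @ model.poly_coeffs[j]
    out = T[:, model.component_order]
    return out[0] if single else out


def inverse_transform(model: PPAEModel, scores: np.ndarray) -> np.ndarray:
    """Decode component scores back to a wear image (clipped to [0,1])."""
    if model.svd_basis is None:
        raise ValueError("polynomial bottleneck not fitted")
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    k = model.n_components
    T = np.zeros((len(scores), k))
    inv_order = np.argsort(model.component_order)
    T[:, :] = scores[:, inv_order]
    raw = np.zeros_like(T)
    raw[:, 0] = T[:, 0]
    for j in range(1, k):
        feats = _poly_features(T[:, :j], model.poly_degree)
        raw[:, j] = T[:, j] + feats @ model.poly_coeffs[j]
    Z = model.latent_mean + raw @ model.svd_basis.T
    Xhat = model.decode_latent(Z)
    S = model.image_size
    out = np.zeros((len(scores), S, S))
    for i in range(len(scores)):
        img = np.zeros((S, S))
        img[model.mask] = Xhat[i]
        out[i] = np.clip(img, 0.0, 1.0)
    return out


def component_wear_interpretation(
    model: PPAEModel, component_index: int, sd_range: float = 2.0
) -> tuple[WearImage, WearImage]:
    """Decoded images at ∓``sd_range`` SD along one component.

    Walking a single component while holding the others at zero and
    decoding visualizes what that wear component encodes (e.g. medial
    vs lateral compartment loss).
    """
    k = model.n_components
    if not 0 <= component_index < k:
        raise IndexError(f"component_index must be in [0, {k})")
    s = np.zeros((2, k))
    s[0, component_index] = -sd_range * model.score_sd[component_index]
    s[1, component_index] = +sd_range * model.score_sd[component_index]
    imgs = inverse_transform(model, s)
    m = model.mask
    return WearImage(pixels=imgs[0], mask=m.copy()), WearImage(pixels=imgs[1], mask=m.copy())


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_ppae(model: PPAEModel, path_npz, path_json=None) -> None:
    arrays = {
        k: getattr(model, k)
        for k in ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4", "mask")
    }
    if model.svd_basis is not None:
        arrays.update(
            latent_mean=model.latent_mean,
            svd_basis=model.svd_basis,
            svd_values=model.svd_values,
            component_order=model.component_order,
            score_sd=model.score_sd,
            total_latent_variance=model.total_latent_variance,
            poly_degree=model.poly_degree,
        )
        for j, c in enumerate(model.poly_coeffs):
            arrays[f"poly_{j}"] = c
    np.savez(path_npz, **arrays, config=json.dumps(asdict(model.config)))
    if path_json is not None:
        with open(path_json, "w") as fh:
            json.dump(asdict(model.config), fh, indent=2)


def load_ppae(path_npz) -> PPAEModel:
    z = np.load(path_npz, allow_pickle=False)
    cfg = TrainingConfig(**json.loads(str(z["config"])))
    model = PPAEModel(
        W1=z["W1"], b1=z["b1"], W2=z["W2"], b2=z["b2"],
        W3=z["W3"], b3=z["b3"], W4=z["W4"], b4=z["b4"],
        mask=z["mask"].astype(bool), config=cfg,
    )
    if "svd_basis" in z:
        model.latent_mean = z["latent_mean"]
        model.svd_basis = z["svd_basis"]
        model.svd_values = z["svd_values"]
        model.component_order = z["component_order"]
        model.score_sd = z["score_sd"]
        model.total_latent_variance = float(z["total_latent_variance"])
        model.poly_degree = int(z["poly_degree"])
        model.poly_coeffs = [z[f"poly_{j}"] for j in range(model.svd_basis.shape[1])]
    return model


def export_scores_csv(case_ids, scores: np.ndarray, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        k = scores.shape[1]
        w.writerow(["case_id"] + [f"comp{j+1}" for j in range(k)])
        for cid, row in zip(case_ids, scores):
            w.writerow([cid] + [f"{v:.8g}" for v in row])
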