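"""Downstream statistics: CCA, LOOCV-LDA risk assessment, 2D embedding.

Canonical correlation analysis (CCA) finds maximally correlated linear
combinations of two multivariate blocks — here wear-component scores on
one side and (Mahalanobis-normalized) twin shape loadings on the other
— with significance assessed by a permutation null.  The morphology
risk model is a linear discriminant analysis (LDA) separating virtual
healthy twins of arthritic knees from healthy controls, evaluated with
strict leave-one-out cross-validation and summarized by predictive
values, sensitivity/specificity and the point-biserial correlation of
the held-out discriminant score with the group label.  UMAP provides a
qualitative 2D view of the shape spaces; nothing quantitative depends
on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "CCAResult",
    "ClassifierReport",
    "cca",
    "lda_risk",
    "confusion_metrics",
    "embed_2d",
]


@dataclass
class CCAResult:
    canonical_correlations: np.ndarray  # descending, in [0, 1]
    x_loadings: np.ndarray  # (p, k) canonical directions for X
    y_loadings: np.ndarray  # (q, k)
    p_values: np.ndarray | None = None

    @property
    def r1(self) -> float:
        return float(self.canonical_correlations[0])


@dataclass
class ConfusionRates:
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    undefined: tuple[str, ...] = ()


@dataclass
class ClassifierReport:
    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    pointwise_correlation_r: float
    p_value: float
    scores: np.ndarray = field(default_factory=lambda: np.zeros(0))
    predictions: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    per_sex: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "ppv": self.ppv,
            "npv": self.npv,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "r": self.pointwise_correlation_r,
            "p": self.p_value,
        }
        if self.per_sex is not None:
            d["per_sex"] = {k: v.to_dict() for k, v in self.per_sex.items()}
        return d


# ---------------------------------------------------------------------------
# Canonical correlation analysis
# ---------------------------------------------------------------------------


def _cca_correlations(
    X: np.ndarray, Y: np.ndarray, reg: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, p = X.shape
    q = Y.shape[1]
    Cxx = X.T @ X / (n - 1)
    Cyy = Y.T @ Y / (n - 1)
    Cxy = X.T @ Y / (n - 1)
    lx = reg * np.trace(Cxx) / p
    ly = reg * np.trace(Cyy) / q
    Cxx = Cxx + lx * np.eye(p)
    Cyy = Cyy + ly * np.eye(q)
    try:
        Lx = linalg.cholesky(Cxx, lower=True)
        Ly = linalg.cholesky(Cyy, lower=True)
    except linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular covariance; increase the `reg` ridge parameter"
        ) from e
    M = linalg.solve_triangular(Lx, Cxy, lower=True)
    M = linalg.solve_triangular(Ly, M.T, lower=True).T
    U, svals, Vt = np.linalg.svd(M)
    r = np.clip(svals, 0.0, 1.0)
    a = linalg.solve_triangular(Lx.T, U, lower=False)
    b = linalg.solve_triangular(Ly.T, Vt.T, lower=False)
    return r, a, b


def cca(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    reg: float = 1e-6,
    standardize: bool = True,
) -> CCAResult:
    """Regularized canonical correlation with a permutation null.

    Canonical correlations come from the SVD of the whitened
    cross-covariance (a ridge of ``reg``·trace/dim stabilizes each
    block's covariance).  Per-correlation p-values are obtained by
    permuting the rows of ``y``: p_i = (1 + #{perm r_i ≥ observed r_i})
    / (1 + n_permutations).
    """
    X = np.asarray(x, dtype=float)
    Y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if len(X) != len(Y):
        raise ValueError("x and y must have the same number of cases")
    n = len(X)
    if n < max(X.shape[1], Y.shape[1]) + 2:
        raise ValueError("need at least features+2 cases")
    X = X - X.mean(0)
    Y = Y - Y.mean(0)
    if standardize:
        X = X / np.where(X.std(0) > 1e-12, X.std(0), 1.0)
        Y = Y / np.where(Y.std(0) > 1e-12, Y.std(0), 1.0)

    r, a, b = _cca_correlations(X, Y, reg)
    p_values = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(r))
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            rp, _, _ = _cca_correlations(X, Y[perm], reg)
            exceed += rp >= r
        p_values = (1.0 + exceed) / (1.0 + n_permutations)
    return CCAResult(
        canonical_correlations=r, x_loadings=a, y_loadings=b, p_values=p_values
    )


# ---------------------------------------------------------------------------
# LDA risk classification with leave-one-out CV
# ---------------------------------------------------------------------------


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionRates:
    """PPV/NPV/sensitivity/specificity from confusion counts.

    Zero-denominator rates are returned as NaN and named in
    ``undefined``.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    if tp + fp + tn + fn == 0:
        raise ValueError("all counts zero")
    undef = []

    def rate(num, den, name):
        if den == 0:
            undef.append(name)
            return float("nan")
        return num / den

    ppv = rate(tp, tp + fp, "ppv")
    npv = rate(tn, tn + fn, "npv")
    sens = rate(tp, tp + fn, "sensitivity")
    spec = rate(tn, tn + fp, "specificity")
    return ConfusionRates(ppv, npv, sens, spec, tuple(undef))


def lda_risk(
    features: np.ndarray,
    labels: np.ndarray,
    sex: np.ndarray | None = None,
    k_folds: int | None = None,
    seed: int = 0,
) -> ClassifierReport:
    """Leave-one-out cross-validated LDA risk classifier.

    ``labels`` is binary: 1 = OA twin (positive), 0 = healthy control.
    For every case, an LDA is trained on all other cases and the
    held-out case's discriminant score and predicted label recorded;
    confusion counts and rates use held-out predictions only.
    ``pointwise_correlation_r`` is the Pearson (point-biserial)
    correlation between the held-out score and the label.  ``k_folds``
    overrides strict leave-one-out with k-fold CV.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    n = len(X)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 cases per class")

    scores = np.zeros(n)
    preds = np.zeros(n, dtype=int)
    if k_folds is None or k_folds >= n:
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        parts = np.array_split(order, k_folds)
        folds = [
            (np.setdiff1d(np.arange(n), te), te) for te in parts if len(te) > 0
        ]
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training fold lost one class; use fewer folds")
        clf = LinearDiscriminantAnalysis(solver="svd")
        clf.fit(X[tr], y[tr])
        scores[te] = clf.decision_function(X[te])
        preds[te] = clf.predict(X[te])

    tp = int(np.sum((preds == 1) & (y == 1)))
    fp = int(np.sum((preds == 1) & (y == 0)))
    tn = int(np.sum((preds == 0) & (y == 0)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    rates = confusion_metrics(tp, fp, tn, fn)
    if np.std(scores) > 1e-12 and np.std(y) > 1e-12:
        r, p = stats.pearsonr(scores, y)
    else:
        r, p = 0.0, 1.0
    per_sex = None
    if sex is not None:
        sex = np.asarray(sex)
        per_sex = {}
        for s in np.unique(sex):
            m = sex == s
            stp = int(np.sum((preds == 1) & (y == 1) & m))
            sfp = int(np.sum((preds == 1) & (y == 0) & m))
            stn = int(np.sum((preds == 0) & (y == 0) & m))
            sfn = int(np.sum((preds == 0) & (y == 1) & m))
            sr = confusion_metrics(stp, sfp, stn, sfn)
            if np.std(scores[m]) > 1e-12 and np.std(y[m]) > 1e-12:
                rr, pp = stats.pearsonr(scores[m], y[m])
            else:
                rr, pp = 0.0, 1.0
            per_sex[str(s)] = ClassifierReport(
                tp=stp, fp=sfp, tn=stn, fn=sfn,
                ppv=sr.ppv, npv=sr.npv,
                sensitivity=sr.sensitivity, specificity=sr.specificity,
                pointwise_correlation_r=float(rr), p_value=float(pp),
            )
    return ClassifierReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        ppv=rates.ppv, npv=rates.npv,
        sensitivity=rates.sensitivity, specificity=rates.specificity,
        pointwise_correlation_r=float(r), p_value=float(p),
        scores=scores, predictions=preds, per_sex=per_sex,
    )


# ---------------------------------------------------------------------------
# 2D embedding (visualization only)
# ---------------------------------------------------------------------------


def embed_2d(features: np.ndarray, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """UMAP embedding to 2D; deterministic given ``seed``.

    Visualization aid only — no quantitative claim in this package
    depends on the embedding's geometry.
    """
    X = np.asarray(features, dtype=float)
    if len(X) < 10:
        raise ValueError("need at least 10 cases to embed")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from umap import UMAP

        emb = UMAP(
            n_components=2,
            n_neighbors=min(n_neighbors, len(X) - 1),
            random_state=seed,
            n_jobs=1,
        ).fit_transform(X)
    return np.asarray(emb)


def plot_embedding(
    embedding: np.ndarray,
    labels: np.ndarray | None = None,
    path=None,
    title: str = "",
):
    """Scatter plot of a 2D shape-space embedding, optionally colored by
    group label; written to ``path`` (PNG/SVG by extension) if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if labels is None:
        ax.scatter(embedding[:, 0], embedding[:, 1], s=12, alpha=0.8)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            m = labels == lab
            ax.scatter(embedding[m, 0], embedding[m, 1], s=12, alpha=0.8, label=str(lab))
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
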