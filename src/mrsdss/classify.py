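"""Three-class linear discriminant classifier with posterior
probabilities and canonical (discriminant-function) scores.

Features are standardized by the training cohort's means and standard
deviations; the discriminant for class k in standardized space is

    g_k(z) = z' S^-1 m_k - (1/2) m_k' S^-1 m_k + log pi_k

with S the pooled within-class covariance (optionally shrunk toward its
diagonal) and m_k the class means.  Posterior probabilities are the
softmax of the g_k, equivalent to normalized Gaussian class densities
under the shared-covariance model.  The canonical projection maps z to
the two discriminant-function (DF) axes — the leading generalized
eigenvectors of the between-class scatter against S — scaled so the
within-class covariance of DF scores is the identity.  For three
classes this plane carries all between-class information, so decision
boundaries drawn in it are exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh


@dataclass
class FeatureVector:
    """Ordered feature values for one subject."""

    names: tuple[str, ...]
    values: np.ndarray
    subject: str | None = None
    crlb: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("feature values must match feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def reorder(self, names: tuple[str, ...]) -> np.ndarray:
        """Values in the requested order (any subset of this vector)."""
        missing = set(names) - set(self.names)
        if missing:
            raise ValueError(f"feature mismatch; missing {sorted(missing)}")
        index = {n: i for i, n in enumerate(self.names)}
        return self.values[[index[n] for n in names]]


@dataclass
class ClassifierModel:
    """Frozen training state of the LDA classifier."""

    feature_names: tuple[str, ...]
    mu: np.ndarray                 # training feature means
    sigma: np.ndarray              # training feature SDs
    class_labels: tuple[str, ...]  # sorted (EP < MB < PA)
    class_means: np.ndarray        # (k, p), standardized space
    pooled_cov: np.ndarray         # (p, p), shrunk
    priors: np.ndarray             # (k,)
    projection: np.ndarray         # (p, 2), whitening canonical axes
    shrinkage: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu", "sigma", "class_means", "pooled_cov", "priors",
                     "projection"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        if np.any(self.sigma <= 0):
            raise ValueError("feature SDs must be positive")
        self._precision = np.linalg.inv(self.pooled_cov)
        self._precision.setflags(write=False)

    @property
    def df_class_means(self) -> np.ndarray:
        """Class means projected to the DF plane, (k, 2)."""
        return self.class_means @ self.projection


@dataclass
class ClassificationResult:
    predicted: str
    posteriors: dict[str, float]
    df_scores: np.ndarray
    boundary_distance: float


def standardize(x: FeatureVector | np.ndarray, model: ClassifierModel) -> np.ndarray:
    """z = (x - mu) / sigma using training statistics only."""
    if isinstance(x, FeatureVector):
        vals = x.reorder(model.feature_names)
    else:
        vals = np.asarray(x, dtype=float)
        if vals.shape[-1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {vals.shape[-1]}"
            )
    return (vals - model.mu) / model.sigma


def train_lda(
    X: np.ndarray,
    labels,
    feature_names: tuple[str, ...] | None = None,
    priors: np.ndarray | dict[str, float] | str | None = None,
    shrinkage: float = 0.1,
) -> ClassifierModel:
    """Fit the standardizer, pooled covariance and canonical axes.

    ``priors`` is uniform by default; pass ``"frequency"`` for training
    class frequencies, or an explicit mapping.  ``shrinkage`` blends the
    pooled covariance toward its diagonal, guaranteeing positive
    definiteness at small n; 0 reproduces classical LDA.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    class_labels = tuple(sorted(set(labels.tolist())))
    k = len(class_labels)
    if k < 2:
        raise ValueError("need at least two classes")
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(p))

    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    if np.any(sigma <= 0):
        bad = [feature_names[i] for i in np.where(sigma <= 0)[0]]
        raise ValueError(f"zero-variance features: {bad}")
    Z = (X - mu) / sigma

    means = np.zeros((k, p))
    pooled = np.zeros((p, p))
    dof = 0
    counts = np.zeros(k)
    for i, lab in enumerate(class_labels):
        Zi = Z[labels == lab]
        counts[i] = len(Zi)
        if len(Zi) < 2:
            warnings.warn(f"class {lab!r} has fewer than 2 samples; "
                          "it contributes its mean only", stacklevel=2)
        means[i] = Zi.mean(axis=0)
        if len(Zi) >= 2:
            pooled += (len(Zi) - 1) * np.cov(Zi, rowvar=False, ddof=1)
            dof += len(Zi) - 1
    if dof == 0:
        raise ValueError("no class has two or more samples")
    pooled /= dof
    if shrinkage > 0:
        pooled = (1.0 - shrinkage) * pooled + shrinkage * np.diag(np.diag(pooled))
    if shrinkage == 0 and (n - k) < p:
        raise ValueError("singular pooled covariance: n - k < p and shrinkage is 0")

    if priors is None:
        pri = np.full(k, 1.0 / k)
    elif isinstance(priors, str) and priors == "frequency":
        pri = counts / counts.sum()
    elif isinstance(priors, dict):
        pri = np.array([priors[lab] for lab in class_labels], dtype=float)
        pri = pri / pri.sum()
    else:
        pri = np.asarray(priors, dtype=float)
        pri = pri / pri.sum()

    grand = (counts[:, None] * means).sum(axis=0) / counts.sum()
    B = np.zeros((p, p))
    for i in range(k):
        d = means[i] - grand
        B += counts[i] * np.outer(d, d)
    B /= counts.sum()

    n_axes = min(k - 1, p)
    evals, evecs = eigh(B, pooled)          # ascending; v' pooled v = 1
    W = evecs[:, ::-1][:, :n_axes]
    # deterministic sign: largest-magnitude loading positive
    for j in range(W.shape[1]):
        i_max = int(np.argmax(np.abs(W[:, j])))
        if W[i_max, j] < 0:
            W[:, j] = -W[:, j]

    return ClassifierModel(
        feature_names=tuple(feature_names),
        mu=mu,
        sigma=sigma,
        class_labels=class_labels,
        class_means=means,
        pooled_cov=pooled,
        priors=pri,
        projection=W,
        shrinkage=shrinkage,
    )


def _discriminants(model: ClassifierModel, z: np.ndarray) -> np.ndarray:
    P = model._precision
    M = model.class_means
    return z @ P @ M.T - 0.5 * np.einsum("kp,pq,kq->k", M, P, M) \
        + np.log(model.priors)


def _softmax(g: np.ndarray) -> np.ndarray:
    e = np.exp(g - g.max())
    return e / e.sum()


def apply_lda(model: ClassifierModel, x: FeatureVector | np.ndarray
              ) -> ClassificationResult:
    """Classify one case: posteriors, DF scores and boundary distance."""
    z = standardize(x, model)
    g = _discriminants(model, z)
    post = _softmax(g)
    pred = model.class_labels[int(np.argmax(post))]
    order = np.argsort(g)[::-1]
    j, l = int(order[0]), int(order[1])
    d = model.class_means[j] - model.class_means[l]
    w = model._precision @ d
    denom = float(np.linalg.norm(w))
    boundary = float(abs(g[j] - g[l]) / denom) if denom > 0 else np.inf
    return ClassificationResult(
        predicted=pred,
        posteriors=dict(zip(model.class_labels, post.astype(float))),
        df_scores=z @ model.projection,
        boundary_distance=boundary,
    )


def df_discriminants(model: ClassifierModel, u: np.ndarray) -> np.ndarray:
    """Class discriminants as a function of DF-plane coordinates.

    Exact for 3 classes because the canonical plane spans all
    between-class mean differences in the whitened metric.
    """
    U = model.df_class_means
    return u @ U.T - 0.5 * np.sum(U**2, axis=1) + np.log(model.priors)


def posteriors_from_df(model: ClassifierModel, u: np.ndarray) -> np.ndarray:
    return _softmax(df_discriminants(model, u))


def decision_boundaries(
    model: ClassifierModel,
    df1_range: tuple[float, float] = (-8.0, 8.0),
    df2_range: tuple[float, float] = (-8.0, 8.0),
    n_points: int = 400,
) -> dict[tuple[str, str], np.ndarray]:
    """Piecewise-linear decision boundaries in the DF plane.

    For each class pair, the locus where their discriminants are equal
    is a straight line; only the stretch where those two classes are the
    top two is kept.
    """
    U = model.df_class_means
    if U.shape[1] == 1:          # two classes: 1-D canonical space
        U = np.hstack([U, np.zeros((U.shape[0], 1))])
    labels = model.class_labels
    k = len(labels)
    out: dict[tuple[str, str], np.ndarray] = {}
    for j in range(k):
        for l in range(j + 1, k):
            d = U[j] - U[l]
            c = 0.5 * (U[j] @ U[j] - U[l] @ U[l]) \
                + np.log(model.priors[l] / model.priors[j])
            # line: u . d = c; parametrize along the perpendicular's span
            norm = np.linalg.norm(d)
            if norm == 0:
                continue
            base = d * c / norm**2
            tangent = np.array([-d[1], d[0]]) / norm
            span = max(df1_range[1] - df1_range[0], df2_range[1] - df2_range[0])
            ts = np.linspace(-span, span, n_points)
            pts = base[None, :] + ts[:, None] * tangent[None, :]
            keep = (
                (pts[:, 0] >= df1_range[0]) & (pts[:, 0] <= df1_range[1])
                & (pts[:, 1] >= df2_range[0]) & (pts[:, 1] <= df2_range[1])
            )
            g = pts @ U.T - 0.5 * np.sum(U**2, axis=1) + np.log(model.priors)
            top2 = np.partition(g, -2, axis=1)[:, -2]
            third_ok = np.min(np.stack([g[:, j], g[:, l]]), axis=0) >= top2 - 1e-9
            pts = pts[keep & third_ok]
            if len(pts):
                out[(labels[j], labels[l])] = pts
    return out


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class EvaluationResult:
    confusion: pd.DataFrame
    accuracy_percent: int
    accuracy_exact: float
    n_correct: int
    n_total: int
    results: list[ClassificationResult] = field(default_factory=list)


def evaluate_classifier(model: ClassifierModel, X, labels) -> EvaluationResult:
    """Confusion matrix and accuracy (percent of correct diagnoses,
    rounded half-up to the nearest integer; the exact fraction is kept)."""
    labels = list(labels)
    if len(labels) == 0:
        raise ValueError("empty test set")
    unknown = set(labels) - set(model.class_labels)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    cls = list(model.class_labels)
    confusion = pd.DataFrame(0, index=cls, columns=cls)
    results = []
    n_correct = 0
    for x, truth in zip(X, labels):
        r = apply_lda(model, x)
        results.append(r)
        confusion.loc[truth, r.predicted] += 1
        n_correct += int(r.predicted == truth)
    exact = 100.0 * n_correct / len(labels)
    return EvaluationResult(
        confusion=confusion,
        accuracy_percent=round_half_up(exact),
        accuracy_exact=exact,
        n_correct=n_correct,
        n_total=len(labels),
        results=results,
    )


__all__ = [
    "FeatureVector",
    "ClassifierModel",
    "ClassificationResult",
    "EvaluationResult",
    "standardize",
    "train_lda",
    "apply_lda",
    "decision_boundaries",
    "df_discriminants",
    "posteriors_from_df",
    "evaluate_classifier",
    "round_half_up",
]
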