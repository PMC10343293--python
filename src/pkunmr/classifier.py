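"""Untargeted classification: PCA -> canonical analysis -> k-NN, validated
by Monte-Carlo embedded cross-validation.

The model chain is fitted strictly on training data: column-mean centering,
principal components retained up to a cumulative explained-variance
threshold, canonical axes from the generalized between/within scatter
eigenproblem (dimension chosen by Wilks' lambda with Bartlett's chi-square
approximation), and a k-nearest-neighbour vote in the canonical subspace.
Monte-Carlo cross-validation repeats a seeded stratified k-fold split and
pools every held-out prediction into one confusion matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .errors import DegenerateDataError, InvalidParameterError

__all__ = [
    "ClassifierConfig",
    "PCAModel",
    "CanonicalModel",
    "ClassifierModel",
    "ConfusionMatrix",
    "pca_fit",
    "ca_fit",
    "knn_classify",
    "mccv",
    "fit_model",
    "project",
    "confusion_accuracy",
]


@dataclass(frozen=True)
class ClassifierConfig:
    explained_variance_threshold: float = 0.99
    mc_runs: int = 16
    cv_folds: int = 8
    k_neighbors: int = 3
    manova_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.explained_variance_threshold <= 1):
            raise InvalidParameterError("explained_variance_threshold must be in (0, 1]")
        if self.mc_runs < 1:
            raise InvalidParameterError("mc_runs must be >= 1")
        if self.cv_folds < 2:
            raise InvalidParameterError("cv_folds must be >= 2")
        if self.k_neighbors < 1:
            raise InvalidParameterError("k_neighbors must be >= 1")
        if not (0 < self.manova_alpha < 1):
            raise InvalidParameterError("manova_alpha must be in (0, 1)")


@dataclass
class PCAModel:
    mean: np.ndarray
    components: np.ndarray  # features x n_retained, orthonormal columns
    explained_variance: np.ndarray  # all eigenvalues of the sample covariance
    explained_ratio: np.ndarray
    n_retained: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean) @ self.components


@dataclass
class CanonicalModel:
    axes: np.ndarray  # n_components x n_axes (in PCA-score space)
    eigenvalues: np.ndarray
    wilks_lambda: float
    chi2: float
    dof: int
    p_value: float
    dimension_p_values: np.ndarray
    n_significant: int

    def transform(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) @ self.axes[:, : self.n_significant]


def pca_fit(X: np.ndarray, threshold: float = 0.99) -> PCAModel:
    """PCA of the sample covariance via SVD of the centered matrix.

    Retains the minimal number of leading components whose cumulative
    explained-variance fraction reaches ``threshold``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidParameterError("X must be 2-D with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise InvalidParameterError("X must be finite")
    if not (0 < threshold <= 1):
        raise InvalidParameterError("threshold must be in (0, 1]")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (X.shape[0] - 1)
    total = eig.sum()
    if total <= 0:
        raise DegenerateDataError("data matrix has zero total variance")
    ratio = eig / total
    cum = np.cumsum(ratio)
    n_retained = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    n_retained = min(n_retained, int((eig > eig[0] * 1e-12).sum()))
    # deterministic sign: largest-magnitude loading positive
    comps = Vt[:n_retained].T
    signs = np.sign(comps[np.abs(comps).argmax(axis=0), np.arange(n_retained)])
    signs[signs == 0] = 1.0
    return PCAModel(mean, comps * signs, eig, ratio, n_retained)


def _scatter_matrices(scores: np.ndarray, labels: np.ndarray):
    classes = np.unique(labels)
    grand = scores.mean(axis=0)
    p = scores.shape[1]
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for cls in classes:
        block = scores[labels == cls]
        if block.shape[0] < 2:
            raise InvalidParameterError(f"class {cls!r} needs >= 2 samples")
        diff = block - block.mean(axis=0)
        Sw += diff.T @ diff
        d = (block.mean(axis=0) - grand)[:, None]
        Sb += block.shape[0] * (d @ d.T)
    return classes, Sw, Sb


def ca_fit(scores: np.ndarray, labels, alpha: float = 0.05) -> CanonicalModel:
    """Canonical variates of between- vs within-class scatter plus MANOVA.

    Axes solve ``Sb a = lambda Sw a`` (within-class scatter regularized by a
    small ridge when near-singular) and are scaled to unit pooled
    within-class variance.  The retained dimension is the number of leading
    axes significant by Wilks' lambda (Bartlett's chi-square), minimum 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 2:
        raise InvalidParameterError("scores must be 2-D")
    classes, Sw, Sb = _scatter_matrices(scores, labels)
    if len(classes) < 2:
        raise InvalidParameterError("need at least 2 classes")
    n, p = scores.shape
    g = len(classes)

    ridge = 1e-8 * np.trace(Sw) / p if np.trace(Sw) > 0 else 1e-12
    Sw_reg = Sw + ridge * np.eye(p)
    try:
        eigvals, eigvecs = linalg.eigh(Sb, Sw_reg)
    except linalg.LinAlgError as exc:
        raise DegenerateDataError(f"within-class scatter is singular: {exc}") from exc
    order = np.argsort(eigvals)[::-1]
    s = min(g - 1, p)
    eigvals = np.clip(eigvals[order][:s], 0.0, None)
    axes = eigvecs[:, order][:, :s]
    # unit within-class variance along each axis, deterministic sign
    for j in range(s):
        norm = float(axes[:, j] @ (Sw / (n - g)) @ axes[:, j])
        if norm > 0:
            axes[:, j] = axes[:, j] / np.sqrt(norm)
        lead = np.abs(axes[:, j]).argmax()
        if axes[lead, j] < 0:
            axes[:, j] = -axes[:, j]

    # Bartlett's sequential tests: dimension > j for j = 0..s-1
    dim_p = np.empty(s)
    factor = n - 1 - (p + g) / 2.0
    for j in range(s):
        lam = float(np.prod(1.0 / (1.0 + eigvals[j:])))
        chi2_stat = -factor * np.log(max(lam, np.finfo(float).tiny))
        dof = (p - j) * (g - 1 - j)
        dim_p[j] = stats.chi2.sf(chi2_stat, dof) if dof > 0 else 1.0
        if j == 0:
            wilks, chi2_0, dof_0 = lam, chi2_stat, dof
    n_sig = 0
    for pv in dim_p:
        if pv < alpha:
            n_sig += 1
        else:
            break
    n_sig = max(n_sig, 1)
    return CanonicalModel(axes, eigvals, wilks, chi2_0, dof_0, float(dim_p[0]), dim_p, n_sig)


def knn_classify(
    train_scores: np.ndarray,
    train_labels,
    test_scores: np.ndarray,
    k: int = 3,
) -> np.ndarray:
    """Majority vote among the k nearest training points (Euclidean).

    Vote ties are broken in favour of the tied class whose member is nearest.
    """
    train_scores = np.atleast_2d(np.asarray(train_scores, dtype=float))
    test_scores = np.atleast_2d(np.asarray(test_scores, dtype=float))
    train_labels = np.asarray(train_labels)
    if train_scores.shape[0] == 0:
        raise InvalidParameterError("training set is empty")
    if not (1 <= k <= train_scores.shape[0]):
        raise InvalidParameterError(f"k={k} exceeds training size {train_scores.shape[0]}")
    d2 = ((test_scores[:, None, :] - train_scores[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argsort(d2, axis=1, kind="stable")[:, :k]
    out = []
    for row in nearest:
        votes: dict = {}
        for idx in row:
            votes[train_labels[idx]] = votes.get(train_labels[idx], 0) + 1
        top = max(votes.values())
        tied = {cls for cls, v in votes.items() if v == top}
        if len(tied) == 1:
            out.append(next(iter(tied)))
        else:
            out.append(next(train_labels[idx] for idx in row if train_labels[idx] in tied))
    return np.array(out)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # true x predicted
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise InvalidParameterError("confusion matrix must be square")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return confusion_accuracy(self)

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "counts": self.counts.tolist(),
            "accuracy_percent": self.accuracy,
        }


def confusion_accuracy(cm: ConfusionMatrix) -> float:
    """Percent of correctly classified samples: 100 x trace / total."""
    total = cm.total
    if total == 0:
        raise InvalidParameterError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / total


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment per sample; every class is dealt round-robin into folds."""
    assignment = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise InvalidParameterError(
                f"class {cls!r} has {len(idx)} samples < {n_folds} folds"
            )
        idx = rng.permutation(idx)
        fold_order = rng.permutation(n_folds)
        assignment[idx] = fold_order[np.arange(len(idx)) % n_folds]
    return assignment


@dataclass
class MCCVResult:
    confusion: ConfusionMatrix
    per_run_accuracy: np.ndarray
    config: ClassifierConfig


def _fit_chain(X_train: np.ndarray, y_train: np.ndarray, config: ClassifierConfig):
    pca = pca_fit(X_train, config.explained_variance_threshold)
    scores = pca.transform(X_train)
    ca = ca_fit(scores, y_train, config.manova_alpha)
    return pca, ca, ca.transform(scores)


def mccv(X, labels, config: ClassifierConfig = ClassifierConfig()) -> MCCVResult:
    """Monte-Carlo embedded cross-validation of the PCA/CA/k-NN chain.

    For each Monte-Carlo run a fresh seeded stratified ``cv_folds`` split is
    drawn; the full chain is refitted on the training folds only and the
    held-out fold is projected and classified.  All held-out predictions
    across all runs are pooled into one confusion matrix (every sample is
    predicted ``mc_runs`` times); per-run accuracies are also recorded.
    """
    X = np.asarray(getattr(X, "matrix", X), dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != len(labels):
        raise InvalidParameterError("label count must match row count")
    classes = list(np.unique(labels))
    class_pos = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    rng = np.random.default_rng(config.seed)
    run_acc = []
    for _ in range(config.mc_runs):
        folds = _stratified_folds(labels, config.cv_folds, rng)
        hits = 0
        for f in range(config.cv_folds):
            test = folds == f
            train = ~test
            pca, ca, train_can = _fit_chain(X[train], labels[train], config)
            test_can = ca.transform(pca.transform(X[test]))
            pred = knn_classify(train_can, labels[train], test_can, config.k_neighbors)
            for t, p in zip(labels[test], pred):
                counts[class_pos[t], class_pos[p]] += 1
                hits += int(t == p)
        run_acc.append(100.0 * hits / len(labels))
    return MCCVResult(ConfusionMatrix(counts, classes), np.array(run_acc), config)


@dataclass
class ClassifierModel:
    """Full-data model used for projecting new samples (cf. the MCCV chain)."""

    pca: PCAModel
    ca: CanonicalModel
    train_scores: np.ndarray  # canonical coordinates of the training samples
    train_labels: np.ndarray
    classes: list
    config: ClassifierConfig
    display_axis: np.ndarray | None = None  # PCA-space direction for 2-D display

    def to_dict(self) -> dict:
        return {
            "mean": self.pca.mean.tolist(),
            "components": self.pca.components.tolist(),
            "explained_ratio": self.pca.explained_ratio.tolist(),
            "n_retained": self.pca.n_retained,
            "canonical_axes": self.ca.axes.tolist(),
            "canonical_eigenvalues": self.ca.eigenvalues.tolist(),
            "wilks_lambda": self.ca.wilks_lambda,
            "wilks_p_value": self.ca.p_value,
            "n_significant": self.ca.n_significant,
            "train_scores": self.train_scores.tolist(),
            "train_labels": [str(v) for v in self.train_labels],
            "classes": [str(c) for c in self.classes],
            "display_axis": None if self.display_axis is None else self.display_axis.tolist(),
            "config": {
                "explained_variance_threshold": self.config.explained_variance_threshold,
                "mc_runs": self.config.mc_runs,
                "cv_folds": self.config.cv_folds,
                "k_neighbors": self.config.k_neighbors,
                "manova_alpha": self.config.manova_alpha,
                "seed": self.config.seed,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        pca = PCAModel(
            mean=np.array(d["mean"]),
            components=np.array(d["components"]),
            explained_variance=np.array(d["explained_ratio"]),
            explained_ratio=np.array(d["explained_ratio"]),
            n_retained=d["n_retained"],
        )
        axes = np.array(d["canonical_axes"])
        eig = np.array(d["canonical_eigenvalues"])
        ca = CanonicalModel(
            axes, eig, d["wilks_lambda"], float("nan"), 0, d["wilks_p_value"],
            np.array([d["wilks_p_value"]]), d["n_significant"],
        )
        return cls(
            pca, ca,
            np.array(d["train_scores"]),
            np.array(d["train_labels"]),
            d["classes"],
            ClassifierConfig(**d["config"]),
            None if d.get("display_axis") is None else np.array(d["display_axis"]),
        )


def fit_model(X, labels, config: ClassifierConfig = ClassifierConfig()) -> ClassifierModel:
    """Fit the PCA/CA chain on the full data set for subsequent projection."""
    X = np.asarray(getattr(X, "matrix", X), dtype=float)
    labels = np.asarray(labels)
    pca, ca, train_can = _fit_chain(X, labels, config)
    display_axis = None
    if ca.n_significant == 1:
        # leading within-class direction orthogonal to CA1, display only
        scores = pca.transform(X)
        _, Sw, _ = _scatter_matrices(scores, labels)
        a1 = ca.axes[:, 0]
        a1 = a1 / np.linalg.norm(a1)
        P = np.eye(scores.shape[1]) - np.outer(a1, a1)
        Sw_perp = P @ Sw @ P
        w, v = np.linalg.eigh(Sw_perp)
        display_axis = v[:, -1]
    return ClassifierModel(pca, ca, train_can, labels, list(np.unique(labels)), config,
                           display_axis)


def project(model: ClassifierModel, new_samples: np.ndarray):
    """Project samples into the trained PCA-CA subspace and classify them.

    Returns ``(coords, predicted)`` where ``coords`` has 2 columns for
    display: the canonical axes when at least 2 are significant, otherwise
    canonical axis 1 plus the stored within-class residual direction.
    """
    X = np.asarray(getattr(new_samples, "matrix", new_samples), dtype=float)
    X = np.atleast_2d(X)
    if X.shape[1] != model.pca.mean.shape[0]:
        raise InvalidParameterError(
            f"feature dimension {X.shape[1]} does not match model ({model.pca.mean.shape[0]})"
        )
    scores = model.pca.transform(X)
    canonical = model.ca.transform(scores)
    pred = knn_classify(model.train_scores, model.train_labels, canonical,
                        model.config.k_neighbors)
    if canonical.shape[1] >= 2:
        coords = canonical[:, :2]
    elif model.display_axis is not None:
        coords = np.column_stack([canonical[:, 0], scores @ model.display_axis])
    else:
        coords = np.column_stack([canonical[:, 0], np.zeros(len(X))])
    return coords, pred
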