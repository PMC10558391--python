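"""PLS-LDA classification of Raman spectra, written from scratch.

Partial least squares (NIPALS PLS2) compresses the centered spectra matrix
onto a few latent components that covary with class membership (one-hot
response); linear discriminant analysis in the resulting score space then
maximizes between-class over pooled within-class scatter. Prediction is
nearest class mean in discriminant (LD) space. Performance is estimated by
stratified K-fold cross-validation with per-class sensitivity/specificity
and overall accuracy; LD directions can be back-projected onto the
wavenumber axis as loading spectra to show which bands drive separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .spectra import SpectralDataset

__all__ = [
    "PLSModel",
    "LDAModel",
    "PLSLDAModel",
    "CVReport",
    "LDLoadingSpectrum",
    "fit_pls",
    "fit_lda",
    "fit_plslda",
    "kfold_cv",
    "confusion_metrics",
    "ld_loadings",
]


@dataclass(frozen=True)
class PLSModel:
    """NIPALS PLS2 fit: scores of new data are ``(X - x_mean) @ rotations``."""

    x_mean: np.ndarray
    weights: np.ndarray  # W, (p, k)
    loadings: np.ndarray  # P, (p, k)
    y_loadings: np.ndarray  # Q, (c, k)
    rotations: np.ndarray  # R = W (P^T W)^-1, (p, k)
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.x_mean) @ self.rotations


@dataclass(frozen=True)
class LDAModel:
    """LDA in PLS score space; ``directions`` columns are ordered by eigenvalue."""

    classes: np.ndarray
    class_means: np.ndarray  # (c, k) in score space
    scatter_within: np.ndarray  # pooled within-class scatter, (k, k)
    directions: np.ndarray  # (k, n_ld)
    eigenvalues: np.ndarray
    priors: np.ndarray

    def transform(self, scores: np.ndarray) -> np.ndarray:
        return np.atleast_2d(scores) @ self.directions


@dataclass(frozen=True)
class PLSLDAModel:
    """Composed classifier with the label codebook (sorted class values)."""

    pls: PLSModel
    lda: LDAModel
    wavenumbers: np.ndarray | None = None

    @property
    def classes(self) -> np.ndarray:
        return self.lda.classes

    def transform(self, X: np.ndarray) -> np.ndarray:
        """LD scores of raw (preprocessed) spectra."""
        return self.lda.transform(self.pls.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Nearest class mean in LD space (Euclidean); ties go to the lowest class."""
        ld = self.transform(X)
        centers = self.lda.class_means @ self.lda.directions
        d2 = ((ld[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return self.classes[np.argmin(d2, axis=1)]


@dataclass(frozen=True)
class CVReport:
    """Cross-validation outcome aggregated over out-of-fold predictions."""

    K: int
    classes: np.ndarray
    confusion: np.ndarray  # rows = true, cols = predicted
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: float  # pooled out-of-fold accuracy (trace / total)
    fold_accuracies: tuple
    mean_fold_accuracy: float
    fold_assignments: np.ndarray

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "classes": self.classes.tolist(),
            "confusion": self.confusion.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "accuracy": self.accuracy,
            "fold_accuracies": list(self.fold_accuracies),
            "mean_fold_accuracy": self.mean_fold_accuracy,
        }


@dataclass(frozen=True)
class LDLoadingSpectrum:
    """LD directions back-projected onto the wavenumber axis, one row per LD."""

    wavenumbers: np.ndarray
    loadings: np.ndarray  # (n_ld, p)


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (np.asarray(y)[:, None] == classes[None, :]).astype(float)


def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int, tol: float = 1e-10,
            max_iter: int = 500) -> PLSModel:
    """NIPALS PLS2 on a spectra matrix X (n, p) and response matrix Y (n, c).

    X and Y are centered internally. If deflation collapses (zero-norm weight)
    the component count is reduced with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if np.any(np.all(X == 0, axis=1)):
        raise ValueError("X contains a constant-zero spectrum")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - Y.mean(axis=0)
    W, P, Q = [], [], []
    for a in range(n_components):
        u = Yc[:, int(np.argmax(Yc.var(axis=0)))].copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xc.T @ u
            norm = np.linalg.norm(w_new)
            if norm < 1e-14:
                break
            w_new /= norm
            t = Xc @ w_new
            tt = t @ t
            if tt < 1e-14:
                break
            q = Yc.T @ t / tt
            qq = q @ q
            if qq < 1e-14:
                w = w_new
                break
            u_new = Yc @ q / qq
            done = np.linalg.norm(w_new - w) < tol
            w, u = w_new, u_new
            if done:
                break
        t = Xc @ w
        tt = t @ t
        if np.linalg.norm(w) < 1e-14 or tt < 1e-14:
            warnings.warn(
                f"PLS deflation collapsed at component {a + 1}; using {a} components",
                stacklevel=2,
            )
            n_components = a
            break
        p_load = Xc.T @ t / tt
        q_load = Yc.T @ t / tt
        Xc = Xc - np.outer(t, p_load)
        Yc = Yc - np.outer(t, q_load)
        W.append(w)
        P.append(p_load)
        Q.append(q_load)
    if n_components == 0:
        raise ValueError("PLS fit failed: no usable components")
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    Qm = np.column_stack(Q)
    R = Wm @ np.linalg.inv(Pm.T @ Wm)
    return PLSModel(
        x_mean=x_mean, weights=Wm, loadings=Pm, y_loadings=Qm, rotations=R,
        n_components=n_components,
    )


def fit_lda(scores: np.ndarray, labels: np.ndarray, ridge: float = 1e-10) -> LDAModel:
    """LDA via the generalized eigenproblem S_b v = lambda S_w v.

    For two classes LD1 is proportional to the Fisher direction
    ``S_w^-1 (m1 - m2)``. A singular within-class scatter is ridge-regularized
    (epsilon proportional to its trace) with a warning.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    k = scores.shape[1]
    counts = np.array([(labels == c).sum() for c in classes])
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 samples")
    overall = scores.mean(axis=0)
    means = np.vstack([scores[labels == c].mean(axis=0) for c in classes])
    Sw = np.zeros((k, k))
    Sb = np.zeros((k, k))
    for c, m, n_c in zip(classes, means, counts):
        d = scores[labels == c] - m
        Sw += d.T @ d
        diff = (m - overall)[:, None]
        Sb += n_c * (diff @ diff.T)
    cond = np.linalg.cond(Sw)
    if not np.isfinite(cond) or cond > 1e12:
        eps = ridge * max(np.trace(Sw), 1.0)
        warnings.warn(f"singular within-class scatter; ridge {eps:.2e} added", stacklevel=2)
        Sw = Sw + eps * np.eye(k)
    eigvals, eigvecs = linalg.eigh(Sb, Sw)
    order = np.argsort(eigvals)[::-1]
    n_ld = min(classes.size - 1, k)
    directions = eigvecs[:, order[:n_ld]]
    return LDAModel(
        classes=classes,
        class_means=means,
        scatter_within=Sw,
        directions=directions,
        eigenvalues=eigvals[order[:n_ld]],
        priors=counts / counts.sum(),
    )


def _resolve_xy(ds, labels, label_col):
    if isinstance(ds, SpectralDataset):
        X = ds.intensities
        y = ds.labels[label_col].to_numpy() if labels is None else np.asarray(labels)
        return X, y, ds.wavenumbers
    if labels is None:
        raise ValueError("labels are required when passing a raw matrix")
    return np.atleast_2d(np.asarray(ds, dtype=float)), np.asarray(labels), None


def fit_plslda(
    ds,
    labels: np.ndarray | None = None,
    n_components: int = 10,
    label_col: str = "concentration_mM",
) -> PLSLDAModel:
    """Fit PLS then LDA on the PLS scores of a (preprocessed) dataset.

    ``ds`` may be a :class:`SpectralDataset` (class labels taken from
    ``label_col`` unless ``labels`` is given) or a plain (n, p) matrix.
    """
    X, y, wavenumbers = _resolve_xy(ds, labels, label_col)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to fit PLS-LDA")
    pls = fit_pls(X, _one_hot(y, classes), n_components)
    lda = fit_lda(pls.transform(X), y)
    return PLSLDAModel(pls=pls, lda=lda, wavenumbers=wavenumbers)


def _stratified_folds(y: np.ndarray, K: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if idx.size < K:
            raise ValueError(f"class {c!r} has {idx.size} members, fewer than K={K}")
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % K
    return folds


def kfold_cv(
    ds,
    labels: np.ndarray | None = None,
    K: int = 5,
    n_components: int = 10,
    seed: int = 0,
    label_col: str = "concentration_mM",
) -> CVReport:
    """Stratified K-fold cross-validation of PLS-LDA, seed-deterministic.

    Folds are stratified by class and shuffled with the given seed. All
    training-data-dependent statistics (centering, PLS, LDA) are refit inside
    each fold. Out-of-fold predictions are pooled into one confusion matrix;
    per-fold accuracies and their mean are reported alongside.
    """
    X, y, _ = _resolve_xy(ds, labels, label_col)
    classes = np.unique(y)
    folds = _stratified_folds(y, K, seed)
    class_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    fold_accs = []
    for k in range(K):
        test = folds == k
        model = fit_plslda(X[~test], labels=y[~test], n_components=n_components)
        pred = model.predict(X[test])
        for t, p in zip(y[test], pred):
            confusion[class_index[t], class_index[p]] += 1
        fold_accs.append(float((pred == y[test]).mean()))
    sens, spec, acc = confusion_metrics(confusion)
    return CVReport(
        K=K,
        classes=classes,
        confusion=confusion,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        fold_accuracies=tuple(fold_accs),
        mean_fold_accuracy=float(np.mean(fold_accs)),
        fold_assignments=folds,
    )


def confusion_metrics(confusion: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-class sensitivity and specificity, and overall accuracy.

    sensitivity_c = TP_c / (TP_c + FN_c); specificity_c = TN_c / (TN_c + FP_c);
    accuracy = trace / total. A class with no true members gets NaN
    sensitivity with a warning.
    """
    C = np.asarray(confusion)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(C < 0) or not np.all(C == np.rint(C)):
        raise ValueError("confusion matrix must hold non-negative integer counts")
    total = C.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(C).astype(float)
    row = C.sum(axis=1).astype(float)
    col = C.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row > 0, tp / row, np.nan)
        tn = total - row - col + tp
        spec = np.where(total - row > 0, tn / (total - row), np.nan)
    if np.any(row == 0):
        warnings.warn("class with zero true members: sensitivity undefined", stacklevel=2)
    return sens, spec, float(tp.sum() / total)


def ld_loadings(model: PLSLDAModel) -> LDLoadingSpectrum:
    """LD directions composed with the PLS rotation, over the wavenumber axis.

    Sign convention: each loading's largest-magnitude element is positive.
    """
    V = model.pls.rotations @ model.lda.directions  # (p, n_ld)
    loadings = []
    for j in range(V.shape[1]):
        v = V[:, j]
        v = v * np.sign(v[np.argmax(np.abs(v))])
        loadings.append(v)
    w = model.wavenumbers
    if w is None:
        w = np.arange(V.shape[0], dtype=float)
    return LDLoadingSpectrum(wavenumbers=w, loadings=np.vstack(loadings))
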