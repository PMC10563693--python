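"""Chemometric models: PCA exploration, PLS-DA with cross-validated
quality metrics and a permutation diagnostic, and RBF-SVM grid search.

PLS-DA regresses a centered class-indicator matrix Y (one column per
class) on centered spectra X through partial least squares and classifies
by argmax of the predicted indicators. Model quality is reported the way
chemometric software prints it:

* R2Y — fraction of indicator variance explained in fit,
* Q2  — cross-validated counterpart, 1 - PRESS/SS from k-fold CV,
* RMSEE / RMSECV / RMSEP — indicator-scale RMS error on the training
  residuals, the cross-validation predictions, and an external test set.

The permutation diagnostic refits the model on n label permutations,
plots R2Y/Q2 against |corr(permuted y, original y)| and reports the
regression-line intercepts; a fit is flagged as overfitting when the Q2
intercept is nonnegative or any permuted model beats the original.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .metrics import ConfusionCounts, count_confusion

__all__ = [
    "PCAResult",
    "PLSDAModel",
    "PLSDAMetrics",
    "PermutationResult",
    "SVMConfig",
    "pca_fit",
    "plsda_fit",
    "plsda_evaluate",
    "plsda_permutation_test",
    "svm_grid_search",
]


# ---------------------------------------------------------------------- #
# PCA


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray  # [n x k]
    loadings: np.ndarray  # [p x k], orthonormal columns
    explained_variance_ratio: np.ndarray  # [k], fractions of total variance
    mean: np.ndarray


def pca_fit(X: np.ndarray, k: int) -> PCAResult:
    """Mean-centered PCA by singular-value decomposition.

    ratio_i = sigma_i^2 / sum(sigma^2) over all components, so the ratios
    of a full decomposition sum to 1.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 records")
    if not (1 <= k <= min(n - 1, p)):
        raise ValueError(f"k must be in [1, {min(n - 1, p)}], got {k}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = (s**2).sum()
    ratio = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAResult(U[:, :k] * s[:k], Vt[:k].T, ratio, mean)


# ---------------------------------------------------------------------- #
# PLS-DA


@dataclass
class PLSDAModel:
    """Fitted PLS-DA: an indicator-coded PLS regression + argmax rule."""

    pls: PLSRegression
    classes: tuple[str, ...]
    n_components: int
    cv_folds: int

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.pls.predict(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_values(X)
        return np.asarray(self.classes)[np.argmax(scores, axis=1)]


@dataclass
class PLSDAMetrics:
    r2y: float
    q2: float
    rmsee: float
    rmsecv: float
    acc_train: float  # percent
    rmsep: float | None = None
    acc_test: float | None = None


def _indicator(y: np.ndarray, classes: tuple[str, ...]) -> np.ndarray:
    Y = np.zeros((len(y), len(classes)))
    for j, c in enumerate(classes):
        Y[np.asarray(y) == c, j] = 1.0
    return Y


def _fit_pls(X: np.ndarray, Y: np.ndarray, k: int) -> PLSRegression:
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(X, Y)
    return pls


def plsda_fit(
    X_train: np.ndarray,
    y_train,
    n_components: int = 2,
    cv_folds: int = 7,
    seed: int = 0,
) -> tuple[PLSDAModel, PLSDAMetrics]:
    """Fit PLS-DA and compute its training/cross-validation metrics.

    Q2 and RMSECV come from stratified k-fold cross-validation with a
    per-fold refit; R2Y and RMSEE from the training residuals.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs two classes in the training set")
    Y = _indicator(y, classes)
    pls = _fit_pls(X, Y, n_components)
    model = PLSDAModel(pls, classes, n_components, cv_folds)

    Y_hat = pls.predict(X)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum()
    ss_res = ((Y - Y_hat) ** 2).sum()
    r2y = 1.0 - ss_res / ss_tot
    rmsee = float(np.sqrt(((Y - Y_hat) ** 2).mean()))

    press = 0.0
    sq_cv = 0.0
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        fold = _fit_pls(X[tr], Y[tr], min(n_components, len(tr) - 1))
        resid = Y[te] - fold.predict(X[te])
        press += (resid**2).sum()
        sq_cv += (resid**2).sum()
    q2 = 1.0 - press / ss_tot
    rmsecv = float(np.sqrt(sq_cv / Y.size))

    acc_train = 100.0 * float(np.mean(model.predict(X) == y))
    return model, PLSDAMetrics(float(r2y), float(q2), rmsee, rmsecv, acc_train)


def plsda_evaluate(
    model: PLSDAModel, metrics: PLSDAMetrics, X_test: np.ndarray, y_test
) -> tuple[PLSDAMetrics, ConfusionCounts]:
    """Complete the metric set on an external test set (RMSEP, test accuracy).

    Returns a new metrics object; the training-stage metrics are untouched.
    """
    X = np.asarray(X_test, dtype=float)
    if X.shape[1] != model.pls.x_loadings_.shape[0]:
        raise ValueError("test matrix is not on the training grid")
    y = np.asarray(y_test)
    Y = _indicator(y, model.classes)
    resid = Y - model.decision_values(X)
    pred = model.predict(X)
    completed = dataclasses.replace(
        metrics,
        rmsep=float(np.sqrt((resid**2).mean())),
        acc_test=100.0 * float(np.mean(pred == y)),
    )
    return completed, count_confusion(y, pred)


@dataclass
class PermutationResult:
    correlations: np.ndarray  # abscissa, |corr| per point; the original model is at 1
    r2y: np.ndarray
    q2: np.ndarray
    r2_line: tuple[float, float]  # (slope, intercept)
    q2_line: tuple[float, float]
    overfit_flag: bool

    @property
    def r2_intercept(self) -> float:
        return self.r2_line[1]

    @property
    def q2_intercept(self) -> float:
        return self.q2_line[1]


def plsda_permutation_test(
    X: np.ndarray,
    y,
    n_permutations: int = 200,
    n_components: int = 2,
    cv_folds: int = 7,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation diagnostic for a PLS-DA configuration.

    The class labels are permuted ``n_permutations`` times; each permuted
    model's R2Y/Q2 are plotted against the absolute correlation of the
    permuted indicator vector with the original one, a straight line is
    fitted through all points including the unpermuted model (at
    correlation 1), and the intercepts at correlation 0 are reported. A
    healthy model has a negative Q2 intercept and no permuted model
    beating the original.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes = tuple(sorted(set(y)))
    y_num = (y == classes[-1]).astype(float)

    def one(y_labels, fold_seed):
        _, m = plsda_fit(X, y_labels, n_components, cv_folds, seed=fold_seed)
        return m.r2y, m.q2

    corrs = [1.0]
    r2s, q2s = [], []
    r2_0, q2_0 = one(y, seed)
    r2s.append(r2_0)
    q2s.append(q2_0)
    for i in range(n_permutations):
        perm = rng.permutation(len(y))
        y_p = y[perm]
        c = abs(float(np.corrcoef(y_num, y_num[perm])[0, 1]))
        r2, q2 = one(y_p, seed + i + 1)
        corrs.append(c)
        r2s.append(r2)
        q2s.append(q2)
    corrs = np.asarray(corrs)
    r2s = np.asarray(r2s)
    q2s = np.asarray(q2s)
    r2_fit = np.polyfit(corrs, r2s, 1)
    q2_fit = np.polyfit(corrs, q2s, 1)
    overfit = bool(
        q2_fit[1] >= 0
        or np.any(r2s[1:] > r2_0)
        or np.any(q2s[1:] > q2_0)
    )
    return PermutationResult(
        corrs, r2s, q2s, (float(r2_fit[0]), float(r2_fit[1])),
        (float(q2_fit[0]), float(q2_fit[1])), overfit,
    )


# ---------------------------------------------------------------------- #
# SVM


@dataclass(frozen=True)
class SVMConfig:
    c: float
    g: float

    def __post_init__(self) -> None:
        if self.c <= 0 or self.g <= 0:
            raise ValueError("c and g must be > 0")


def default_svm_grid() -> tuple[list[float], list[float]]:
    """Base-2 candidate lists: c in 2^-10..2^20, g in 2^-20..2^4."""
    return (
        [2.0**e for e in range(-10, 21)],
        [2.0**e for e in range(-20, 5)],
    )


def svm_grid_search(
    X_train: np.ndarray,
    y_train,
    grid: tuple[list[float], list[float]] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
):
    """RBF-SVM (c, g) selection by k-fold CV accuracy over a log2 grid.

    Ties in CV accuracy break toward smaller c, then smaller g. Returns
    the refit classifier, the winning :class:`SVMConfig`, the full CV
    table (c, g, accuracy), and the (mean, sd) used for standardization.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    cs, gs = grid if grid is not None else default_svm_grid()
    if not cs or not gs:
        raise ValueError("empty grid")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd if standardize else X

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xs, y))
    for tr, _ in folds:
        if len(set(y[tr])) < 2:
            raise ValueError("degenerate fold with a single class")

    table = []
    best = None  # (neg-acc, c, g) minimized -> highest acc, smallest c then g
    for c in sorted(cs):
        for g in sorted(gs):
            correct = 0
            for tr, te in folds:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(Xs[tr], y[tr])
                correct += int(np.sum(clf.predict(Xs[te]) == y[te]))
            acc = correct / len(y)
            table.append((c, g, acc))
            key = (-acc, c, g)
            if best is None or key < best[0]:
                best = (key, c, g)
    _, c_best, g_best = best
    final = SVC(C=c_best, gamma=g_best, kernel="rbf")
    final.fit(Xs, y)
    return final, SVMConfig(c_best, g_best), table, (mu, sd)
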