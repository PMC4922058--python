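"""PLS-DA of preprocessed spectra against metabolic-cluster labels.

Partial least squares discriminant analysis regresses a one-hot class
response on the (column-centered) spectral matrix via NIPALS with deflation.
Latent-variable count is chosen by stratified cross-validation with a
one-standard-error parsimony rule; cluster separation is assessed by a
permutation test on the mean cross-validated accuracy.

Sign convention: each X-weight vector is flipped so its largest-magnitude
element is positive (scores/loadings flipped consistently), which makes
models bit-reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


@dataclass
class PLSDAModel:
    n_lv: int
    classes: list
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray  # p x A
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # c x A
    scores: np.ndarray  # n x A
    coef: np.ndarray  # p x c, maps centered X to centered class scores
    explained_x: np.ndarray  # % per LV
    explained_y: np.ndarray  # % per LV
    cv_accuracy: pd.Series | None = None  # % per class
    perm_p: float | None = None
    perm_p_per_class: pd.Series | None = None

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"feature length {X.shape[1]} does not match model ({self.x_mean.size})"
            )
        return (X - self.x_mean) @ self.coef + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.predict_scores(X), axis=1)
        return np.asarray(self.classes, dtype=object)[idx]


def _one_hot(y: np.ndarray, classes: list) -> np.ndarray:
    return (np.asarray(y)[:, None] == np.asarray(classes, dtype=object)[None, :]).astype(float)


def fit(X: np.ndarray, y, n_lv: int) -> PLSDAModel:
    """NIPALS PLS2 fit with one-hot response.

    Explained X/Y variance per latent variable is computed from the deflation
    residuals relative to the centered matrices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    Y = _one_hot(y, classes)
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    E = X - x_mean
    F = Y - y_mean
    ssx, ssy = (E**2).sum(), (F**2).sum()
    n, p = E.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((Y.shape[1], n_lv))
    T = np.zeros((n, n_lv))
    ex = np.zeros(n_lv)
    ey = np.zeros(n_lv)
    for a in range(n_lv):
        if (E**2).sum() <= 1e-12 * max(ssx, 1e-300):
            raise ValueError(f"n_lv={n_lv} exceeds the rank of X (rank {a})")
        u = F[:, np.argmax((F**2).sum(axis=0))].copy()
        t_old = None
        for _ in range(500):
            w = E.T @ u
            w /= np.linalg.norm(w)
            t = E @ w
            q = F.T @ t / (t @ t)
            u = F @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) <= 1e-12 * np.linalg.norm(t):
                break
            t_old = t
        flip = np.sign(w[np.argmax(np.abs(w))]) or 1.0
        w, t, q = flip * w, flip * t, flip * q
        pvec = E.T @ t / (t @ t)
        E = E - np.outer(t, pvec)
        F = F - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pvec, q, t
        ex[a] = 100.0 * (t @ t) * (pvec @ pvec) / ssx
        ey[a] = 100.0 * (t @ t) * (q @ q) / ssy
    coef = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSDAModel(
        n_lv=n_lv,
        classes=classes,
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        coef=coef,
        explained_x=ex,
        explained_y=ey,
    )


def _rowspace_project(X: np.ndarray) -> np.ndarray:
    """Project wide matrices onto the row space of the centered data.

    Cross-validated predictions and permutation statistics only involve
    inner products within that space, so replacing X (n x p, p >> n) by its
    n-dimensional representation is exact and much faster.
    """
    if X.shape[1] <= 4 * X.shape[0]:
        return X
    Xc = X - X.mean(axis=0)
    _, _, vh = np.linalg.svd(Xc, full_matrices=False)
    return Xc @ vh.T


def _cv_predictions(
    X: np.ndarray, y: np.ndarray, n_lv: int, cv_folds: int, seed: int
) -> np.ndarray:
    """Out-of-fold predicted classes for each LV count 1..n_lv (n_lv x n)."""
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    counts = pd.Series(y).value_counts()
    if cv_folds > counts.min():
        raise ValueError(
            f"cv_folds={cv_folds} exceeds the smallest class size ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**32))
    preds = np.empty((n_lv, len(y)), dtype=object)
    for train, test in skf.split(X, y):
        model = fit(X[train], y[train], n_lv)
        W, P, Q = model.x_weights, model.x_loadings, model.y_loadings
        Xc = X[test] - model.x_mean
        for a in range(1, n_lv + 1):
            coef_a = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], Q[:, :a].T)
            scores = Xc @ coef_a + model.y_mean
            preds[a - 1, test] = np.asarray(classes, dtype=object)[scores.argmax(axis=1)]
    return preds


def select_n_lv(X, y, max_lv: int = 10, cv_folds: int = 10, seed: int = 0) -> int:
    """Smallest LV count within one standard error of the best mean CV
    accuracy (stratified k-fold)."""
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    X = _rowspace_project(np.asarray(X, dtype=float))
    y = np.asarray(y)
    max_lv = min(max_lv, np.linalg.matrix_rank(X - X.mean(axis=0)))
    preds = _cv_predictions(X, y, max_lv, cv_folds, seed)
    acc = (preds == y[None, :]).mean(axis=1)
    best = int(np.argmax(acc))
    # SE of the best accuracy from its binomial sampling variance
    n = len(y)
    se = np.sqrt(max(acc[best] * (1 - acc[best]), 1e-12) / n)
    return int(np.nonzero(acc >= acc[best] - se)[0][0]) + 1


def classify_and_accuracy(model: PLSDAModel, X, y_true) -> pd.Series:
    """Per-class accuracy (%) of argmax classification, to 0.1 %."""
    y_true = np.asarray(y_true)
    pred = model.predict(np.asarray(X, dtype=float))
    out = {}
    for c in model.classes:
        sel = y_true == c
        out[c] = round(100.0 * (pred[sel] == c).mean(), 1)
    return pd.Series(out, name="accuracy_pct")


def cv_accuracy(
    X, y, n_lv: int, cv_folds: int = 10, seed: int = 0
) -> tuple[float, pd.Series]:
    """Overall and per-class cross-validated accuracy (%)."""
    X = _rowspace_project(np.asarray(X, dtype=float))
    y = np.asarray(y)
    pred = _cv_predictions(X, y, n_lv, cv_folds, seed)[n_lv - 1]
    overall = 100.0 * (pred == y).mean()
    per_class = pd.Series(
        {c: round(100.0 * (pred[y == c] == c).mean(), 1) for c in sorted(set(y.tolist()))}
    )
    return overall, per_class


def permutation_test(
    X,
    y,
    n_perm: int = 1000,
    cv_folds: int = 10,
    seed: int = 0,
    n_lv: int | None = None,
) -> dict:
    """Permutation test of cluster separation.

    The statistic is the mean overall CV accuracy; each permutation shuffles
    the class labels and refits.  p = (#{perm >= observed} + 1)/(n_perm + 1);
    per-class p-values from per-class accuracies are reported alongside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = _rowspace_project(np.asarray(X, dtype=float))
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    if n_lv is None:
        n_lv = select_n_lv(X, y, cv_folds=cv_folds, seed=seed)
    obs_overall, obs_class = cv_accuracy(X, y, n_lv, cv_folds, seed)
    classes = list(obs_class.index)
    exceed = 0
    exceed_class = pd.Series(0, index=classes)
    for b in range(n_perm):
        yb = rng.permutation(y)
        ob, oc = cv_accuracy(X, yb, n_lv, cv_folds, seed)
        exceed += ob >= obs_overall
        exceed_class += (oc >= obs_class).astype(int)
    p = (exceed + 1) / (n_perm + 1)
    p_class = (exceed_class + 1) / (n_perm + 1)
    return {
        "n_lv": n_lv,
        "observed_accuracy": obs_overall,
        "observed_accuracy_per_class": obs_class,
        "p": float(p),
        "p_per_class": p_class,
    }


def fit_full(
    X, y, max_lv: int = 10, cv_folds: int = 10, seed: int = 0,
    n_perm: int | None = None,
) -> PLSDAModel:
    """LV selection + fit + CV accuracies (+ optional permutation test)."""
    X = np.asarray(X, dtype=float)
    n_lv = select_n_lv(X, y, max_lv=max_lv, cv_folds=cv_folds, seed=seed)
    model = fit(X, y, n_lv)
    overall, per_class = cv_accuracy(X, y, n_lv, cv_folds, seed)
    model.cv_accuracy = per_class
    if n_perm:
        res = permutation_test(X, y, n_perm=n_perm, cv_folds=cv_folds, seed=seed, n_lv=n_lv)
        model.perm_p = res["p"]
        model.perm_p_per_class = res["p_per_class"]
    return model


__all__ = [
    "PLSDAModel",
    "fit",
    "select_n_lv",
    "classify_and_accuracy",
    "cv_accuracy",
    "permutation_test",
    "fit_full",
]
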