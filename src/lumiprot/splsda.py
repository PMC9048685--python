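"""Sparse PLS discriminant analysis with repeated-split stability selection.

The sPLS-DA fit follows the NIPALS convention: per component, the X-weight
vector is the covariance direction between the (deflated) data and the
centered class-indicator matrix, soft-thresholded so that exactly ``keepX``
entries survive (ties broken by absolute value, then feature index), then the
data are regressed out along the resulting score.  With ``keepX`` equal to
the number of features the model reduces to dense PLS-DA.

Stability selection refits the model on many stratified training splits and
retains the features whose selection frequency reaches a threshold
(default: selected in at least 50% of the resamples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        feature_ids = [f"f{j}" for j in range(Xv.shape[1])]
    y = np.asarray(y)
    return Xv, y, feature_ids


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Keep the *keep* largest-|w| entries (soft-thresholded), zero the rest."""
    p = len(w)
    if keep >= p:
        return w.copy()
    order = np.lexsort((np.arange(p), -np.abs(w)))  # |w| desc, then index asc
    kept = order[:keep]
    lam = np.abs(w[order[keep]])
    out = np.zeros_like(w)
    out[kept] = np.sign(w[kept]) * (np.abs(w[kept]) - lam)
    if not np.any(out):
        # all survivors tied with the threshold; fall back to hard selection
        out[kept] = w[kept]
    return out


@dataclass
class SplsdaModel:
    classes_: np.ndarray
    feature_ids: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    weights: np.ndarray       # p x ncomp, sparse X-weights
    x_loadings: np.ndarray    # p x ncomp, regression loadings used for deflation
    y_loadings: np.ndarray    # 2 x ncomp
    scores: np.ndarray        # n x ncomp training scores
    centroids: np.ndarray     # 2 x ncomp class centroids in score space
    ncomp: int
    keepX: tuple[int, ...]

    @property
    def rotation(self) -> np.ndarray:
        """W (P^T W)^-1: maps centered/scaled X to component scores."""
        WtP = self.x_loadings.T @ self.weights
        return self.weights @ np.linalg.pinv(WtP.T)

    def transform(self, X) -> np.ndarray:
        Xv = np.asarray(X, dtype=float)
        Xc = (Xv - self.x_mean) / self.x_scale
        return Xc @ self.rotation

    def decision_scores(self, X) -> np.ndarray:
        """Continuous score for the second class (higher -> classes_[1])."""
        T = self.transform(X)
        yhat = T @ self.y_loadings.T
        return yhat[:, 1] - yhat[:, 0]

    def predict(self, X) -> np.ndarray:
        """Maximum-distance rule: nearest class centroid in score space."""
        T = self.transform(X)
        d = ((T[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[d.argmin(axis=1)]

    def selected_features(self, component: int | None = None) -> list[str]:
        """Features with a nonzero weight (in any component by default)."""
        W = self.weights if component is None else self.weights[:, [component]]
        mask = (W != 0).any(axis=1)
        return [f for f, m in zip(self.feature_ids, mask) if m]


def fit_splsda(
    X,
    y,
    ncomp: int = 1,
    keepX: int | tuple[int, ...] | None = None,
    scale: bool = True,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> SplsdaModel:
    """Fit a two-class sPLS-DA model.

    ``keepX`` is the number of surviving features per component (an int
    applies to every component; ``None`` means dense).
    """
    Xv, y, feature_ids = _as_xy(X, y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    n, p = Xv.shape
    if isinstance(keepX, (int, np.integer)):
        keepX = (int(keepX),) * ncomp
    elif keepX is None:
        keepX = (p,) * ncomp
    else:
        keepX = tuple(int(k) for k in keepX)
        if len(keepX) != ncomp:
            raise ValueError("keepX must have one entry per component")
    if any(k < 1 or k > p for k in keepX):
        raise ValueError(f"keepX entries must lie in [1, {p}]")

    Y = np.column_stack([(y == c).astype(float) for c in classes])
    x_mean = Xv.mean(axis=0)
    x_scale = Xv.std(axis=0, ddof=1) if scale else np.ones(p)
    x_scale = np.where(x_scale < 1e-12, 1.0, x_scale)
    Xr = (Xv - x_mean) / x_scale
    Yr = Y - Y.mean(axis=0)

    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    Q = np.zeros((2, ncomp))
    T = np.zeros((n, ncomp))
    for h in range(ncomp):
        u = Yr[:, 0].copy()
        if not np.any(u):
            u = np.ones(n)
        w_old = np.zeros(p)
        for _ in range(max_iter):
            w = Xr.T @ u
            w = _soft_threshold_keep(w, keepX[h])
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = Xr @ w
            tt = t @ t
            if tt == 0:
                break
            q = Yr.T @ t / tt
            nq = np.linalg.norm(q)
            u = Yr @ q / nq if nq > 0 else u
            if np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        t = Xr @ w
        tt = t @ t
        if tt == 0:
            # degenerate component; stop early
            W, P, Q, T = W[:, :h], P[:, :h], Q[:, :h], T[:, :h]
            ncomp = h
            keepX = keepX[:h]
            break
        pvec = Xr.T @ t / tt
        qvec = Yr.T @ t / tt
        Xr = Xr - np.outer(t, pvec)
        Yr = Yr - np.outer(t, qvec)
        W[:, h], P[:, h], Q[:, h], T[:, h] = w, pvec, qvec, t

    centroids = np.vstack([T[y == c].mean(axis=0) for c in classes])
    return SplsdaModel(
        classes_=classes,
        feature_ids=feature_ids,
        x_mean=x_mean,
        x_scale=x_scale,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        centroids=centroids,
        ncomp=ncomp,
        keepX=keepX,
    )


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------


def _balanced_error(y_true: np.ndarray, y_pred: np.ndarray, classes) -> float:
    errs = [np.mean(y_pred[y_true == c] != c) for c in classes]
    return float(np.mean(errs))


def tune_hyperparameters(
    X,
    y,
    ncomp_grid=(1, 2),
    keepX_grid=(5, 10, 25, 50),
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[int, int]:
    """Grid search minimizing cross-validated balanced misclassification rate.

    Ties resolve to the smallest keepX, then the smallest ncomp.
    """
    Xv, y, _ = _as_xy(X, y)
    if not len(ncomp_grid) or not len(keepX_grid):
        raise ValueError("hyperparameter grids must be nonempty")
    classes, counts = np.unique(y, return_counts=True)
    n_folds = min(cv_folds, counts.min())
    if n_folds < 2:
        raise ValueError("smallest class too small for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xv, y))
    best = None
    p = Xv.shape[1]
    for keep in sorted(set(min(int(k), p) for k in keepX_grid)):
        for ncomp in sorted(ncomp_grid):
            bers = []
            for train, test in splits:
                model = fit_splsda(Xv[train], y[train], ncomp=ncomp, keepX=keep)
                bers.append(_balanced_error(y[test], model.predict(Xv[test]), classes))
            key = (float(np.mean(bers)), keep, ncomp)
            if best is None or key < best:
                best = key
    return best[2], best[1]


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    frequencies: pd.Series        # feature -> selection frequency in [0, 1]
    threshold: float
    ncomp: int
    keepX: int
    n_resamples: int
    accuracy: float | None = None
    auc: float | None = None

    @property
    def selected(self) -> list[str]:
        return list(self.frequencies.index[self.frequencies >= self.threshold])


def _stratified_train_indices(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    idx = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        k = max(1, int(round(train_fraction * len(members))))
        k = min(k, len(members) - 1) if len(members) > 1 else 1
        idx.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(idx))


def stability_select(
    X,
    y,
    n_resamples: int = 1000,
    train_fraction: float = 0.8,
    threshold: float = 0.5,
    seed: int = 0,
    ncomp: int | None = None,
    keepX: int | None = None,
    retune_each_resample: bool = False,
    ncomp_grid=(1, 2),
    keepX_grid=(5, 10, 25, 50),
) -> SelectionResult:
    """Repeated stratified-split refitting; keep features selected often enough.

    Hyperparameters are tuned once on the full data by default and reused in
    every resample; ``retune_each_resample=True`` re-runs the grid search
    inside each split (much slower).
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    Xv, y, feature_ids = _as_xy(X, y)
    rng = np.random.default_rng(seed)
    if ncomp is None or keepX is None:
        t_ncomp, t_keep = tune_hyperparameters(
            Xv, y, ncomp_grid, keepX_grid, seed=seed
        )
        ncomp = ncomp if ncomp is not None else t_ncomp
        keepX = keepX if keepX is not None else t_keep
    counts = np.zeros(Xv.shape[1])
    for _ in range(n_resamples):
        train = _stratified_train_indices(y, train_fraction, rng)
        if retune_each_resample:
            nc, kx = tune_hyperparameters(
                Xv[train], y[train], ncomp_grid, keepX_grid,
                seed=int(rng.integers(2**31)),
            )
        else:
            nc, kx = ncomp, keepX
        model = fit_splsda(Xv[train], y[train], ncomp=nc, keepX=kx)
        counts += (model.weights != 0).any(axis=1)
    freqs = pd.Series(counts / n_resamples, index=feature_ids, name="frequency")
    return SelectionResult(
        frequencies=freqs,
        threshold=threshold,
        ncomp=ncomp,
        keepX=keepX,
        n_resamples=n_resamples,
    )


def evaluate_classification(
    X,
    y,
    selection: list[str],
    seed: int = 0,
    ncomp: int = 1,
    n_auc_splits: int = 20,
    test_fraction: float = 0.2,
) -> tuple[float, float]:
    """Accuracy and cross-validated AUC on a selected feature panel.

    Accuracy is the fitted model's prediction accuracy over all samples.
    AUC averages the test-set ROC area over ``n_auc_splits`` stratified
    80/20 splits, refitting on each training portion.
    """
    if not selection:
        raise ValueError(
            "selection is empty; lower the stability threshold or check effects"
        )
    if isinstance(X, pd.DataFrame):
        Xs = X.loc[:, selection]
    else:
        raise TypeError("evaluate_classification needs a DataFrame with named features")
    Xv, y, _ = _as_xy(Xs, y)
    ncomp = min(ncomp, Xv.shape[1])
    model = fit_splsda(Xv, y, ncomp=ncomp)
    accuracy = float(np.mean(model.predict(Xv) == y))

    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_auc_splits):
        train = _stratified_train_indices(y, 1 - test_fraction, rng)
        test = np.setdiff1d(np.arange(len(y)), train)
        if len(np.unique(y[test])) < 2:
            continue
        fold = fit_splsda(Xv[train], y[train], ncomp=ncomp)
        scores = fold.decision_scores(Xv[test])
        aucs.append(roc_auc_score((y[test] == fold.classes_[1]).astype(int), scores))
    auc = float(np.mean(aucs)) if aucs else float("nan")
    return accuracy, auc


# ---------------------------------------------------------------------------
# Hierarchical clustering of samples on the selected panel
# ---------------------------------------------------------------------------


@dataclass
class ClusteringResult:
    linkage: np.ndarray
    leaf_order: list[str]
    ordered_data: pd.DataFrame
    sample_ids: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels in the original sample order."""
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids)


def cluster_samples(X: pd.DataFrame) -> ClusteringResult:
    """Agglomerative clustering of samples: Euclidean distance, complete linkage."""
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if X.shape[1] < 2:
        import warnings

        warnings.warn("fewer than 2 selected features; clustering on what remains")
    Z = hierarchy.linkage(X.to_numpy(dtype=float), method="complete",
                          metric="euclidean")
    order = hierarchy.leaves_list(Z)
    leaf_order = [X.index[i] for i in order]
    return ClusteringResult(
        linkage=Z,
        leaf_order=leaf_order,
        ordered_data=X.iloc[order],
        sample_ids=list(X.index),
    )
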