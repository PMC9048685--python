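"""Ridge-regularized canonical correlation between two peptide blocks.

Canonical directions solve the regularized eigenproblem

    (Cxx + l1*I)^-1 Cxy (Cyy + l2*I)^-1 Cyx  a = rho^2 a

computed through the symmetric form M = Rx^{-1/2} Cxy Ry^{-1} Cyx Rx^{-1/2}
with Rx = Cxx + l1*I, Ry = Cyy + l2*I, so correlations come out real and
sorted.  The sign of each variate pair is fixed by making the largest-|loading|
X feature positive, keeping downstream cluster membership reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .io_model import AnnotationTable
from . import enrichment as _enrichment


@dataclass
class CcaResult:
    correlations: np.ndarray      # nonincreasing, clipped to [0, 1]
    x_loadings: pd.DataFrame      # features x variates (block A directions)
    y_loadings: pd.DataFrame      # features x variates (block B directions)
    lambda1: float
    lambda2: float


def _cov_blocks(X: np.ndarray, Y: np.ndarray):
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Cxx = Xc.T @ Xc / (n - 1)
    Cyy = Yc.T @ Yc / (n - 1)
    Cxy = Xc.T @ Yc / (n - 1)
    return Cxx, Cyy, Cxy


def regularized_cca(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    lambda1: float = 0.1,
    lambda2: float = 0.1,
    n_variates: int | None = None,
) -> CcaResult:
    """Fit ridge-regularized CCA between two samples x features blocks."""
    if list(X.index) != list(Y.index):
        raise ValueError("blocks must share the same samples in the same order")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("regularization must be nonnegative")
    Xv = X.to_numpy(dtype=float)
    Yv = Y.to_numpy(dtype=float)
    Cxx, Cyy, Cxy = _cov_blocks(Xv, Yv)
    p, q = Cxx.shape[0], Cyy.shape[0]
    Rx = Cxx + lambda1 * np.eye(p)
    Ry = Cyy + lambda2 * np.eye(q)

    # symmetric whitened product; eigh keeps everything real
    Rx_inv_sqrt = linalg.inv(linalg.sqrtm(Rx).real)
    K = Rx_inv_sqrt @ Cxy @ linalg.solve(Ry, Cxy.T, assume_a="pos") @ Rx_inv_sqrt
    K = (K + K.T) / 2
    evals, evecs = linalg.eigh(K)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    k = n_variates or min(p, q, X.shape[0] - 1)
    corr = np.sqrt(evals[:k])
    corr = np.clip(corr, 0.0, 1.0)
    A = Rx_inv_sqrt @ evecs[:, :k]
    # B directions from the regression of Y-side on the X variates
    B = linalg.solve(Ry, Cxy.T, assume_a="pos") @ A
    norms = np.linalg.norm(B, axis=0)
    norms[norms == 0] = 1.0
    B = B / norms
    # sign convention: largest-|loading| X feature positive per variate
    for j in range(k):
        lead = np.argmax(np.abs(A[:, j]))
        if A[lead, j] < 0:
            A[:, j] *= -1
            B[:, j] *= -1
    variates = [f"CC{j+1}" for j in range(k)]
    return CcaResult(
        correlations=corr,
        x_loadings=pd.DataFrame(A, index=X.columns, columns=variates),
        y_loadings=pd.DataFrame(B, index=Y.columns, columns=variates),
        lambda1=lambda1,
        lambda2=lambda2,
    )


def tune_regularization(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    grid=(1e-3, 1e-2, 1e-1, 1.0),
    seed: int = 0,
    n_splits: int | None = None,
) -> tuple[float, float]:
    """Grid search maximizing the leave-one-out first canonical correlation.

    For each (l1, l2) pair, each sample is held out, the CCA is fitted on the
    rest, and the held-out sample's variate products are accumulated; the pair
    with the highest out-of-sample first-variate correlation wins.
    """
    n = X.shape[0]
    splits = range(n) if n_splits is None else range(min(n, n_splits))
    best = None
    for l1 in grid:
        for l2 in grid:
            u_out, v_out = [], []
            for i in splits:
                keep = [j for j in range(n) if j != i]
                fit = regularized_cca(X.iloc[keep], Y.iloc[keep], l1, l2, n_variates=1)
                xc = X.iloc[[i]].to_numpy() - X.iloc[keep].to_numpy().mean(axis=0)
                yc = Y.iloc[[i]].to_numpy() - Y.iloc[keep].to_numpy().mean(axis=0)
                u_out.append(float((xc @ fit.x_loadings.to_numpy()[:, 0])[0]))
                v_out.append(float((yc @ fit.y_loadings.to_numpy()[:, 0])[0]))
            if len(u_out) > 2 and np.std(u_out) > 0 and np.std(v_out) > 0:
                score = abs(np.corrcoef(u_out, v_out)[0, 1])
            else:
                score = -np.inf
            key = (score, -l1, -l2)
            if best is None or key > best[0]:
                best = (key, (l1, l2))
    return best[1]


def loading_clusters(
    cca: CcaResult, threshold: float = 0.2, block: str = "y", variate: int = 0
) -> tuple[list[str], list[str]]:
    """Split features by loading sign at |loading| >= threshold on one variate.

    Returns (positive_cluster, negative_cluster).
    """
    loadings = cca.y_loadings if block == "y" else cca.x_loadings
    col = loadings.iloc[:, variate]
    pos = list(col.index[(col >= threshold)])
    neg = list(col.index[(col <= -threshold)])
    return pos, neg


def correlated_cluster_enrichment(
    cca: CcaResult,
    ann: AnnotationTable,
    background,
    threshold: float = 0.2,
    block: str = "y",
    n_permutations: int = 10000,
    seed: int = 0,
    levels=_enrichment.DEFAULT_LEVELS,
) -> dict[str, pd.DataFrame]:
    """Empirical enrichment of the positive and negative loading clusters.

    Empty clusters yield empty result tables rather than errors.
    """
    pos, neg = loading_clusters(cca, threshold, block=block)
    out = {}
    for name, cluster in (("positive", pos), ("negative", neg)):
        if not cluster:
            out[name] = pd.DataFrame()
            continue
        out[name] = _enrichment.empirical_enrichment(
            cluster, ann, background, n_permutations, seed=seed, levels=levels
        )
    return out
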