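"""Explained-variance decomposition of a feature matrix by clinical variables.

Two-step procedure: (1) PCA on the column-centered log-intensity matrix;
(2) for each clinical variable and each retained principal component, the R^2
of the regression of the component scores on the variable (group-indicator
encoding for categorical variables, i.e. a one-way ANOVA R^2; a single
regressor for continuous variables); the variable's explained-variance
proportion is the eigenvalue-weighted sum of those R^2 values, with weights
normalized over the retained eigenvalues.

Each variable is assessed marginally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import ClinicalTable, IntensityMatrix

CONTINUOUS_VARIABLES = {"age", "tils"}


@dataclass
class PCPR2Result:
    explained: pd.Series          # variable -> proportion in [0, 1]
    r2: pd.DataFrame              # variables x components
    eigenvalues: np.ndarray       # retained, nonincreasing
    weights: np.ndarray           # eigenvalues normalized to sum to 1


def run_pca(
    m: IntensityMatrix, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """PCA via SVD of the column-centered matrix.

    Returns (scores, eigenvalues); scores are mutually orthogonal, eigenvalues
    are the score variances (divisor n - 1), nonincreasing.  Components with
    numerically zero eigenvalue are dropped.
    """
    X = m.values
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_comp = min(n - 1, X.shape[1])
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, n_features)={max_comp}"
        )
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    keep = eigenvalues > eigenvalues[0] * 1e-12 if eigenvalues.size else slice(0)
    scores = (U * s)[:, keep][:, :n_components]
    eigenvalues = eigenvalues[keep][:n_components]
    return scores, eigenvalues


def _design_matrix(values: pd.Series, variable: str) -> np.ndarray | None:
    """Column(s) encoding one clinical variable; None if constant."""
    if variable in CONTINUOUS_VARIABLES:
        x = values.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            return None
        return x[:, None]
    codes, uniques = pd.factorize(values)
    if len(uniques) < 2:
        return None
    # one-hot, full rank after dropping the first level (intercept added later)
    return np.eye(len(uniques))[codes][:, 1:]


def _r2(score: np.ndarray, design: np.ndarray) -> float:
    """Coefficient of determination of OLS of score on [1, design]."""
    X = np.column_stack([np.ones(len(score)), design])
    beta, *_ = np.linalg.lstsq(X, score, rcond=None)
    resid = score - X @ beta
    tss = ((score - score.mean()) ** 2).sum()
    if tss == 0:
        return 0.0
    return float(max(0.0, 1.0 - (resid**2).sum() / tss))


def compute_pcpr2(
    m: IntensityMatrix,
    clinical: ClinicalTable,
    variables: list[str],
    n_components: int | None = None,
) -> PCPR2Result:
    """Proportion of dataset variability explained by each clinical variable."""
    clin = clinical.aligned_to(m.sample_ids).data
    scores, eigenvalues = run_pca(m, n_components)
    weights = eigenvalues / eigenvalues.sum()
    r2 = pd.DataFrame(
        0.0, index=variables, columns=[f"PC{k+1}" for k in range(len(eigenvalues))]
    )
    explained = {}
    for v in variables:
        design = _design_matrix(clin[v], v)
        if design is None:
            import warnings

            warnings.warn(f"clinical variable {v!r} is constant; explained set to 0")
            explained[v] = 0.0
            continue
        for k in range(scores.shape[1]):
            r2.loc[v, f"PC{k+1}"] = _r2(scores[:, k], design)
        explained[v] = float((weights * r2.loc[v].to_numpy()).sum())
    return PCPR2Result(
        explained=pd.Series(explained, name="explained"),
        r2=r2,
        eigenvalues=eigenvalues,
        weights=weights,
    )


def permutation_threshold(
    m: IntensityMatrix,
    clinical: ClinicalTable,
    variable: str,
    n_permutations: int = 200,
    quantile: float = 0.95,
    n_components: int | None = None,
    seed: int = 0,
) -> float:
    """Null quantile of explained(variable) under sample-label permutation.

    The PCA is fixed; only the variable's sample labels are permuted.
    """
    rng = np.random.default_rng(seed)
    clin = clinical.aligned_to(m.sample_ids).data
    scores, eigenvalues = run_pca(m, n_components)
    weights = eigenvalues / eigenvalues.sum()
    values = clin[variable].reset_index(drop=True)
    nulls = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = values.iloc[rng.permutation(len(values))].reset_index(drop=True)
        design = _design_matrix(perm, variable)
        if design is None:
            nulls[b] = 0.0
            continue
        r2s = np.array([_r2(scores[:, k], design) for k in range(scores.shape[1])])
        nulls[b] = float((weights * r2s).sum())
    return float(np.quantile(nulls, quantile))
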