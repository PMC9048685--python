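"""Over-representation testing of selected peptide sets with a permutation null.

Each taxonomic rank, and the function level, is tested separately.  For every
category the observed count of selected peptides is compared with the
expectation under random selection via a one-sided Fisher (hypergeometric
tail) test, and via an empirical p-value from permutations that reassign
category labels uniformly at random across the background peptides while
preserving category sizes:

    empirical p = (1 + #{permutation count >= observed}) / (B + 1)

A sensitivity analysis repeats selection and enrichment on the residuals of
the log intensities regressed on clinical covariates; an enrichment is
flagged significant when its empirical p is below alpha in the main and/or
the sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    RANKS,
    AnnotationTable,
    ClinicalTable,
    ComparisonSpec,
    IntensityMatrix,
    assign_groups,
    log_transform,
)
from . import splsda

DEFAULT_LEVELS = tuple(RANKS) + ("function",)
LOW_SUPPORT_MIN_PEPTIDES = 2


def _check_sets(selected, background):
    selected = list(dict.fromkeys(selected))
    background = list(dict.fromkeys(background))
    if not selected:
        raise ValueError("selected set is empty")
    extra = set(selected) - set(background)
    if extra:
        raise ValueError(f"selected features outside background: {sorted(extra)}")
    return selected, background


def category_enrichment(
    selected,
    ann: AnnotationTable,
    background,
    levels=DEFAULT_LEVELS,
) -> pd.DataFrame:
    """One-sided Fisher over-representation test per category at each level.

    Columns: level, category, observed, n_selected_annotated, category_size,
    background_size, expected_proportion, fisher_p.
    """
    selected, background = _check_sets(selected, background)
    sel_set = set(selected)
    rows = []
    for level in levels:
        cats = ann.categories(level, features=background).dropna()
        n_annot = len(cats)
        sel_annot = cats.index.isin(sel_set)
        n_sel_annot = int(sel_annot.sum())
        for cat, members in cats.groupby(cats).groups.items():
            K = len(members)
            k = int(sum(1 for f in members if f in sel_set))
            # P(X >= k), X ~ Hypergeom(N=n_annot, K, n=n_sel_annot)
            p = float(stats.hypergeom.sf(k - 1, n_annot, K, n_sel_annot))
            rows.append(
                {
                    "level": level,
                    "category": cat,
                    "observed": k,
                    "n_selected_annotated": n_sel_annot,
                    "category_size": K,
                    "background_size": n_annot,
                    "expected_proportion": K / n_annot if n_annot else np.nan,
                    "fisher_p": p,
                    "low_support": k < LOW_SUPPORT_MIN_PEPTIDES,
                }
            )
    return pd.DataFrame(rows)


def empirical_enrichment(
    selected,
    ann: AnnotationTable,
    background,
    n_permutations: int = 10000,
    seed: int = 0,
    levels=DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Fisher table plus permutation-based empirical p-values.

    Permutations shuffle the category labels over the annotated background
    (category sizes preserved exactly) and recount selected members.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    result = category_enrichment(selected, ann, background, levels)
    selected, background = _check_sets(selected, background)
    sel_set = set(selected)
    rng = np.random.default_rng(seed)
    emp = np.ones(len(result))
    for level, block in result.groupby("level", sort=False):
        cats = ann.categories(level, features=background).dropna()
        if cats.empty:
            continue
        codes, uniques = pd.factorize(cats)
        n_cat = len(uniques)
        sel_mask = cats.index.isin(sel_set).nonzero()[0]
        obs = np.bincount(codes[sel_mask], minlength=n_cat)
        ge = np.zeros(n_cat, dtype=np.int64)
        for _ in range(n_permutations):
            perm = rng.permutation(codes)
            counts = np.bincount(perm[sel_mask], minlength=n_cat)
            ge += counts >= obs
        pvals = (1.0 + ge) / (n_permutations + 1.0)
        lookup = dict(zip(uniques, pvals))
        emp[block.index] = [lookup[c] for c in block["category"]]
    result["empirical_p"] = emp
    return result


def direction_of_enrichment(
    result: pd.DataFrame,
    selected,
    ann: AnnotationTable,
    m: IntensityMatrix,
    groups: dict[str, str],
    group_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Annotate each category with the group carrying the higher abundance.

    Direction is the group with the larger summed raw intensity of the
    category's selected peptides (averaged per sample to tolerate unequal
    group sizes).
    """
    group_labels = group_labels or {"A": "A", "B": "B"}
    gser = pd.Series(groups).loc[m.sample_ids]
    directions = []
    for _, row in result.iterrows():
        cats = ann.categories(row["level"], features=list(selected))
        members = [f for f in selected if cats.get(f) == row["category"]]
        if not members:
            directions.append(None)
            continue
        sums = m.data.loc[:, members].sum(axis=1)
        mean_a = sums[gser == "A"].mean()
        mean_b = sums[gser == "B"].mean()
        directions.append(group_labels["A"] if mean_a >= mean_b else group_labels["B"])
    out = result.copy()
    out["higher_in"] = directions
    return out


# ---------------------------------------------------------------------------
# Covariate residualization and sensitivity analysis
# ---------------------------------------------------------------------------

_CATEGORICAL = ("gender", "site", "stage", "grade")


def _covariate_design(clin: pd.DataFrame, covariates) -> np.ndarray:
    cols = [np.ones(len(clin))]
    for cov in covariates:
        if cov in ("age", "tils"):
            cols.append(clin[cov].to_numpy(dtype=float))
        elif cov in _CATEGORICAL:
            codes, uniques = pd.factorize(clin[cov])
            for lvl in range(1, len(uniques)):
                cols.append((codes == lvl).astype(float))
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("collinear covariate design; redundant columns resolved by "
                      "minimum-norm least squares")
    return X


def residualize(
    log_m: IntensityMatrix, clinical: ClinicalTable, covariates
) -> pd.DataFrame:
    """Residuals of each feature's log intensity regressed on the covariates.

    With no covariates the data are returned unchanged.
    """
    if not covariates:
        return log_m.data.copy()
    clin = clinical.aligned_to(log_m.sample_ids).data
    X = _covariate_design(clin, covariates)
    Y = log_m.values
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, index=log_m.sample_ids, columns=log_m.feature_ids)


@dataclass
class EnrichmentAnalysis:
    """Merged main + sensitivity enrichment for one comparison."""

    comparison: ComparisonSpec
    table: pd.DataFrame          # includes empirical_p_main / empirical_p_sensitivity
    selection_main: splsda.SelectionResult
    selection_sensitivity: splsda.SelectionResult | None


ALL_COVARIATES = ("age", "gender", "site", "stage", "grade", "tils")


def default_covariates(comparison: ComparisonSpec) -> tuple[str, ...]:
    """Every clinical covariate except the comparison variable itself."""
    return tuple(c for c in ALL_COVARIATES if c != comparison.variable)


def run_enrichment_analysis(
    m: IntensityMatrix,
    clinical: ClinicalTable,
    ann: AnnotationTable,
    comparison: ComparisonSpec,
    covariates: tuple[str, ...] | None = None,
    n_resamples: int = 1000,
    threshold: float = 0.5,
    n_permutations: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    levels=DEFAULT_LEVELS,
    ncomp: int | None = None,
    keepX: int | None = None,
    pseudocount: float = 1.0,
) -> EnrichmentAnalysis:
    """Full main + sensitivity pipeline for one clinical comparison.

    Main analysis: stability selection on log intensities, then empirical
    enrichment of the selected set against the full background.  Sensitivity:
    the same pipeline on covariate-residualized log intensities.  The merged
    table carries both empirical p-values and a ``significant`` flag
    (empirical p < alpha in main and/or sensitivity).
    """
    if covariates is None:
        covariates = default_covariates(comparison)
    if comparison.variable in covariates:
        raise ValueError("covariates must exclude the comparison variable")
    clin = clinical.aligned_to(m.sample_ids)
    groups, _ = assign_groups(clin, comparison)
    y = np.array([groups[s] for s in m.sample_ids])
    logm = log_transform(m, pseudocount)
    background = m.feature_ids
    labels = {"A": comparison.group_a_label, "B": comparison.group_b_label}

    sel_main = splsda.stability_select(
        logm.data, y, n_resamples=n_resamples, threshold=threshold, seed=seed,
        ncomp=ncomp, keepX=keepX,
    )
    main = empirical_enrichment(
        sel_main.selected, ann, background, n_permutations, seed=seed, levels=levels
    )
    main = direction_of_enrichment(main, sel_main.selected, ann, m, groups, labels)

    sel_sens = None
    if covariates:
        resid = residualize(logm, clin, covariates)
        sel_sens = splsda.stability_select(
            resid, y, n_resamples=n_resamples, threshold=threshold, seed=seed + 1,
            ncomp=ncomp, keepX=keepX,
        )
        if sel_sens.selected:
            sens = empirical_enrichment(
                sel_sens.selected, ann, background, n_permutations,
                seed=seed + 1, levels=levels,
            )
        else:
            sens = main.iloc[0:0]
    else:
        sens = main.copy()
        sens = sens.rename(columns={"empirical_p": "empirical_p"})

    merged = main.rename(
        columns={"empirical_p": "empirical_p_main", "fisher_p": "fisher_p_main"}
    )
    sens_cols = sens[["level", "category", "empirical_p"]].rename(
        columns={"empirical_p": "empirical_p_sensitivity"}
    )
    merged = merged.merge(sens_cols, on=["level", "category"], how="left")
    sig_main = merged["empirical_p_main"] < alpha
    sig_sens = merged["empirical_p_sensitivity"] < alpha
    merged["significant_main"] = sig_main
    merged["significant_sensitivity"] = sig_sens.fillna(False)
    merged["significant"] = merged["significant_main"] | merged["significant_sensitivity"]
    merged["significant_both"] = merged["significant_main"] & merged[
        "significant_sensitivity"
    ].fillna(False)
    return EnrichmentAnalysis(
        comparison=comparison,
        table=merged,
        selection_main=sel_main,
        selection_sensitivity=sel_sens,
    )
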