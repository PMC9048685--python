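"""Per-sample alpha diversity and nonparametric group comparisons.

Richness is the count of nonzero-abundance peptides.  Shannon diversity uses
within-sample relative abundances p_i with the convention that zero-abundance
peptides contribute 0 to the sum; the returned index is the standard
nonnegative H = -sum p_i ln(p_i) in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ClinicalTable, IntensityMatrix


def richness(row: np.ndarray) -> int:
    """Number of strictly positive entries."""
    row = np.asarray(row, dtype=float)
    if (row < 0).any():
        raise ValueError("abundances must be nonnegative")
    return int((row > 0).sum())


def shannon(row: np.ndarray) -> float:
    """Shannon index H in nats; H = 0 for rows with at most one positive entry."""
    row = np.asarray(row, dtype=float)
    if (row < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = row.sum()
    if total == 0:
        return 0.0
    p = row[row > 0] / total
    p = p[p > 0]  # guard against underflow of extreme ratios
    return float(-(p * np.log(p)).sum())


def diversity_table(m: IntensityMatrix) -> pd.DataFrame:
    """Per-sample richness and Shannon H."""
    values = m.values
    return pd.DataFrame(
        {
            "richness": [(r > 0).sum() for r in values],
            "shannon": [shannon(r) for r in values],
        },
        index=m.sample_ids,
    )


@dataclass
class GroupTestResult:
    test: str           # "wilcoxon-rank-sum" or "kruskal-wallis"
    statistic: float
    pvalue: float
    group_sizes: dict[str, int]


def compare_alpha_diversity(
    values: pd.Series, groups: pd.Series
) -> GroupTestResult:
    """Two groups -> Wilcoxon rank-sum; three or more -> Kruskal-Wallis.

    The two-sample test uses the Mann-Whitney U formulation with scipy's
    ``method="auto"`` (exact for small tie-free samples, normal approximation
    with tie correction otherwise), two-sided.
    """
    values = pd.Series(values)
    groups = pd.Series(groups).loc[values.index]
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g].to_numpy() for g in labels]
    sizes = {str(g): len(s) for g, s in zip(labels, samples)}
    if any(len(s) < 1 for s in samples):
        raise ValueError("every group needs at least one observation")
    if len(labels) == 2:
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided",
                                 method="auto")
        return GroupTestResult("wilcoxon-rank-sum", float(res.statistic),
                               float(res.pvalue), sizes)
    res = stats.kruskal(*samples)
    return GroupTestResult("kruskal-wallis", float(res.statistic),
                           float(res.pvalue), sizes)


def compare_by_clinical(
    m: IntensityMatrix,
    clinical: ClinicalTable,
    variable: str,
    age_bins: tuple[float, ...] = (0, 65, 75, 200),
) -> dict[str, GroupTestResult]:
    """Test richness and Shannon H across groups of one clinical variable.

    ``age`` is binned on ``age_bins`` (left-open intervals, configurable);
    ``tils`` is dichotomized at >= 5% vs 0%.
    """
    clin = clinical.aligned_to(m.sample_ids).data
    if variable == "age":
        groups = pd.cut(clin["age"], bins=list(age_bins)).astype(str)
    elif variable == "tils":
        groups = np.where(clin["tils"] >= 5, "TILs +", "TILs -")
        groups = pd.Series(groups, index=clin.index)
    elif variable in ("gender", "site", "stage", "grade"):
        groups = clin[variable]
    else:
        raise ValueError(f"unsupported clinical variable {variable!r}")
    groups.index = pd.Index(m.sample_ids)
    div = diversity_table(m)
    return {
        metric: compare_alpha_diversity(div[metric], groups)
        for metric in ("richness", "shannon")
    }
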