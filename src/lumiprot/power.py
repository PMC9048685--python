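"""Empirical power and sample-size estimation for differential analyses.

A large two-group reference population is simulated from a fitted (or
default) zero-inflated log-normal reference with a stated number of
differentially abundant features injected at log2 fold changes of 1.25, 1.5
and 2.  For each candidate per-group sample size N, many random subsamples
are drawn; per feature a two-sided rank-sum test on log intensities is run
and Benjamini-Hochberg adjusted over all features; empirical power for a fold
change tier is the mean rejection rate of that tier's injected features
across subsamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import EffectSpec, ReferenceDistribution, generate_cohort

DEFAULT_TIERS = (1.25, 1.5, 2.0)
NOT_REACHED = -1


@dataclass
class PowerCurve:
    """Empirical power on an N x log2FC grid, plus the null rejection rate."""

    power: pd.DataFrame            # index: N per group, columns: log2FC tiers
    null_rejection: pd.Series      # index: N; mean rejection rate of null features
    n_subsamples: int
    alpha: float
    correction: str = "benjamini-hochberg"
    test: str = "ranksum"

    def __post_init__(self):
        if self.power.isna().any().any():
            raise ValueError("power grid has missing cells")


def build_reference_population(
    ref: ReferenceDistribution,
    n_per_group: int = 5000,
    n_effect_features: int = 300,
    tiers=DEFAULT_TIERS,
    seed: int = 0,
):
    """Simulate the two-group reference population with tiered injected effects.

    ``n_effect_features`` is split evenly across the fold-change tiers; the
    perturbed features are the first ones of the feature space (the reference
    order carries no meaning for exchangeable synthetic features).

    Returns (matrix, truth) where truth maps each feature to its injected
    log2FC tier (0 for null features) and records the per-sample groups.
    """
    if n_effect_features % len(tiers):
        raise ValueError("n_effect_features must split evenly across tiers")
    if n_effect_features > ref.n_features:
        raise ValueError("more effect features than features in the reference")
    per_tier = n_effect_features // len(tiers)
    log2fc = {}
    for t, tier in enumerate(tiers):
        for fid in ref.feature_ids[t * per_tier : (t + 1) * per_tier]:
            log2fc[fid] = tier
    effects = EffectSpec(log2fc=log2fc, up_group="A")
    matrix, _clinical, truth = generate_cohort(
        ref, (n_per_group, n_per_group), effects, seed=seed
    )
    return matrix, truth


def _rejections(
    log_a: np.ndarray, log_b: np.ndarray, alpha: float, test: str
) -> np.ndarray:
    """Boolean per-feature rejection after BH correction across all features."""
    if test == "ranksum":
        res = stats.mannwhitneyu(
            log_a, log_b, axis=0, alternative="two-sided", method="asymptotic"
        )
        pvals = np.asarray(res.pvalue)
    elif test == "ttest":
        res = stats.ttest_ind(log_a, log_b, axis=0)
        pvals = np.asarray(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    pvals = np.nan_to_num(pvals, nan=1.0)
    adjusted = stats.false_discovery_control(pvals, method="bh")
    return adjusted < alpha


def estimate_power(
    population,
    truth: pd.DataFrame,
    n_grid,
    n_subsamples: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    test: str = "ranksum",
    pseudocount: float = 1.0,
) -> PowerCurve:
    """Empirical power per (N per group, log2FC tier) by repeated subsampling."""
    fc = truth.attrs["effect_log2fc"]
    groups = truth.set_index("sample_id")["group"]
    values = np.log2(population.values + pseudocount)
    a_rows = np.flatnonzero((groups == "A").to_numpy())
    b_rows = np.flatnonzero((groups == "B").to_numpy())
    tiers = sorted(set(fc[fc != 0]))
    tier_masks = {tier: (fc == tier).to_numpy() for tier in tiers}
    null_mask = (fc == 0).to_numpy()

    n_grid = sorted(int(n) for n in n_grid)
    if any(n < 2 for n in n_grid):
        raise ValueError("N per group must be >= 2")
    if max(n_grid) > min(len(a_rows), len(b_rows)):
        raise ValueError("N exceeds the population group size")

    rng = np.random.default_rng(seed)
    power = pd.DataFrame(index=n_grid, columns=tiers, dtype=float)
    null_rate = pd.Series(index=n_grid, dtype=float)
    for n in n_grid:
        tier_hits = {tier: 0.0 for tier in tiers}
        null_hits = 0.0
        for _ in range(n_subsamples):
            sub_a = rng.choice(a_rows, size=n, replace=False)
            sub_b = rng.choice(b_rows, size=n, replace=False)
            rej = _rejections(values[sub_a], values[sub_b], alpha, test)
            for tier, mask in tier_masks.items():
                tier_hits[tier] += rej[mask].mean()
            if null_mask.any():
                null_hits += rej[null_mask].mean()
        for tier in tiers:
            power.loc[n, tier] = tier_hits[tier] / n_subsamples
        null_rate[n] = null_hits / n_subsamples
    power.index.name = "n_per_group"
    power.columns.name = "log2fc"
    return PowerCurve(
        power=power,
        null_rejection=null_rate,
        n_subsamples=n_subsamples,
        alpha=alpha,
        test=test,
    )


def minimum_n_for_power(curve: PowerCurve, target: float = 0.8) -> pd.Series:
    """Smallest grid N reaching the target power, per log2FC tier.

    Tiers never reaching the target get the sentinel ``NOT_REACHED`` (-1).
    """
    if curve.power.empty:
        raise ValueError("empty power curve")
    out = {}
    for tier in curve.power.columns:
        reaching = curve.power.index[curve.power[tier] >= target]
        out[tier] = int(reaching.min()) if len(reaching) else NOT_REACHED
    return pd.Series(out, name=f"min_n_power_{target}")
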