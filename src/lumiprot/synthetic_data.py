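"""Seeded synthetic cohorts with known injected effects.

Intensities follow a zero-inflated log-normal model: each feature f has a
detection probability pi_f and, when detected, an intensity exp(Normal(mu_f,
sigma_f)).  Differential abundance is injected as a location shift of
log2fc * ln(2) on the log scale in one group, i.e. an exact multiplicative
fold change of 2**log2fc on detected intensities; detection probabilities are
left unperturbed.

All generators are pure functions of (inputs, seed).  A single integer seed
fans out to independent substreams (intensity / clinical / annotation) via
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import RANKS, AnnotationTable, ClinicalTable, IntensityMatrix

SIGMA_FLOOR = 0.05

# substream indices for SeedSequence.spawn
_STREAM_INTENSITY, _STREAM_CLINICAL, _STREAM_ANNOTATION = 0, 1, 2


@dataclass
class ReferenceDistribution:
    """Per-feature zero-inflated log-normal parameters."""

    feature_ids: list[str]
    pi: np.ndarray      # detection probability, in [0, 1]
    mu: np.ndarray      # location of log intensity (natural log)
    sigma: np.ndarray   # scale of log intensity, > 0

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        p = len(self.feature_ids)
        if not (len(self.pi) == len(self.mu) == len(self.sigma) == p):
            raise ValueError("parameter arrays must match feature_ids length")
        if ((self.pi < 0) | (self.pi > 1)).any():
            raise ValueError("pi must lie in [0, 1]")
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class EffectSpec:
    """Features to perturb, their signed log2 fold changes, and the up group."""

    log2fc: Mapping[str, float] = field(default_factory=dict)
    up_group: Literal["A", "B"] = "A"

    def __post_init__(self):
        for fid, fc in self.log2fc.items():
            if not np.isfinite(fc) or fc == 0:
                raise ValueError(f"log2fc for {fid!r} must be finite and nonzero")
        if self.up_group not in ("A", "B"):
            raise ValueError("up_group must be 'A' or 'B'")


def fit_reference_distribution(m: IntensityMatrix) -> ReferenceDistribution:
    """Estimate (pi, mu, sigma) per feature from an observed matrix.

    pi is the nonzero fraction; mu and sigma are the mean and standard
    deviation of the natural log of the nonzero entries, with a floor of
    ``SIGMA_FLOOR`` on sigma.  Never-detected features get pi = 0 and default
    location parameters.
    """
    if m.shape[0] < 2:
        raise ValueError("need at least 2 samples to fit a reference distribution")
    values = m.values
    detected = values > 0
    pi = detected.mean(axis=0)
    mu = np.zeros(m.shape[1])
    sigma = np.full(m.shape[1], SIGMA_FLOOR)
    for j in range(m.shape[1]):
        obs = values[detected[:, j], j]
        if obs.size:
            logs = np.log(obs)
            mu[j] = logs.mean()
            if obs.size > 1:
                sigma[j] = max(logs.std(ddof=1), SIGMA_FLOOR)
    return ReferenceDistribution(m.feature_ids, pi, mu, sigma)


def default_reference(
    n_features: int = 2000,
    seed: int | None = 0,
    pi_range: tuple[float, float] = (0.6, 1.0),
    mu_range: tuple[float, float] = (8.0, 16.0),
    sigma_range: tuple[float, float] = (0.5, 1.5),
) -> ReferenceDistribution:
    """A documented default reference for when no observed matrix is supplied.

    Detection probabilities, log-locations and log-scales are drawn uniformly
    from the stated ranges; the defaults mimic moderately zero-inflated,
    heavy-tailed peptide intensities.
    """
    rng = np.random.default_rng(seed)
    feature_ids = [f"pep{i:05d}" for i in range(n_features)]
    return ReferenceDistribution(
        feature_ids=feature_ids,
        pi=rng.uniform(*pi_range, n_features),
        mu=rng.uniform(*mu_range, n_features),
        sigma=rng.uniform(*sigma_range, n_features),
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _sample_clinical(sample_ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariates drawn from marginals resembling the pilot cohort."""
    n = len(sample_ids)
    tils_pool = np.array([5.0, 10.0, 20.0, 50.0, 60.0])
    tils = np.where(
        rng.random(n) < 0.5, 0.0, rng.choice(tils_pool, size=n)
    )
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "gender": rng.choice(["M", "F"], size=n, p=[14 / 24, 10 / 24]),
            "age": np.clip(np.round(rng.normal(73, 11, n)), 30, 95).astype(int),
            "site": rng.choice(
                ["right colon", "left colon"], size=n, p=[15 / 24, 9 / 24]
            ),
            "stage": rng.choice(
                ["I", "II", "III", "IV"], size=n, p=[6 / 24, 6 / 24, 10 / 24, 2 / 24]
            ),
            "grade": rng.choice(["G1", "G2", "G3"], size=n, p=[2 / 24, 15 / 24, 7 / 24]),
            "tils": tils,
        }
    )


def generate_cohort(
    ref: ReferenceDistribution,
    n_per_group: tuple[int, int],
    effects: EffectSpec | None = None,
    seed: int = 0,
) -> tuple[IntensityMatrix, ClinicalTable, pd.DataFrame]:
    """Simulate a two-group cohort from a reference distribution.

    Returns the intensity matrix, a clinical table with covariates drawn from
    documented marginals, and a truth table with per-sample group labels plus
    per-feature injected log2 fold changes (0 for unperturbed features, stored
    as DataFrame attrs ``effect_log2fc`` / ``up_group``).

    Effects multiply detected intensities by ``2**log2fc`` in the designated
    group only, so all other marginals are identical across groups under
    matched seeds.
    """
    effects = effects or EffectSpec()
    n_a, n_b = n_per_group
    if n_a < 1 or n_b < 1:
        raise ValueError("each group needs at least one sample")
    unknown = set(effects.log2fc) - set(ref.feature_ids)
    if unknown:
        raise ValueError(f"effect feature ids outside feature space: {sorted(unknown)}")

    streams = np.random.SeedSequence(seed).spawn(3)
    rng = np.random.default_rng(streams[_STREAM_INTENSITY])
    n = n_a + n_b
    p = ref.n_features
    detected = rng.random((n, p)) < ref.pi[None, :]
    log_intensity = rng.normal(ref.mu[None, :], ref.sigma[None, :], size=(n, p))
    values = np.where(detected, np.exp(log_intensity), 0.0)

    sample_ids = [f"sim{i:05d}" for i in range(n)]
    group = np.array(["A"] * n_a + ["B"] * n_b)

    fc = np.zeros(p)
    if effects.log2fc:
        idx = {fid: j for j, fid in enumerate(ref.feature_ids)}
        up_rows = group == effects.up_group
        for fid, l2fc in effects.log2fc.items():
            j = idx[fid]
            fc[j] = l2fc
            values[up_rows, j] *= 2.0 ** l2fc

    matrix = IntensityMatrix(
        pd.DataFrame(values, index=sample_ids, columns=ref.feature_ids)
    )
    clin_rng = np.random.default_rng(streams[_STREAM_CLINICAL])
    clinical = ClinicalTable(_sample_clinical(sample_ids, clin_rng))
    truth = pd.DataFrame({"sample_id": sample_ids, "group": group})
    truth.attrs["effect_log2fc"] = pd.Series(fc, index=ref.feature_ids)
    truth.attrs["up_group"] = effects.up_group
    return matrix, clinical, truth


def bootstrap_cohort(
    m: IntensityMatrix,
    n_per_group: tuple[int, int],
    effects: EffectSpec | None = None,
    seed: int = 0,
) -> tuple[IntensityMatrix, ClinicalTable, pd.DataFrame]:
    """Alternative generator: resample observed sample rows with replacement.

    Kept as a nonparametric counterpart to :func:`generate_cohort`; injected
    effects are applied identically (multiplicative on nonzero entries).
    """
    effects = effects or EffectSpec()
    n_a, n_b = n_per_group
    streams = np.random.SeedSequence(seed).spawn(3)
    rng = np.random.default_rng(streams[_STREAM_INTENSITY])
    n = n_a + n_b
    rows = rng.integers(0, m.shape[0], size=n)
    values = m.values[rows].copy()
    sample_ids = [f"boot{i:05d}" for i in range(n)]
    group = np.array(["A"] * n_a + ["B"] * n_b)
    fc = np.zeros(m.shape[1])
    if effects.log2fc:
        unknown = set(effects.log2fc) - set(m.feature_ids)
        if unknown:
            raise ValueError(
                f"effect feature ids outside feature space: {sorted(unknown)}"
            )
        idx = {fid: j for j, fid in enumerate(m.feature_ids)}
        up_rows = group == effects.up_group
        for fid, l2fc in effects.log2fc.items():
            j = idx[fid]
            fc[j] = l2fc
            values[up_rows, j] *= 2.0 ** l2fc
    matrix = IntensityMatrix(
        pd.DataFrame(values, index=sample_ids, columns=m.feature_ids)
    )
    clin_rng = np.random.default_rng(streams[_STREAM_CLINICAL])
    clinical = ClinicalTable(_sample_clinical(sample_ids, clin_rng))
    truth = pd.DataFrame({"sample_id": sample_ids, "group": group})
    truth.attrs["effect_log2fc"] = pd.Series(fc, index=m.feature_ids)
    truth.attrs["up_group"] = effects.up_group
    return matrix, clinical, truth


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

#: genus -> (phylum, class, order, family); dominant gut genera as defaults
_DEFAULT_TREE: dict[str, tuple[str, str, str, str]] = {
    "Bacteroides": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
    "Faecalibacterium": ("Firmicutes", "Clostridia", "Eubacteriales", "Oscillospiraceae"),
    "Clostridium": ("Firmicutes", "Clostridia", "Eubacteriales", "Clostridiaceae"),
    "Ruminococcus": ("Firmicutes", "Clostridia", "Eubacteriales", "Oscillospiraceae"),
    "Bifidobacterium": (
        "Actinobacteria", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae",
    ),
    "Fusobacterium": (
        "Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae",
    ),
    "Methanobrevibacter": (
        "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae",
    ),
}

_ARCHAEAL_GENERA = {"Methanobrevibacter"}


@dataclass
class TaxonomyProfile:
    """Sampling profile for synthetic lineages.

    ``genus_probs`` must sum to 1.  ``truncation`` maps a rank to the
    probability that a lineage stops just above it (everything from that rank
    down is missing); a scalar applies to every rank below superkingdom.
    """

    genus_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "Bacteroides": 0.35,
            "Faecalibacterium": 0.15,
            "Clostridium": 0.13,
            "Ruminococcus": 0.12,
            "Bifidobacterium": 0.10,
            "Fusobacterium": 0.08,
            "Methanobrevibacter": 0.07,
        }
    )
    truncation: Mapping[str, float] | float = 0.1
    species_per_genus: int = 3
    tree: Mapping[str, tuple[str, str, str, str]] = field(
        default_factory=lambda: dict(_DEFAULT_TREE)
    )

    def __post_init__(self):
        total = sum(self.genus_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genus probabilities must sum to 1, got {total}")
        unknown = set(self.genus_probs) - set(self.tree)
        if unknown:
            raise ValueError(f"genera missing from tree: {sorted(unknown)}")
        if isinstance(self.truncation, Mapping):
            bad = set(self.truncation) - set(RANKS[1:])
            if bad:
                raise ValueError(f"unknown truncation ranks: {sorted(bad)}")

    def truncation_prob(self, rank: str) -> float:
        if isinstance(self.truncation, Mapping):
            return float(self.truncation.get(rank, 0.0))
        return float(self.truncation)


def _function_pool(rng: np.random.Generator, size: int = 40) -> list[str]:
    codes = [f"K{rng.integers(0, 100000):05d}" for _ in range(size - size // 5)]
    codes += [f"CKO-h{rng.integers(0, 1000)}" for _ in range(size // 5)]
    return codes


def generate_annotations(
    feature_ids: Sequence[str],
    profile: TaxonomyProfile | None = None,
    seed: int = 0,
    human_fraction: float = 0.2,
    function_prob: float = 0.7,
    human_function_prob: float = 1.0,
    origins: Mapping[str, str] | None = None,
) -> AnnotationTable:
    """Sample an annotation table for *feature_ids*.

    Microbial features get a lineage drawn down the profile's rank tree with
    per-rank truncation, and a function code with probability
    ``function_prob``; human features carry no lineage and get a function code
    with probability ``human_function_prob``.  Explicit per-feature *origins*
    override ``human_fraction``.
    """
    profile = profile or TaxonomyProfile()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[_STREAM_ANNOTATION])
    genera = list(profile.genus_probs)
    probs = np.array([profile.genus_probs[g] for g in genera])
    pool = _function_pool(rng)

    rows = []
    for fid in feature_ids:
        if origins is not None:
            origin = origins[fid]
        else:
            origin = "human" if rng.random() < human_fraction else "microbial"
        lineage = {r: None for r in RANKS}
        code = None
        if origin == "microbial":
            genus = genera[rng.choice(len(genera), p=probs)]
            phylum, klass, order, family = profile.tree[genus]
            superkingdom = "Archaea" if genus in _ARCHAEAL_GENERA else "Bacteria"
            species = f"{genus} sp{1 + rng.integers(profile.species_per_genus)}"
            full = dict(
                zip(RANKS, (superkingdom, phylum, klass, order, family, genus, species))
            )
            lineage.update(full)
            for rank in RANKS[1:]:
                if rng.random() < profile.truncation_prob(rank):
                    cut = RANKS.index(rank)
                    for r in RANKS[cut:]:
                        lineage[r] = None
                    break
            if rng.random() < function_prob:
                code = pool[rng.integers(len(pool))]
        else:
            if rng.random() < human_function_prob:
                code = pool[rng.integers(len(pool))]
        rows.append({"feature_id": fid, "origin": origin, **lineage,
                     "function_code": code})
    return AnnotationTable(pd.DataFrame(rows))
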