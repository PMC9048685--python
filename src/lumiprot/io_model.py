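"""Core data types, file I/O, clinical grouping, and annotation-based aggregation.

The quantitative backbone of the pipeline is a samples x peptide-features
intensity matrix with nonnegative entries; a zero means the peptide was not
detected in that sample.  Peptides carry an origin class (microbial or human),
an optionally truncated taxonomic lineage, and an optional function code.
Clinical covariates follow a fixed seven-column schema (sample code, gender,
age, tumor site, stage, grade, TILs percentage).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: NCBI-style rank ladder, top to bottom.  Intermediate clades are unsupported.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

STAGES = ("I", "II", "III", "IV")
GRADES = ("G1", "G2", "G3")
SITES = ("right colon", "left colon")
GENDERS = ("M", "F")

CLINICAL_COLUMNS = ("sample_id", "gender", "age", "site", "stage", "grade", "tils")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# IntensityMatrix
# ---------------------------------------------------------------------------


class IntensityMatrix:
    """Samples x features matrix of nonnegative peptide intensities.

    Parameters
    ----------
    data
        DataFrame with sample ids as the index and feature ids as columns.
        Values must be nonnegative and finite; zeros are structural
        ("not detected"), not missing.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite intensity values")
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative intensity at sample {data.index[bad[0]]!r}, "
                f"feature {data.columns[bad[1]]!r}"
            )
        self.data = data.astype(float)

    # -- basic protocol ----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityMatrix):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover
        n, p = self.shape
        return f"IntensityMatrix({n} samples x {p} features)"

    # -- convenience -------------------------------------------------------

    def subset_features(self, feature_ids: list[str]) -> "IntensityMatrix":
        missing = set(feature_ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown feature ids: {sorted(missing)}")
        return IntensityMatrix(self.data.loc[:, list(feature_ids)])

    def total_sum_scale(self, target: float = 1.0) -> "IntensityMatrix":
        """Optional per-sample total-sum normalization (off by default upstream)."""
        sums = self.data.sum(axis=1).replace(0.0, np.nan)
        scaled = self.data.div(sums, axis=0).fillna(0.0) * target
        return IntensityMatrix(scaled)


# ---------------------------------------------------------------------------
# AnnotationTable
# ---------------------------------------------------------------------------


class AnnotationTable:
    """Per-peptide origin, taxonomic lineage and function-code annotations.

    Lineages must be contiguous prefixes of the seven-rank ladder: once a rank
    is missing, every rank below it must also be missing.  Human peptides
    carry no lineage; microbial peptides may lack a function code.
    """

    def __init__(self, data: pd.DataFrame):
        required = ["feature_id", "origin", *RANKS, "function_code"]
        missing_cols = [c for c in required if c not in data.columns]
        if missing_cols:
            raise ValidationError(f"annotation table missing columns: {missing_cols}")
        data = data.loc[:, required].copy()
        if data["feature_id"].duplicated().any():
            dups = data.loc[data["feature_id"].duplicated(), "feature_id"].tolist()
            raise ValidationError(f"duplicate feature ids in annotations: {dups}")
        bad_origin = set(data["origin"].unique()) - {"microbial", "human"}
        if bad_origin:
            raise ValidationError(f"unknown origin values: {sorted(bad_origin)}")
        lineage = data[list(RANKS)]
        present = lineage.notna() & (lineage != "")
        # prefix property: a named rank below a missing one is forbidden
        holes = (~present).to_numpy()
        filled_below_hole = np.logical_and(
            np.maximum.accumulate(holes, axis=1), ~holes
        )
        if filled_below_hole.any():
            row = int(np.argwhere(filled_below_hole.any(axis=1))[0][0])
            raise ValidationError(
                f"non-contiguous lineage for feature "
                f"{data['feature_id'].iloc[row]!r}"
            )
        human_with_lineage = (data["origin"] == "human") & present.any(axis=1)
        if human_with_lineage.any():
            fid = data.loc[human_with_lineage, "feature_id"].iloc[0]
            raise ValidationError(f"human feature {fid!r} carries a lineage")
        fc = data["function_code"].dropna()
        fc = fc[fc != ""]
        ok = fc.str.match(r"^K\d{5}$") | fc.str.startswith("CKO-")
        if not ok.all():
            raise ValidationError(
                f"malformed function codes: {fc[~ok].unique().tolist()}"
            )
        self.data = data.set_index("feature_id", drop=False)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data["feature_id"])

    def categories(self, level: str, features: list[str] | None = None) -> pd.Series:
        """Category label per feature at *level* (a rank or ``"function"``).

        Unannotated features at that level get NaN.
        """
        if level == "function":
            col = self.data["function_code"]
        elif level in RANKS:
            col = self.data[level]
        else:
            raise ValueError(f"unknown level {level!r}; use one of {RANKS} or 'function'")
        col = col.replace("", np.nan)
        if features is not None:
            col = col.reindex(features)
        return col

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# ClinicalTable
# ---------------------------------------------------------------------------


class ClinicalTable:
    """Per-patient covariates; rejects incomplete rows outright."""

    def __init__(self, data: pd.DataFrame):
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in data.columns]
        if missing_cols:
            raise ValidationError(f"clinical table missing columns: {missing_cols}")
        data = data.loc[:, list(CLINICAL_COLUMNS)].copy()
        if data.isna().any().any():
            bad = data.loc[data.isna().any(axis=1), "sample_id"].tolist()
            raise ValidationError(f"incomplete clinical rows for samples: {bad}")
        if data["sample_id"].duplicated().any():
            dups = data.loc[data["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        for col, allowed in (
            ("gender", GENDERS),
            ("site", SITES),
            ("stage", STAGES),
            ("grade", GRADES),
        ):
            bad = set(data[col].unique()) - set(allowed)
            if bad:
                raise ValidationError(f"invalid {col} values: {sorted(bad)}")
        data["age"] = data["age"].astype(int)
        data["tils"] = data["tils"].astype(float)
        if ((data["tils"] < 0) | (data["tils"] > 100)).any():
            raise ValidationError("tils must lie in [0, 100]")
        self.data = data.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def __len__(self) -> int:
        return len(self.data)

    def aligned_to(self, sample_ids: list[str]) -> "ClinicalTable":
        missing = set(sample_ids) - set(self.data.index)
        if missing:
            raise ValidationError(f"clinical rows missing for samples: {sorted(missing)}")
        return ClinicalTable(self.data.loc[list(sample_ids)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# ComparisonSpec and grouping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonSpec:
    """A two-group dichotomization of one clinical variable.

    Built-in rules:

    - ``stage``: stages I and II form group A ("Stage I-II"), III and IV
      group B ("Stage III-IV").
    - ``grade``: G1 and G2 form group A ("G1-2"), G3 group B ("G3").
    - ``tils``: TILs >= 5% form group A ("TILs +"), exactly 0% group B
      ("TILs -"); intermediate values in (0, 5) are rejected rather than
      silently binned.
    """

    variable: Literal["stage", "grade", "tils"]
    group_a_label: str = field(default="", compare=False)
    group_b_label: str = field(default="", compare=False)

    _LABELS = {
        "stage": ("Stage I-II", "Stage III-IV"),
        "grade": ("G1-2", "G3"),
        "tils": ("TILs +", "TILs -"),
    }

    def __post_init__(self):
        if self.variable not in self._LABELS:
            raise ValueError(f"unsupported comparison variable {self.variable!r}")
        a, b = self._LABELS[self.variable]
        if not self.group_a_label:
            object.__setattr__(self, "group_a_label", a)
        if not self.group_b_label:
            object.__setattr__(self, "group_b_label", b)

    def classify(self, row: pd.Series) -> str:
        if self.variable == "stage":
            return "A" if row["stage"] in ("I", "II") else "B"
        if self.variable == "grade":
            return "A" if row["grade"] in ("G1", "G2") else "B"
        tils = float(row["tils"])
        if tils >= 5:
            return "A"
        if tils == 0:
            return "B"
        raise ValidationError(
            f"TILs value {tils} for sample {row['sample_id']!r} is in (0, 5): "
            "undefined under the >=5% vs 0% dichotomy"
        )


def assign_groups(
    clinical: ClinicalTable, spec: ComparisonSpec
) -> tuple[dict[str, str], dict[str, int]]:
    """Map each sample to group "A" or "B" under *spec*.

    Returns
    -------
    groups
        sample_id -> "A" | "B".
    sizes
        {"A": n_A, "B": n_B}; always n_A + n_B == len(clinical).
    """
    groups = {
        sid: spec.classify(row) for sid, row in clinical.data.iterrows()
    }
    sizes = {
        "A": sum(1 for g in groups.values() if g == "A"),
        "B": sum(1 for g in groups.values() if g == "B"),
    }
    return groups, sizes


# ---------------------------------------------------------------------------
# AggregatedMatrix and operations
# ---------------------------------------------------------------------------


@dataclass
class AggregatedMatrix:
    """Per-category summed intensities at one taxonomic rank or at function level."""

    level: str
    data: pd.DataFrame  # samples x categories

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def category_ids(self) -> list[str]:
        return list(self.data.columns)


UNASSIGNED = "unassigned"


def aggregate_by_annotation(
    m: IntensityMatrix, ann: AnnotationTable, level: str
) -> AggregatedMatrix:
    """Sum peptide intensities per annotation category at *level*.

    A category's abundance in a sample is the sum of the intensities of all
    peptides annotated with that category.  Peptides lacking an annotation at
    *level* are pooled into an explicit ``"unassigned"`` bucket so that per-
    sample totals are conserved.
    """
    cats = ann.categories(level, features=m.feature_ids)
    labels = cats.fillna(UNASSIGNED).to_numpy()
    grouped = m.data.T.groupby(labels).sum().T
    grouped.index.name = m.data.index.name
    return AggregatedMatrix(level=level, data=grouped)


def log_transform(m: IntensityMatrix, pseudocount: float = 1.0) -> IntensityMatrix:
    """Elementwise ``log2(value + pseudocount)``; order-preserving per feature."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    return IntensityMatrix(np.log2(m.data + pseudocount))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


@dataclass
class LoadReport:
    n_missing_cells: int = 0


def load_intensity_table(
    path, orientation: Literal["samples-rows", "features-rows"] = "samples-rows"
) -> tuple[IntensityMatrix, LoadReport]:
    """Read a TSV intensity table.

    First column holds sample ids (default) or feature ids
    (``orientation="features-rows"``, i.e. the transposed layout).  Missing
    cells are treated as 0 and counted in the load report; negative or
    non-numeric cells are hard errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup_cols = pd.Index(header)[pd.Index(header).duplicated()].unique().tolist()
    if dup_cols:
        raise ValidationError(f"duplicate ids in header: {dup_cols}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise ValidationError(
                    f"non-numeric cell at row {df.index[bad.argmax()]!r}, "
                    f"column {col!r}"
                )
            df[col] = coerced
    n_missing = int(df.isna().sum().sum())
    df = df.fillna(0.0)
    if orientation == "features-rows":
        df = df.T
    report = LoadReport(n_missing_cells=n_missing)
    return IntensityMatrix(df), report


def save_intensity_table(m: IntensityMatrix, path) -> None:
    df = m.data.copy()
    df.index.name = df.index.name or "sample_id"
    df.to_csv(path, sep="\t")


def load_annotation_table(path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AnnotationTable(df)


def save_annotation_table(ann: AnnotationTable, path) -> None:
    ann.data.to_csv(path, sep="\t", index=False)


def load_clinical_table(path) -> ClinicalTable:
    df = pd.read_csv(path)
    return ClinicalTable(df)


def save_clinical_table(clinical: ClinicalTable, path) -> None:
    clinical.data.to_csv(path, index=False)
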