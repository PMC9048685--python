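"""Bundled reference datasets.

The pilot cohort is the published clinical table of the 24 colon-cancer
patients whose colonic-luminal metaproteomes motivated this pipeline; it is
shipped in-package so grouping and summary operations can be exercised
without external files.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .io_model import ClinicalTable

_PILOT_COHORT_CSV = """\
sample_id,gender,age,site,stage,grade,tils
S061,F,75,right colon,II,G2,0
S085,M,75,right colon,III,G2,20
S097,F,64,right colon,II,G3,0
S099,F,77,right colon,III,G2,0
S103,F,62,left colon,III,G2,0
S107,F,88,right colon,II,G2,0
S109,F,65,left colon,III,G2,0
S111,M,77,right colon,I,G2,0
S119,M,76,right colon,I,G2,5
S121,M,79,right colon,II,G2,20
S125,M,75,right colon,I,G3,10
S131,M,72,right colon,I,G1,0
S135,F,87,right colon,II,G3,50
S141,M,51,left colon,I,G1,0
S143,M,70,left colon,IV,G2,5
S145,F,80,left colon,III,G3,0
S147,F,79,right colon,III,G3,60
S151,M,75,left colon,III,G2,5
S157,M,77,right colon,II,G3,0
S161,M,66,left colon,III,G2,10
S165,F,33,left colon,IV,G3,5
S175,M,66,left colon,III,G2,10
S181,M,74,right colon,III,G2,0
S183,M,83,right colon,I,G2,50
"""


def pilot_cohort() -> ClinicalTable:
    """The 24-patient colon-cancer clinical table bundled with the package."""
    df = pd.read_csv(io.StringIO(_PILOT_COHORT_CSV))
    return ClinicalTable(df)


def cohort_summary(clinical: ClinicalTable) -> dict:
    """Descriptive statistics used in cohort reporting.

    Percentages are rounded to the nearest integer; medians follow the
    standard midpoint convention for even counts.
    """
    df = clinical.data
    n = len(df)

    def pct(count: int) -> int:
        # half-up rounding: 62.5% reports as 63%
        return int(np.floor(100 * count / n + 0.5))

    stage_counts = df["stage"].value_counts().to_dict()
    grade_counts = df["grade"].value_counts().to_dict()
    tils_pos = df.loc[df["tils"] > 0, "tils"]
    return {
        "n": n,
        "n_male": int((df["gender"] == "M").sum()),
        "n_female": int((df["gender"] == "F").sum()),
        "median_age": float(df["age"].median()),
        "age_range": (int(df["age"].min()), int(df["age"].max())),
        "n_right_colon": int((df["site"] == "right colon").sum()),
        "n_left_colon": int((df["site"] == "left colon").sum()),
        "stage_counts": stage_counts,
        "stage_percent": {s: pct(c) for s, c in stage_counts.items()},
        "grade_counts": grade_counts,
        "grade_percent": {g: pct(c) for g, c in grade_counts.items()},
        "n_tils_zero": int((df["tils"] == 0).sum()),
        "n_tils_positive": int((df["tils"] > 0).sum()),
        "median_tils_positive": float(tils_pos.median()) if len(tils_pos) else None,
    }
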