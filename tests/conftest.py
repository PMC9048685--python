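import numpy as np
import pandas as pd
import pytest

from lumiprot import datasets
from lumiprot.io_model import AnnotationTable, IntensityMatrix
from lumiprot.synthetic_data import (
    EffectSpec,
    default_reference,
    generate_annotations,
    generate_cohort,
)


@pytest.fixture(scope="session")
def pilot_clinical():
    return datasets.pilot_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 30-sample / 200-feature cohort with 5 planted log2FC=2 effects."""
    ref = default_reference(200, seed=1, pi_range=(0.9, 1.0), sigma_range=(0.5, 1.0))
    planted = ref.feature_ids[:5]
    effects = EffectSpec({f: 2.0 for f in planted}, up_group="A")
    matrix, clinical, truth = generate_cohort(ref, (15, 15), effects, seed=3)
    return {
        "ref": ref,
        "matrix": matrix,
        "clinical": clinical,
        "truth": truth,
        "planted": planted,
    }


@pytest.fixture(scope="session")
def small_annotations(small_cohort):
    return generate_annotations(small_cohort["matrix"].feature_ids, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_matrix():
    return IntensityMatrix(
        pd.DataFrame(
            [[2.0, 1.0, 1.0, 0.0], [0.0, 0.0, 0.0, 0.0], [4.0, 4.0, 4.0, 4.0]],
            index=["s1", "s2", "s3"],
            columns=["p1", "p2", "p3", "p4"],
        )
    )


def make_annotations(rows):
    """Helper: build an AnnotationTable from (feature_id, origin, lineage, code)."""
    from lumiprot.io_model import RANKS

    records = []
    for fid, origin, lineage, code in rows:
        rec = {"feature_id": fid, "origin": origin, "function_code": code}
        for i, rank in enumerate(RANKS):
            rec[rank] = lineage[i] if lineage and i < len(lineage) else None
        records.append(rec)
    return AnnotationTable(pd.DataFrame(records))
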