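import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lumiprot.enrichment import (
    category_enrichment,
    default_covariates,
    direction_of_enrichment,
    empirical_enrichment,
    residualize,
    run_enrichment_analysis,
)
from lumiprot.io_model import ComparisonSpec, IntensityMatrix, log_transform

from conftest import make_annotations


def _genus_annotations(assignments):
    """feature -> genus (None = unannotated microbial)."""
    rows = []
    for fid, genus in assignments.items():
        lineage = (
            ["Bacteria", "Ph", "Cl", "Or", "Fa", genus] if genus else ["Bacteria"]
        )
        rows.append((fid, "microbial", lineage, None))
    return make_annotations(rows)


class TestCategoryEnrichment:
    def test_hand_computed_hypergeometric_tail(self):
        # background 20, category 4, selected 10, all 4 members selected:
        # p = C(4,4) C(16,6) / C(20,10)
        background = [f"p{i}" for i in range(20)]
        ann = _genus_annotations(
            {f: ("CatA" if i < 4 else "CatB") for i, f in enumerate(background)}
        )
        selected = background[:4] + background[4:10]
        res = category_enrichment(selected, ann, background, levels=("genus",))
        row = res[res["category"] == "CatA"].iloc[0]
        expected = math.comb(4, 4) * math.comb(16, 6) / math.comb(20, 10)
        assert row["observed"] == 4
        assert row["fisher_p"] == pytest.approx(expected)

    def test_identical_proportions_p_near_one(self):
        background = [f"p{i}" for i in range(40)]
        ann = _genus_annotations(
            {f: ("CatA" if i % 2 == 0 else "CatB") for i, f in enumerate(background)}
        )
        selected = background[:20]  # 10 CatA, 10 CatB: same 50% proportion
        res = category_enrichment(selected, ann, background, levels=("genus",))
        assert (res["fisher_p"] > 0.5).all()

    def test_disjoint_category_p_one(self):
        background = [f"p{i}" for i in range(10)]
        ann = _genus_annotations(
            {f: ("CatA" if i < 5 else "CatB") for i, f in enumerate(background)}
        )
        res = category_enrichment(background[5:], ann, background, levels=("genus",))
        row = res[res["category"] == "CatA"].iloc[0]
        assert row["observed"] == 0
        assert row["fisher_p"] == pytest.approx(1.0)

    def test_empty_selected_rejected(self):
        ann = _genus_annotations({"p0": "CatA"})
        with pytest.raises(ValueError, match="empty"):
            category_enrichment([], ann, ["p0"])

    def test_selected_outside_background_rejected(self):
        ann = _genus_annotations({"p0": "CatA"})
        with pytest.raises(ValueError, match="outside background"):
            category_enrichment(["p1"], ann, ["p0"])

    def test_low_support_flag(self):
        background = [f"p{i}" for i in range(10)]
        ann = _genus_annotations(
            {f: ("CatA" if i < 1 else "CatB") for i, f in enumerate(background)}
        )
        res = category_enrichment(background[:2], ann, background, levels=("genus",))
        assert res.set_index("category")["low_support"]["CatA"]


class TestEmpiricalEnrichment:
    def test_single_category_covering_all_p_one(self):
        background = [f"p{i}" for i in range(10)]
        ann = _genus_annotations({f: "Only" for f in background})
        res = empirical_enrichment(background[:4], ann, background, 200, seed=0,
                                   levels=("genus",))
        assert res["empirical_p"].iloc[0] == pytest.approx(1.0)

    def test_converges_to_hypergeometric(self):
        # 50-peptide toy: empirical p within 3 Monte-Carlo SE of the exact tail
        background = [f"p{i}" for i in range(50)]
        ann = _genus_annotations(
            {f: ("CatA" if i < 10 else "CatB") for i, f in enumerate(background)}
        )
        selected = background[:6] + background[10:20]  # 6/10 CatA among 16
        res = empirical_enrichment(selected, ann, background, 10000, seed=3,
                                   levels=("genus",))
        row = res[res["category"] == "CatA"].iloc[0]
        exact = float(stats.hypergeom.sf(5, 50, 10, 16))
        se = math.sqrt(exact * (1 - exact) / 10000)
        assert abs(row["empirical_p"] - exact) <= 3 * se + 2 / 10001

    def test_empirical_p_within_bounds(self):
        background = [f"p{i}" for i in range(30)]
        ann = _genus_annotations(
            {f: ("CatA" if i < 15 else "CatB") for i, f in enumerate(background)}
        )
        B = 500
        res = empirical_enrichment(background[:10], ann, background, B, seed=1,
                                   levels=("genus",))
        assert (res["empirical_p"] >= 1 / (B + 1)).all()
        assert (res["empirical_p"] <= 1.0).all()

    def test_deterministic_given_seed(self):
        background = [f"p{i}" for i in range(30)]
        ann = _genus_annotations(
            {f: ("CatA" if i < 12 else "CatB") for i, f in enumerate(background)}
        )
        r1 = empirical_enrichment(background[:8], ann, background, 300, seed=5)
        r2 = empirical_enrichment(background[:8], ann, background, 300, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_monotone_in_enrichment_strength(self):
        # same background/categories; stronger overlap -> smaller empirical p
        background = [f"p{i}" for i in range(40)]
        ann = _genus_annotations(
            {f: ("CatA" if i < 10 else "CatB") for i, f in enumerate(background)}
        )
        ps = []
        for n_in_cat in (2, 5, 8):
            selected = background[:n_in_cat] + background[10 : 10 + (10 - n_in_cat)]
            res = empirical_enrichment(selected, ann, background, 2000, seed=7,
                                       levels=("genus",))
            ps.append(res.set_index("category")["empirical_p"]["CatA"])
        assert ps[0] >= ps[1] >= ps[2]

    def test_null_calibration_band(self):
        # random selections: <= 7.5% of categories significant at 0.05
        rng = np.random.default_rng(13)
        background = [f"p{i}" for i in range(60)]
        genera = [f"G{k}" for k in range(6)]
        ann = _genus_annotations(
            {f: genera[i % 6] for i, f in enumerate(background)}
        )
        flags = []
        for rep in range(25):
            selected = list(rng.choice(background, size=15, replace=False))
            res = empirical_enrichment(selected, ann, background, 400,
                                       seed=100 + rep, levels=("genus",))
            flags.extend((res["empirical_p"] < 0.05).tolist())
        assert np.mean(flags) <= 0.075

    def test_invalid_permutation_count(self):
        ann = _genus_annotations({"p0": "CatA"})
        with pytest.raises(ValueError):
            empirical_enrichment(["p0"], ann, ["p0"], 0)


class TestDirection:
    def test_higher_group_labelled(self):
        background = ["p0", "p1"]
        ann = _genus_annotations({"p0": "CatA", "p1": "CatA"})
        m = IntensityMatrix(
            pd.DataFrame(
                [[10.0, 10.0], [1.0, 1.0]], index=["s1", "s2"], columns=background
            )
        )
        res = category_enrichment(background, ann, background, levels=("genus",))
        out = direction_of_enrichment(
            res, background, ann, m, {"s1": "A", "s2": "B"},
            {"A": "High", "B": "Low"},
        )
        assert (out["higher_in"] == "High").all()


class TestResidualize:
    def test_no_covariates_is_identity(self, small_cohort):
        logm = log_transform(small_cohort["matrix"])
        out = residualize(logm, small_cohort["clinical"], [])
        pd.testing.assert_frame_equal(out, logm.data)

    def test_residuals_orthogonal_to_design(self, small_cohort):
        logm = log_transform(small_cohort["matrix"])
        out = residualize(logm, small_cohort["clinical"], ["age", "gender"])
        clin = small_cohort["clinical"].aligned_to(logm.sample_ids).data
        age = clin["age"].to_numpy(dtype=float)
        assert abs(out.to_numpy().T @ (age - age.mean())).max() < 1e-6

    def test_confounded_effect_removed(self, rng):
        # feature driven entirely by age: residualization flattens group gap
        n = 40
        age = np.concatenate([rng.integers(70, 90, 20), rng.integers(40, 60, 20)])
        values = np.exp(0.1 * age)[:, None] * np.ones((n, 3))
        values += rng.normal(0, 0.01, size=values.shape)
        from lumiprot.io_model import ClinicalTable

        clinical = ClinicalTable(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(n)],
                    "gender": ["M"] * n,
                    "age": age,
                    "site": ["right colon"] * n,
                    "stage": ["I"] * 20 + ["IV"] * 20,
                    "grade": ["G2"] * n,
                    "tils": [0.0] * n,
                }
            )
        )
        m = IntensityMatrix(
            pd.DataFrame(np.abs(values), index=[f"s{i}" for i in range(n)],
                         columns=["p0", "p1", "p2"])
        )
        logm = log_transform(m)
        raw_gap = abs(
            logm.data.iloc[:20, 0].mean() - logm.data.iloc[20:, 0].mean()
        )
        resid = residualize(logm, clinical, ["age"])
        resid_gap = abs(resid.iloc[:20, 0].mean() - resid.iloc[20:, 0].mean())
        assert resid_gap < 0.05 * raw_gap

    def test_collinear_design_warns(self, small_cohort):
        logm = log_transform(small_cohort["matrix"])
        clin = small_cohort["clinical"].data.copy()
        clin["tils"] = clin["age"] * 1.0  # force exact collinearity
        clin.loc[:, "tils"] = np.clip(clin["tils"], 0, 100)
        from lumiprot.io_model import ClinicalTable

        clinical = ClinicalTable(clin.reset_index(drop=True))
        with pytest.warns(UserWarning, match="collinear"):
            residualize(logm, clinical, ["age", "tils"])


class TestDefaultCovariates:
    @pytest.mark.parametrize("variable", ["stage", "grade", "tils"])
    def test_excludes_comparison_variable(self, variable):
        covs = default_covariates(ComparisonSpec(variable))
        assert variable not in covs
        assert len(covs) == 5


class TestRunEnrichmentAnalysis:
    def test_full_pipeline_on_planted_cohort(self, small_cohort, small_annotations):
        m = small_cohort["matrix"]
        truth = small_cohort["truth"]
        # overwrite clinical grouping so the comparison matches planted truth
        clin = small_cohort["clinical"].data.copy().reset_index(drop=True)
        clin["stage"] = np.where(truth["group"] == "A", "IV", "I")
        from lumiprot.io_model import ClinicalTable

        clinical = ClinicalTable(clin)
        analysis = run_enrichment_analysis(
            m, clinical, small_annotations, ComparisonSpec("stage"),
            n_resamples=40, n_permutations=300, seed=0, keepX=10, ncomp=1,
        )
        table = analysis.table
        assert {"empirical_p_main", "empirical_p_sensitivity", "significant",
                "higher_in"} <= set(table.columns)
        assert set(analysis.selection_main.selected) >= set(
            small_cohort["planted"]
        ) or len(analysis.selection_main.selected) > 0

    def test_comparison_variable_in_covariates_rejected(
        self, small_cohort, small_annotations
    ):
        with pytest.raises(ValueError, match="exclude"):
            run_enrichment_analysis(
                small_cohort["matrix"], small_cohort["clinical"],
                small_annotations, ComparisonSpec("stage"),
                covariates=("stage", "age"),
            )

    def test_noise_covariates_leave_pvalues_similar(
        self, small_cohort, small_annotations
    ):
        # covariates independent of the data: sensitivity p close to main p
        m = small_cohort["matrix"]
        truth = small_cohort["truth"]
        clin = small_cohort["clinical"].data.copy().reset_index(drop=True)
        clin["stage"] = np.where(truth["group"] == "A", "IV", "I")
        rng = np.random.default_rng(21)
        clin["age"] = rng.integers(40, 90, len(clin))
        from lumiprot.io_model import ClinicalTable

        clinical = ClinicalTable(clin)
        analysis = run_enrichment_analysis(
            m, clinical, small_annotations, ComparisonSpec("stage"),
            covariates=("age",), n_resamples=40, n_permutations=400, seed=2,
            keepX=10, ncomp=1,
        )
        t = analysis.table.dropna(subset=["empirical_p_sensitivity"])
        strong = t[t["empirical_p_main"] < 0.05]
        if len(strong):
            assert (strong["empirical_p_sensitivity"] < 0.25).mean() >= 0.5
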