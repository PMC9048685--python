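# lumiprot

Statistical analysis pipeline for colonic-luminal metaproteome peptide-intensity
data: alpha diversity, explained-variance decomposition of clinical covariates
(PCA eigenvector regressions weighted by eigenvalues), stability-selected
sparse PLS discriminant analysis, permutation-based taxonomic/functional
enrichment with a covariate-residualized sensitivity analysis, regularized
canonical correlation between microbial and host peptide blocks, and empirical
power / sample-size simulation — all exercisable end-to-end on seeded
synthetic cohorts with known injected effects.

## Test

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` (worked cohort-table targets plus property-based
criteria at stated tolerances; ~30 s of the ~1 min total).

## Data model

- **Intensity matrix** — TSV, samples as rows, peptide features as columns,
  nonnegative reals; `0` means "not detected". Use `--transpose` for the
  features-as-rows layout.
- **Annotation table** — TSV with columns `feature_id`, `origin`
  (`microbial`/`human`), `superkingdom` … `species` (lineage may be truncated,
  but only from the bottom), `function_code` (`K#####` or `CKO-…`, optional).
- **Clinical table** — CSV with `sample_id`, `gender` (M/F), `age`, `site`
  (right/left colon), `stage` (I–IV), `grade` (G1–G3), `tils` (0–100 %).
  Incomplete rows are rejected.

A 24-patient colon-cancer clinical table is bundled
(`lumiprot.datasets.pilot_cohort()`).

## CLI

```bash
lumiprot simulate --n-per-group 20 20 --n-features 500 --seed 1 --out-prefix syn
lumiprot validate --matrix syn_matrix.tsv --clinical syn_clinical.csv
lumiprot aggregate --matrix syn_matrix.tsv --annotations syn_annotations.tsv --level genus --out genus.tsv
lumiprot diversity --matrix syn_matrix.tsv --clinical syn_clinical.csv --by stage
lumiprot pcpr2 --matrix syn_matrix.tsv --clinical syn_clinical.csv --variables stage,grade,tils,age,gender,site
lumiprot discriminate --matrix syn_matrix.tsv --clinical syn_clinical.csv --compare tils --resamples 1000 --seed 1
lumiprot enrich --matrix syn_matrix.tsv --clinical syn_clinical.csv --annotations syn_annotations.tsv --compare stage --permutations 10000 --seed 1 --out enrich.tsv
lumiprot correlate --block-a microbial.tsv --block-b host.tsv --annotations syn_annotations.tsv
lumiprot power --n-features 2000 --n-grid 15:200:20 --subsamples 200 --seed 1 --out power.tsv
```

Clinical dichotomies: stage I–II vs III–IV; grade G1–2 vs G3; TILs ≥ 5 % vs
exactly 0 % (values in (0, 5) are rejected as undefined).

## Conventions worth knowing

- Log transform is `log2(x + 1)` by default (pseudocount configurable); no
  cross-sample normalization is applied unless requested
  (`IntensityMatrix.total_sum_scale`).
- Shannon diversity is returned as the standard nonnegative `−Σ p·ln p` in
  nats, with zero-abundance features contributing 0.
- Stability selection: hyperparameters (ncomp, keepX) tuned once by
  cross-validated balanced error (ties → smallest keepX, then ncomp), then
  1,000 stratified 80/20 refits; features kept when selected in ≥ 50 % of
  resamples.
- Empirical enrichment p-values use size-preserving category-label
  permutations with the +1 correction: `(1 + #{perm ≥ obs}) / (B + 1)`.
- Power analysis: two-sided rank-sum per feature on log intensities (t-test
  mode available), Benjamini–Hochberg at α = 0.05, power = mean per-feature
  rejection rate within each log2FC tier.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` substreams; matched seeds give bitwise-identical
  outputs.

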