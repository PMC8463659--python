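# csfmir

Analysis pipeline for censored qPCR miRNA array data across three
participant groups (community controls, deployed controls, deployed with
mild TBI):

- **QC flagging** of per-reaction amplifications (`good` / `censored` /
  `excluded` from Cq, amplification score, Cq confidence).
- **Endogenous-control (EC) normalization**: per-sample candidate
  screening, stability ranking (mean pairwise SD of Cq differences with
  iterative removal) with a pairwise-variation stopping rule, then
  ΔCq = Cq − geometric mean of the EC Cq values, carrying detection
  censoring through as a per-sample ΔCq threshold.
- **Differential expression** of censored ΔCq by the two-group log-rank
  test, 2^−ΔΔCq fold changes with combined-SD intervals, BH FDR.
- **Differential detection** by Fisher's exact test with
  conditional-MLE odds ratios and exact intervals.
- **Covariate regressions** of expression on biological variables per
  group, and between-run correlation summaries.
- **Multivariable dependency search**: near-equal-count binning
  (μ ± f·s grid search), plug-in mutual information, interaction
  information and symmetric delta, a 43-list search (3 pairwise + 39
  primary×secondary three-way + 1 miRNA×deployment×tbi), within-list
  z-scoring with top-20 selection beyond 1 SD, composite scores
  (weights 1, ½, ⅓) and a stringent distribution-based filter.
- **Synthetic data generator**: seeded qPCR amplification records and
  phenotype tables with mechanistic censoring, card-level sample
  offsets, stable planted ECs, and plantable level / detection /
  synergy effects with a ground-truth manifest.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including a
10⁴-replicate null calibration of the censored log-rank test and an
exhaustive Fisher-exact enumeration check; the full suite takes a few
minutes. The study-reproduction tests require the participant-level
supplementary data (set `CSFMIR_SUPPLEMENTARY_DIR`) and are skipped
otherwise.

## CLI

```bash
# generate a synthetic dataset
csfmir --seed 1 --out-dir data simulate

# run everything end-to-end
csfmir --config run.yaml all

# or stage by stage (each stage reads the previous stage's CSVs)
csfmir --config run.yaml qc
csfmir --config run.yaml normalize
csfmir --config run.yaml de
csfmir --config run.yaml detect
csfmir --config run.yaml assoc
csfmir --config run.yaml deps
csfmir --config run.yaml composite
csfmir --config run.yaml filter
```

A minimal `run.yaml`:

```yaml
amplifications: data/amplifications.csv
phenotypes: data/phenotypes.csv
out_dir: results
```

All thresholds (Cq ceiling 34, amp-score floor 1.0, EC criteria,
pairwise-variation threshold 0.1527, 20%/10% miRNA filters, α = 0.025,
binning grid, stringent-filter cutoff) are configurable; see
`csfmir.pipeline.RunConfig`.

Input formats: long CSV/TSV with one row per reaction
(`sample_id, mirna_id, cq, amp_score, cq_conf`; `Undetermined`/`NA`/empty
mean no Cq call), or a wide samples × probes Cq matrix; a per-sample
phenotype CSV with a `group` column (`ComC`/`DepC`/`DepTBI`) plus
covariates (age, bmi, mmse, abeta42, ttau, ptau181, apoe, smoke, race,
n_tbi, years_since_tbi — tau/abeta ratios are derived).

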