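# repdx

TCR-β repertoire analytics over AIRR-style clonotype tables: per-sample
diversity, cross-tissue clonotype sharing and clonal-expansion statistics,
V/J/VJ gene-usage comparison, a ROC-based discriminative VJ-pairing screen,
and a repeated equal-sampling L1-logistic (LASSO) diagnostic harness. A
synthetic repertoire generator with recorded ground truth stands in for
patient cohorts, so every stage is testable offline.

## Package layout

| module | contents |
|---|---|
| `repdx.repertoire_io` | AIRR TSV + metadata readers/writers, clonotype keys (`aa`, `nt`, `v_aa_j`), the frozen 48 TRBV × 13 TRBJ gene universe (624 VJ pairings), validation |
| `repdx.synthetic_data` | tissue-panel simulator (T/N/B per patient, power-law blood, planted expansion and overlap) and cohort simulator (Dirichlet VJ usage with planted case/control shift); `SimTruth` ground truth; deterministic fixtures |
| `repdx.diversity` | Shannon entropy, top-k clonality, entropy–clonality correlation, paired/rank group comparisons with Bonferroni adjustment |
| `repdx.overlap` | pairwise/three-way sharing fractions (clone-abundance and clonotype-count variants), expansion ratios, within- vs between-patient sharing, public clonotypes, chi-square clinical association |
| `repdx.usage` | V/J/VJ usage matrices, Kruskal–Wallis + pairwise Wilcoxon differential usage, dominant-pairing selection, PCA on scaled usage |
| `repdx.diagnostics` | rank-based feature AUC, log fold change, marker screen, 80/20 equal-sampling splits, cross-validated L1 logistic fit, repeated evaluation report |
| `repdx.cli` | `repdx` command-line interface and full-pipeline orchestration |

## CLI

```bash
repdx simulate  --config sim.yaml --out fixtures/
repdx validate  --airr fixtures/ --meta fixtures/metadata.tsv --policy quarantine
repdx diversity --airr fixtures/ --meta fixtures/metadata.tsv --level aa --k 100 --out diversity.tsv
repdx overlap   --airr fixtures/ --meta fixtures/metadata.tsv --key v_aa_j --out overlap.tsv
repdx usage     --airr fixtures/ --meta fixtures/metadata.tsv --level VJ --out usage.tsv
repdx pca       --airr fixtures/ --meta fixtures/metadata.tsv --out pca.tsv
repdx markers   --airr fixtures/ --meta fixtures/metadata.tsv --lfc 0.25 --auc 0.7 --out markers.tsv
repdx classify  --airr fixtures/ --meta fixtures/metadata.tsv --repeats 100 --seed 1 --out report.json
repdx all       --config run.yaml --out out/        # full pipeline + manifest
```

A `sim.yaml` mirrors `SimConfig` field-for-field, e.g.:

```yaml
n_patients: 10
clonotypes_per_sample: 400
reads_per_sample: 20000
frac_shared_TN: 0.5
frac_shared_blood: 0.3
seed: 1
```

For the case/control cohort mode set `n_cohorts: 2` with `n_case`,
`n_control`, `n_diff_features` and `effect_size`.

## Notes

- Clonotype identity defaults to `v_aa_j` (`<V>_<CDR3aa>_<J>`); `aa` and
  `nt` schemes are selectable everywhere a key scheme is accepted.
- Entropy uses natural log by default (`base=2` available).
- All simulators are bit-reproducible under a fixed seed; per-patient and
  per-sample streams are spawned from a single `SeedSequence`.
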