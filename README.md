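# lyticpred

Protein-sequence feature engineering and binary classification toolkit:

* **Four feature encoders** — amino-acid composition (AAC, 20 features),
  dipeptide composition (DC, 400 features), auto-covariance of PSSM columns
  (PSSM-AC, 20 × lg features) and average-chemical-shift lag summaries
  conditioned on secondary structure (acACS, |nuclei| × (λ+1) features).
* **SMOTE** minority-class oversampling to parity.
* **F-score ranking** with incremental feature selection (IFS).
* **RBF-SVM** classification with (c, γ) grid search.
* **Jackknife / stratified k-fold** evaluation reporting Sn, Sp, MCC, Acc.

The toolkit parses PSI-BLAST ASCII PSSM profiles and PSIPRED `.ss2`
secondary-structure files — it does not run those programs. A synthetic
fixture generator (`lyticpred.synthetic`) emulates all three input kinds so
the whole pipeline is testable offline.

## CLI

```bash
# generate a synthetic dataset (FASTA ×2, per-record .pssm/.ss2, manifest)
lyticpred synthesize --n-pos 20 --n-neg 40 --seed 1 --separation 2.0 --outdir data/

# encode features
lyticpred extract --pos data/pos.fasta --neg data/neg.fasta \
    --manifest data/manifest.tsv --blocks AAC,DC,acACS,PSSM-AC \
    --lg 28 --lam 17 --out features.csv

# balance, rank, select, train, evaluate
lyticpred balance  --matrix features.csv --k 5 --seed 1 --out balanced.csv
lyticpred rank     --matrix balanced.csv --out ranking.csv
lyticpred ifs      --matrix balanced.csv --ranking ranking.csv --step 10 --out curve.csv
lyticpred train    --matrix balanced.csv --grid --out model.joblib
lyticpred evaluate --matrix features.csv --protocol jackknife \
    --smote-mode outside --seed 1 --out report.json

# or the whole workflow from one YAML config
lyticpred run --config config.yaml --outdir run/

# hyperparameter sweeps (lg, lam, or the 15 nuclei subsets)
lyticpred sweep --config config.yaml --parameter nuclei --values all --outdir sweeps/
```

`config.yaml` holds the fields of `lyticpred.pipeline.PipelineConfig`
(paths, feature blocks, `lg`, `lam`, nuclei, SMOTE settings, SVM settings,
evaluation protocol). Defaults reproduce the published operating point:
all four blocks, lg=28, λ=17, all four nuclei, SMOTE to parity before a
jackknife evaluation.

## Library example

```python
from lyticpred import (
    load_dataset, PipelineConfig, build_feature_matrix,
    smote_balance, fscore_rank, jackknife,
)
from lyticpred.classify import SVMConfig, svm_trainer

ds = load_dataset("pos.fasta", "neg.fasta", "manifest.tsv")
matrix = build_feature_matrix(ds, PipelineConfig())
balanced = smote_balance(matrix, k=5, seed=1)
ranking = fscore_rank(balanced)
report = jackknife(matrix, svm_trainer(SVMConfig(c=8.0)), smote_mode="outside", seed=1)
print(report.to_tsv_line())  # Sn  Sp  MCC  Acc
```

## Protocol notes

* SMOTE placement is explicit everywhere: `outside` balances once before
  the cross-validation loop (matches the published protocol but leaks
  synthetic near-copies of held-out minority points into training);
  `inside` re-balances each training split (statistically sound). Reports
  record which mode produced them.
* The acACS lag statistic defaults to the mean of signed differences
  (`acacs_variant="difference"`); a conventional auto-covariance variant is
  available. The F-score denominator defaults to the symmetric Bessel form
  (`variant="symmetric"`); the asymmetric `printed` form is available.
* The shipped average-chemical-shift table
  (`src/lyticpred/data/acs_default.tsv`) contains nominal random-coil
  values with helix/sheet offsets; supply your own table via
  `--acs-table` / `ACSTable.from_file` for production use.

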