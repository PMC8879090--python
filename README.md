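# trapeval

Evaluation pipeline for using pre-trained ImageNet classifiers as binary
species detectors on camera-trap imagery. The package covers the full
analysis chain:

1. **Store** (`trapeval.store`) — prediction records (per-image, per-model
   top-5 synsets with confidences), ground truth and a bundled 36-model
   catalog, interchangeably in CSV, JSON Lines or a single SQLite database.
2. **Synthetic data** (`trapeval.synthetic`) — a Gaussian-copula generator
   producing top-5 records with configurable per-model sensitivity and
   specificity, rare positives and tunable inter-model correlation, so the
   whole pipeline is testable without any CNN inference.
3. **Detection mapping** (`trapeval.mapping`) — collapse each model's top-5
   output to one boolean per (image, model): detected iff any top-5 synset
   is in the target set (default: the two ImageNet categories whose labels
   cover the lynx, `n02127052` and `n02125311`), independent of rank and
   confidence.
4. **Metrics** (`trapeval.metrics`) — TP/TN/FP/FN plus twelve derived
   parameters (TPR, TNR, PPV, ACC, ERR, BAC, GM, YI, DP, F1, MCC, Cohen's
   kappa), with NaN-plus-warning semantics for undefined values and
   deterministic top/bottom-k rankings.
5. **Ensembles** (`trapeval.ensemble`) — kappa-cutoff member selection
   (with an optional sharp-drop truncation rule), threshold voting
   ("detected iff at least t members detect"), brute-force threshold search
   and relative-improvement comparison against standalone models.
6. **CLI** (`trapeval.cli`) — `simulate` / `evaluate` / `ensemble` /
   `report` subcommands tying the stages together.

The package bundles, as plain-CSV reference data, the published confusion
counts of 36 CNN models evaluated on 293,604 camera-trap images (1630 lynx
positives), plus the counts of the Multi-3/4/5 voting ensembles. All derived
metric tables and ensemble comparisons reproduce from those counts alone.

Note on discriminant power: the published tables were produced with the
coefficient `sqrt(3)/3.14` (pi truncated), so that is the default
(`DP_COEF_PUBLISHED`); pass `dp_coef=DP_COEF_EXACT` for `sqrt(3)/pi`.

## CLI

```sh
# generate a synthetic dataset (4 study-like model profiles, 400 images)
trapeval simulate --n-images 400 --prevalence 0.25 --models 4 --seed 7 --out-dir out/

# per-model confusion counts + 12 metrics + rankings
trapeval evaluate --predictions out/predictions.csv --truth out/truth.csv --out-dir out/

# kappa-selected voting ensembles with a brute-force threshold sweep
trapeval ensemble --predictions out/predictions.csv --truth out/truth.csv \
    --max-members 5 --max-members 4 --max-members 3 --out-dir out/

# top/bottom-5 report from a saved metric table
trapeval report --table out/metric_table.csv --metric KAPPA
```

Exit code 2 signals a validation error (malformed records, missing truth
rows, impossible selection rules).

## Library quick start

```python
import trapeval as te

table = te.metric_table_from_counts(te.load_study_counts())
members = te.select_members(table, te.SelectionRule(kappa_cutoff=0.2, max_members=5))
# -> ['Inc_Res_v2', 'Pns_lrg', 'Inc_v4', 'Ns_lrg', 'Inc_v3']
```

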