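# fleaselect

Feature-selection toolkit combining a population-based metaheuristic (the
"flea" optimizer) with L1-penalized least squares, plus the surrounding
experiment machinery: synthetic planted-signal feature data, class
dissimilarity statistics, a confusion-matrix metric suite, a ResNet-50
layer-graph census, and a before/after-optimization pipeline with a
three-arm ablation.

## What it does

- **`fleaselect.synthetic`** — seeded generators for wide feature matrices
  with a planted informative block, correlated redundant copies and pure
  noise columns; stratified train/validation splitting with
  largest-remainder rounding; rotate/reflect/shear/resize image augmentation.
- **`fleaselect.lasso`** — the penalized objective
  `J(psi) = (1/2N)||f - L psi||^2 + alpha*||psi||_1`, a cyclic
  coordinate-descent solver with soft-thresholding, and nonzero-coefficient
  feature masks. A Gram-space variant of the same solver
  (`fleaselect._cd`, numba-accelerated) backs the optimizer's hot path.
- **`fleaselect.foa`** — the flea optimization algorithm: a population of
  points in `[0,1]^t`, thresholded into candidate feature masks and scored
  by the negated converged LASSO objective; resilin-weighted
  exploration/exploitation updates with elitism; descending-importance
  feature ranking and a final full-tolerance LASSO shrinkage step.
- **`fleaselect.dissimilarity`** — per-class intra/inter-class mean
  Euclidean distance and the class margin (inter − intra).
- **`fleaselect.metrics`** — accuracy, error, recall, specificity,
  precision, FPR, F1, MCC and Cohen's kappa from confusion counts; macro
  multiclass averaging; one-sample t-test and mean confidence interval.
- **`fleaselect.architecture`** — constructive layer graphs of the standard
  (177-node, 25.6 M parameter) and reduced (146-node) bottleneck network,
  with exact kind censuses and learnable-parameter counts.
- **`fleaselect.pipeline`** — six-classifier bank (decision tree + five
  tanh MLPs), stratified k-fold evaluation before and after selection,
  percent-improvement table, and a three-arm ablation
  (LASSO-only / FOA-only / hybrid).

## CLI

```bash
fleaselect simulate --spec spec.yaml --out data/ --seed 1
fleaselect select --data data/features.csv --alpha 0.003 --population 20 \
    --iterations 100 --seed 1 --out result.json
fleaselect dissim --data data/features.csv --mask result.mask.csv --out report.csv
fleaselect run --data data/features.csv --config cfg.yaml --seed 1 --out results/
fleaselect ablation --data data/features.csv --seed 1 --out ablation.csv
fleaselect arch-report [--modified] [--stage-config 3,4,3,3] [--width 1.0]
```

`spec.yaml` holds `SyntheticSpec` fields (`n_per_class`, `n_features`,
`n_informative`, `class_separation`, ...); the experiment config accepts
`n_folds`, `classifiers`, `classifier_max_iter` and a nested `foa` block
with `FOAConfig` fields.

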