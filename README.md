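# riskpattern

Interpretable rule-pattern discovery and evaluation for **imbalanced binary
clinical outcomes**, with clinician-in-the-loop model editing.

`riskpattern` is aimed at clinical-data scientists who need a risk model a
physician can read, question, and amend. The model is a *pattern*: a set of
m variable–value conditions (e.g. `GFR ≤ 45 ml/min`, `urgent PCI = Yes`,
`contrast volume > 79.5 mL`) plus a minimum match count k. A patient record
is predicted positive when it satisfies at least k of the m conditions. The
threshold is shown to users as a *matching ratio* — ⌊100·k/m⌋ percent — and
ratios parse back with a ceiling, so an 18% ratio on an 11-condition
pattern means "match at least 2 of 11".

The package covers the full workflow around that model:

- **Cohort handling** — CSV cohorts in chronological order with mixed
  numeric/categorical predictors, missing values retained (a missing value
  simply never matches a condition), chronological train/test splitting,
  outcome labeling from paired creatinine columns (AKIN criterion:
  ≥ 0.3 mg/dL or ≥ 1.5-fold rise), and 1:1 up/down resampling helpers.
- **Discovery (pre-mode)** — numeric variables are binarized at the cutoff
  maximizing information gain for the outcome (the classification-tree
  branching criterion); a deterministic greedy forward search grows the
  condition set, re-optimizing k exhaustively at every step against a
  training objective suited to rare outcomes (F-score by default, G-mean
  optional).
- **Knowledge incorporation** — *in-mode*: apply clinician edits
  (add/remove variables, change cutoffs or comparators) and re-optimize k
  on the training data, never touching conditions the clinician did not
  edit; *post-mode*: data-free overrides of values and threshold. Every
  step is appended to an edit history carried inside the pattern file.
- **Evaluation** — sensitivity, specificity, precision, F-score
  (0 when TP = 0), G-mean = √(sensitivity·specificity), trapezoidal ROC
  AUC with tie grouping (the pattern's ROC score is its match fraction
  k/m), Youden-optimal operating points for external risk-score columns,
  and a baseline-characteristics comparison table (one-way ANOVA for
  numeric variables, Yates-corrected chi-square for categorical ones).
- **Synthetic cohorts** — a generator for train/test pairs with planted
  k-of-m risk structure, rare outcomes, and train→test concept drift,
  including a 16-variable AKI-like default (training prevalence ≈ 8.3%
  drifting to ≈ 5.2%).

## Worked example

Simulate the AKI-like cohort, discover a pattern on the first 70% of
records, flip one condition the way a clinician would, refine it offline,
and compare all three models on the held-out 30%:

```bash
riskpattern simulate --seed 11 --out-dir demo
# wrote demo/train.csv (n=1791, prevalence 0.074) and demo/test.csv (n=769, prevalence 0.049)

riskpattern discover --cohort demo/train.csv --schema demo/schema.yaml \
    --target AKI --train-fraction 0.7 --out demo/pre.json --deterministic
# pattern: [AKI = Yes] gfr ≤ 38.09..., urgent_pci = Yes, age ≤ 31.64..., mi_history = No,
#          hypotension = No, pre_peak_creatinine > 64.22..., iabp = No (match ≥ 5/7, ratio 71%)
# training metrics: {"auc": 0.6871, "sensitivity": 0.4891, "specificity": 0.8708, ...}

echo '[{"action": "set_comparator", "variable": "age", "payload": ">"}]' > demo/edits_in.json
riskpattern edit --cohort demo/train.csv --schema demo/schema.yaml --target AKI \
    --pattern demo/pre.json --edits demo/edits_in.json --out demo/in.json --deterministic
# pattern: [AKI = Yes] ... age > 31.64... (match ≥ 6/7, ratio 85%)

echo '[{"action": "set_value", "variable": "age", "payload": 70.0},
      {"action": "set_value", "variable": "gfr", "payload": 45.0}]' > demo/edits_post.json
riskpattern refine --pattern demo/in.json --edits demo/edits_post.json \
    --out demo/post.json --deterministic   # no cohort: post-mode is data-free

riskpattern evaluate --cohort demo/test.csv --schema demo/schema.yaml --target AKI \
    --pattern demo/pre.json --pattern demo/in.json --pattern demo/post.json \
    --out demo/report.csv
#            model    auc  sensitivity  specificity  f_score  g_mean  threshold
#   pre (pre-mode) 0.6019       0.3684       0.8550   0.1772  0.5612        5.0
#     in (in-mode) 0.6030       0.3684       0.8564   0.1783  0.5617        6.0
# post (post-mode) 0.5959       0.1316       0.9439   0.1190  0.3524        6.0
```

What the numbers mean: the discovered pattern predicts AKI when at least
5 of its 7 conditions hold; flipping the age condition makes the
re-optimized threshold stricter (6 of 7, ratio 85%). On the drifted test
period the models keep high specificity at modest sensitivity — the
AKI-like default deliberately carries a weak, noisy signal, so test AUCs
around 0.6 are the expected regime, not a failure of the tooling. On
strong planted-signal cohorts (`riskpattern.synth.planted_signal_config`)
discovery recovers the planted variables and reaches test AUCs above 0.95;
see `docs/methods.md`.

The same workflow is available as a library:

```python
from riskpattern import (aki_cohort_config, generate_cohort,
                         discover_pattern, evaluate_pattern)
train, test = generate_cohort(aki_cohort_config(), seed=11)
pattern = discover_pattern(train)
print(pattern)
print(evaluate_pattern(pattern, test).to_dict())
```

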