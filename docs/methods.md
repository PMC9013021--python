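# Methods

This note documents the model, the algorithms, the defaults, and the
design decisions behind `riskpattern`, in the order a reader would meet
them in the workflow.

## The pattern model

A pattern P over a variable schema is a pair (C, k): a set of m = |C|
conditions, each on a distinct variable, and a minimum match count
k ∈ [1, m]. Conditions are `x ≤ v` / `x > v` for numeric variables
(boundaries read exactly as written: ≤ inclusive, > exclusive) and
`x = c` for binary/categorical ones. A record r matches condition count

    s(r) = #{ c ∈ C : c holds on r },

and the prediction is positive iff s(r) ≥ k. A missing value satisfies no
condition — never an error. This is deliberate: the method is meant for
incomplete registry data, and treating missingness as non-match makes a
pattern's positive set shrink, not explode, as data quality degrades.

**Matching ratio.** Users see k as a percentage. Display uses the floor,
⌊100·k/m⌋; parsing a ratio uses the ceiling, k = ⌈ratio·m⌉. The pair is
chosen so the two operations round-trip exactly for every 1 ≤ k ≤ m ≤ 50
(floor display keeps the percentage below the next count; ceiling parsing
recovers it; the identity holds for all m < 100). Rounding the display
instead would break the round trip (k=2, m=7 displays 29%, but
⌈0.29·7⌉ = 3). Pattern files store k explicitly; the percentage is
cosmetic.

**Continuous score.** For ROC analysis a pattern scores a record by its
match fraction s(r)/m, an (m+1)-level score whose level sets are exactly
the k-thresholded predictions. This is a design choice of this package:
a k-of-m rule has no canonical continuous score, and the match fraction
is the one whose thresholds coincide with the rule family itself.

## Information-gain binarization

Numeric variables are categorized as "≤ x" / "> x" with x chosen to
maximize information gain (base-2 Shannon entropy) for the binary target
on training data — the branching criterion of classification trees,
applied once per variable. Candidate cutoffs are the midpoints between
consecutive distinct observed values: on integer-valued data this yields
half-unit cutoffs (58.5 years, 79.5 mL), the form clinical scorecards
print. Records with a missing value are excluded from the scan rather
than treated as a third block, consistent with the non-match rule above.
Ties in gain break toward the smaller cutoff, for determinism. A variable
with fewer than two distinct values, or whose best gain is zero, yields
no rule.

## Greedy discovery (pre-mode)

Candidate conditions are generated once: for each numeric variable, the
best-gain cutoff, oriented toward the side with the higher positive-class
rate (so candidates read as risk factors, "contrast volume > 79.5 mL");
for each categorical/binary variable, one equality condition per observed
category.

The search is deterministic greedy forward selection. Starting from the
empty set (objective 0), each step tentatively adds every unused
candidate, re-optimizes k by exhaustive scan over 1..m′ on the training
data, and keeps the best addition. Stopping: improvement below
`min_improvement`, candidate pool exhausted, or `max_conditions` reached.
Tie-breaks, in order: training objective, chi-square association of the
candidate's match indicator with the target, lexicographic variable name.
A pattern never holds two conditions on one variable, so accepting a
candidate retires all other candidates on that variable.

Defaults: objective = training F-score (the point metric that balances
precision and sensitivity for rare outcomes; G-mean is selectable),
`max_conditions` = 16 (one per input variable of the motivating cohort),
`min_improvement` = 1e-6 (any strict improvement). Threshold ties break
toward larger k — the stricter, more specific pattern.

Two behaviors of this search are worth knowing. First, with the
permissive default `min_improvement` it will happily append marginal
conditions after the signal is captured (tiny training-F gains exist in
any finite sample); variable *identification* is therefore judged as
containment of the true variables in the discovered set, and the
`min_improvement` knob is the brake if parsimony matters. Second, on data
with no signal at all, a strict improvement threshold (say 0.01–0.05)
stops the search at one or two conditions with a training objective near
the all-positive baseline F = 2p/(1+p).

**Arcs.** For interpretability, every unordered pair of pattern variables
is tested for association: the 2×2 table of their per-record
condition-match indicators over all supplied records, chi-square test of
independence with Yates continuity correction. Indicators (not raw
values) are tested because indicators are what the pattern computes with.
A degenerate table (an indicator constant on the cohort) reports
statistic 0, p = 1. Under independent indicators the flagged-arc rate at
α = 0.05 sits slightly below 0.05 (the correction is conservative);
the test suite verifies ≈ 4% over 1000 null replicates.

## Knowledge incorporation

**In-mode** applies a clinician's edits — add/remove variables, change a
cutoff or comparator — exactly as given, then re-optimizes only k on the
training data. Conditions the edit list did not touch are never revised;
"the model keeps the variable–value pairs the clinician accepted" is the
contract that makes interactive editing trustworthy. An optional
`full_rediscovery` switch (off by default) instead resumes the greedy
search with the edited conditions pinned. Adding a variable without an
explicit value pulls a data-derived default: the best-gain cutoff
(risk-oriented side) for numeric variables, the highest-positive-rate
category otherwise.

**Post-mode** applies overrides verbatim — condition values, comparators,
or k itself — with no data access at all; it is a pure function of
(pattern, edits), and the CLI's `refine` command refuses a cohort
argument to keep that property honest. The resulting k must stay in
[1, m]; `set_min_matches` is rejected in in-mode, where k belongs to the
optimizer.

Every application appends one history entry (mode, timestamp, edit list,
resulting m, k, and — for data-driven steps — the training objective).
Replaying the recorded edit lists from the discovery output reconstructs
the final pattern; the history rides inside the pattern JSON.

## Evaluation

Point metrics follow the standard rare-outcome panel: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP) with 0/0
defined as 0, F-score = 2·precision·sensitivity/(precision+sensitivity)
defined as 0 when TP = 0, and G-mean = √(sensitivity·specificity).

The ROC curve places one vertex per distinct score (ties grouped — no
interpolated staircase through tied scores) plus the (0,0) endpoint; AUC
is the trapezoidal area, which equals Mann–Whitney pairwise concordance
with ties counted one half (verified against a brute-force oracle and
scikit-learn in the tests). The optimal operating point maximizes
Youden's J = sensitivity + specificity − 1; ties resolve toward higher
specificity. External risk-score columns are evaluated either at a
published numeric cutoff (score ≥ cutoff positive; `>` selectable) or at
the Youden point, so externally developed scorecards are not understated
by a miscalibrated published threshold.

Cohort comparison mirrors a baseline-characteristics table: numeric
variables by two-group one-way ANOVA (the equal-variance F-test,
algebraically the pooled t-test squared), categorical/binary variables
and the outcome by chi-square with Yates correction on 2×2 tables. The
correction is load-bearing: on the motivating cohort's published
composition, the corrected statistic reproduces the printed p-values
(0.007 outcome, 0.016 anemia, 0.019 urgent PCI) where the uncorrected
one does not (0.006/0.011/0.016).

## Synthetic cohorts

The generator draws predictors independently from per-variable marginals
(Gaussian for numeric, Bernoulli/categorical otherwise), optionally with
shifted test-period marginals, and draws the outcome per record with
probability

    P(y = 1 | r) = baseline_risk + risk_per_match · s_planted(r),

clamped to [0, 1] (a warning is logged if clamping touches more than 5%
of records). The additive-risk form is chosen over a logistic link
because it makes the planted pattern exactly the structure k-of-m
matching detects and keeps prevalence arithmetic transparent:
E[prevalence] = baseline + risk_per_match · E[s]. An optional pairwise
correlation hook (Gaussian, applied to numeric pairs) induces
associations for the arcs to find. Records are ordered train-then-test to
emulate chronology.

**AKI-like default** (`aki_cohort_config`): 16 variables with the
motivating cohort's published train/test means, SDs, and category rates
(age 64.37 ± 11.07 y; contrast volume 135.23 ± 71.17 mL train vs
124.46 ± 63.90 mL test; urgent PCI 11.4% vs 14.8%; ...). The planted
pattern is contrast volume > 200 mL, GFR ≤ 45 ml/min, LVEF ≤ 45%,
urgent PCI = Yes. With baseline risk 0.04 (test period 0.015) and +0.10
per matched condition, the expected match probabilities under the
configured marginals (≈ 0.18 + 0.11 + 0.03 + 0.11 in train,
≈ 0.12 + 0.08 + 0.03 + 0.15 in test) put the expected prevalences at the
published 8.3% / 5.2%, with the drop split between covariate drift and
the lower test-period baseline. This is intentionally a *weak-signal*
regime: it reproduces the study conditions (rare outcome, drift, modest
effect sizes), not a best case for the method.

**Strong-signal config** (`planted_signal_config`): 2–4 planted
conditions, each matched by ≈ 5% of records (numeric cutoffs at 1.645 SD,
binary p = 0.05), +0.75 risk per match over a 0.001 baseline, four noise
variables. The arithmetic: a record matching any condition is positive
with probability ≳ 0.75 while non-matchers are positive with 0.001, so
≈ 99% of positives score ≥ 1/m and ≈ 4% of negatives do — an oracle
match-fraction AUC near 0.98 at ≈ 10% prevalence. The test suite runs 20
seeded replicates at n_train = 2000: the planted variables are contained
in the discovered set in ≥ 90% of replicates (20/20 observed) and the
mean discovered-pattern test AUC exceeds 0.95.

What these fixtures do *not* emulate: informative missingness, site and
temporal effects beyond a mean shift, correlated comorbidity structure
(unless configured), or calibration drift. Passing the recovery suite
shows the search finds k-of-m structure when it exists and is strong; it
does not promise clinical-grade discrimination on real registries, where
the AKI-like default's AUC ≈ 0.6–0.7 regime is the more honest preview.

## Numerical and degenerate-input choices

- Entropy and gain in bits (base 2); gain ordering is base-invariant.
- Best-split ties → smaller cutoff; threshold-scan ties → larger k;
  greedy ties → target association, then variable name. All searches are
  fully deterministic; the `seed` in `DiscoveryConfig` is reserved.
- Objective identically 0 for every k → k = m is returned with a logged
  warning (the degenerate pattern predicts as little as possible).
- Floating-point ceiling in ratio parsing subtracts 1e-9 before ⌈·⌉ to
  absorb representation excess on exact products (e.g. 0.7·10).
- Creatinine unit conversion fixed at 88.4 μmol/L per mg/dL.
- Chronological split takes ⌊fraction·n⌋ records for training, clamped so
  both sides are non-empty; no shuffling anywhere.
- Resampling: up-sampling draws positives with replacement to the
  negative count; down-sampling subsamples negatives without replacement;
  both require the expected minority/majority orientation and a seed.

## Known limitations

- One condition per variable; no multi-way discretization, per-condition
  weights, or pattern ensembles.
- Greedy forward search with threshold re-optimization is a heuristic; it
  is not guaranteed to find the globally optimal condition set, and with
  the permissive default stopping rule it overfits marginal conditions
  (see above).
- No confidence intervals on AUC, no calibration assessment.
- The cohort-comparison ANOVA assumes roughly normal numeric variables;
  heavy-tailed laboratory values may warrant a rank test the package does
  not provide.
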