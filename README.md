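# urgetide

Analysis of urge–tic associations from continuous "urge monitor" recordings
in Gilles de la Tourette syndrome (GTS), together with a synthetic-cohort
simulator with known causal structure so the whole pipeline is testable
without any clinical data.

## The problem

Premonitory urges are unpleasant sensations that many GTS patients report
before a tic.  Whether tics are *driven* by urges — or urges are a byproduct
of anticipating tics — is an open question with direct consequences for
behavioral therapy.  The urge-monitor paradigm addresses it with temporally
fine-grained data: the patient continuously reports urge intensity on a
0–100 slider (sampled at 10 Hz) for a 300-s session while being video
recorded; two independent raters then code each 1-s interval for motor tics
(intensity 1–8) and vocal tics (intensity 1–7).

`urgetide` turns those raw inputs into per-subject and group-level
association measures.  For each subject, with per-subject z-standardized
series on the trimmed 1-s grid (first and last 10 s dropped, 280 intervals
of a standard session):

* **logistic**: `logit P(tic_t = 1) = b0 + β·z_urge_t` — β is the log-odds
  change per SD of urge, `OR = exp(β)`;
* **linear**: `z_urge_t = b0 + β·tic_t` — β is the urge elevation (in SD) in
  tic intervals vs tic-free intervals;
* **intensity**: Pearson `r` between z-urge and the z-scored *instantaneous
  tic intensity* (11-s central moving average of the fused interval
  intensity, 0 where no tic).

Each measure is labelled positive / n.s. / negative at two-sided α = 0.05.
Group-level counterparts are mixed-effects models with per-subject random
intercept and random slope (maximal structure; logistic family fitted by
Laplace maximum likelihood, linear families via `statsmodels` MixedLM),
tested by a df-1 likelihood-ratio test, with an automatic fall-back to the
random-intercept model for singular fits.  Cohort statistics include
inter-rater reliability, Bonferroni–Holm-corrected correlations with
clinical scores (YGTSS, PUTS, RUSH, GTS-QoL, Conners; families tic: 2,
urge: 2, urge–tic: 3) and Welch comparisons against an adult cohort with the
one-sided hypothesis "adults > children" for the association measures.

The simulator generates cohorts under three regimes — `urge_drives_tic`
(tic probability coupled to the standardized urge), `tic_drives_urge`
(urge bumps around a constant-rate tic process) and `none` — plus a
two-rater observation model and clinical-like scores with a configurable
linkage, so calibration, recovery and power of every stage are measurable
against ground truth.

## Worked example

```python
from urgetide import (SimulationConfig, simulate_cohort, preprocess_bundle,
                      analyze_cohort, classification_counts, fit_group_model)

cfg = SimulationConfig(n_subjects=25, gamma=0.44, slope_sd=0.3, seed=7)
cohort = simulate_cohort(cfg)
series = [preprocess_bundle(b) for b in cohort.bundles]

results = analyze_cohort(series)
print(classification_counts(results))
group = fit_group_model(series, family="logistic")
print(group.summary().to_string(index=False))
```

prints

```
           positive  ns  negative  degenerate
measure
logistic         18   6         1           0
linear           18   6         1           0
intensity        24   1         0           0
  family     beta  chi_sq(1)            p  re_var_intercept  re_var_slope  singular_fallback window_s  n_subjects
logistic 0.418987 262.148951 5.835840e-59               0.0           NaN               True     full          25
```

The cohort was simulated with a mean coupling slope of 0.44 and
between-subject SD 0.3, so most — but not all — subjects show a significant
positive urge–tic association, one drew a negative slope, and the group
fixed effect (0.42) recovers the generating value.  `singular_fallback=True`
records that the random slope was removed: the simulated subjects share a
baseline tic rate, so the random-intercept variance sits on the boundary.
Per-subject results are `AssociationResult` objects
(`results[0].summary()`, `results[0].odds_ratio`, ...).

The same pipeline runs from files:

```bash
urgetide simulate --seed 7 --out cohort/
urgetide analyze --cohort cohort/ --out results/ [--nonvocal-only] [--compare-cohort adults/]
```

writing summaries, associations, classification counts, group-model fits,
inter-rater reliability, clinical correlations and (with a second cohort)
Welch comparisons as CSV, plus a provenance record.

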