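# Methods

## Data model

A session is a pair of synchronized streams on a common clock: a continuous
urge self-report (0–100 slider, 10 Hz) and two raters' per-1-s-interval tic
codes (motor presence + intensity 1–8, vocal presence + intensity 1–7).
Intervals are 0-based and half-open, `[t, t+1)` seconds; the urge sample at
time `s` belongs to interval `floor(s)`.

## Preprocessing

1. **Alignment.** The 10 Hz trace is collapsed to one value per interval by
   the within-interval arithmetic mean (the variance-minimizing summary; a
   "last sample in interval" option exists for sensitivity analyses).
2. **Rater fusion.** Per modality, presence is the disjunction of the two
   raters (a tic is counted if at least one rater scored it) and intensity is
   the mean over the raters who assigned one — so a tic seen by a single
   rater keeps that rater's intensity.
3. **Modality combination.** Motor and vocal intensities are combined per
   interval by taking the maximum of the present values.  When a session has
   no usable audio, vocal codes are dropped and the subject is flagged
   motor-only.
4. **Instantaneous tic intensity.** An 11-s central moving average of the
   combined intensity, with 0 substituted in tic-free intervals so the
   smooth signal decays between tics.  Edge windows truncate to the
   available intervals (preserving series length); the subsequent trim
   removes the most affected region anyway.
5. **Trimming and standardization.** The first and last 10 s are dropped
   (280 intervals of a standard 300-s session), then urge and instantaneous
   intensity are z-standardized per subject (ddof = 1, following the
   convention of R's `scale()`).  A zero-variance series marks the subject
   degenerate rather than dividing by zero.  Standardization follows
   trimming, so the z-scores refer to the analyzed range.

## Association measures

Per subject: logistic regression of tic presence on z-urge (ML, two-sided
Wald p), OLS of z-urge on tic presence (the slope equals the conditional-
mean difference exactly), and Pearson correlation between z-urge and
z-instantaneous intensity (t-based p).  Two-sided tests are required to
admit negative associations, which do occur.  Complete separation and
one-class responses are labelled degenerate; no penalized likelihood is
substituted, keeping the estimator plain ML.

Group level: mixed models with per-subject random intercept and random
slope, unstructured covariance.  The logistic family is fitted by maximizing
the Laplace approximation to the marginal likelihood (implemented in
`urgetide.mixedlogit`, validated against `lme4::glmer` — agreement to ~1e-3
on the fixed effects and ~1e-4 on the log-likelihood on a frozen test
dataset); the linear families use `statsmodels` MixedLM with ML (not REML)
so the likelihood-ratio test of the fixed slope (df 1) is valid.  A fit is
declared singular when any random-effect variance falls below 1e-6 or the
random-effect correlation reaches ±1; the model is then refitted without the
random slope and flagged.  Families with a z-standardized response are
fitted on the 50–250 s window: full-range standardization removes
between-subject intercept variance and reliably produces singular maximal
fits, while the restricted window leaves the intercept variance identified.

## Cohort statistics

Inter-rater reliability is Pearson's r on the 0/1 presence indicators
(equivalently the phi coefficient) and on the combined intensity series
(0 where no tic).  Correlations between urge-monitor measures and clinical
scores use pairwise-complete observations (n reported per pair, pairs with
fewer than 3 observations skipped) with Bonferroni–Holm correction applied
per clinical score within each measure family — tic (2 measures), urge (2),
urge–tic (3); `holm_adjust` accepts an explicit family size m, which may
exceed the number of computed p-values.  Cohort comparisons use Welch
t-tests with Satterthwaite df; association measures additionally get the
one-sided test of the directional hypothesis that adults couple more
strongly than children.  A non-vocal control analysis reruns the entire
pipeline with vocal codes masked.

## Simulator

* **Urge**: an Ornstein–Uhlenbeck process, Euler–Maruyama at the recording
  rate, clipped to [0, 100] after each step.  OU rather than a random walk
  because the slider signal is bounded, mean-reverting and stationary.
  Defaults: mean 13, relaxation time 20 s, diffusion 4.7 (stationary SD
  ≈ 15), matching reported pediatric urge-monitor cohorts (mean urge ≈ 13,
  SD ≈ 15) in level and spread; the 20-s relaxation time is a
  phenomenological choice reproducing the slow drift of real traces and is
  not calibrated against recorded traces.
* **Tics (urge-driven regime)**: per interval,
  `tic ~ Bernoulli(logit⁻¹(α + γ·z))` with z the standardized interval-mean
  urge — the same covariate the analysis uses, so the simulated γ *is* the
  estimand of the logistic measure.  Baseline α = 0.46 gives ≈ 61% tic
  intervals.  Intensities are `round(clip(2.2 + 0.5·z + noise))` on the
  modality scale; 6% of tics carry a vocal code.
* **Tics → urge regime**: tics form a constant-rate Bernoulli process; each
  adds an asymmetric triangular bump to the urge (3 s linear rise before,
  5 s decay after, peak |γ|·10 urge units), encoding the increase–decrease
  pattern of urge around tic execution.
* **Raters**: each true tic is scored independently per rater with
  sensitivity 0.9; tic-free intervals draw false positives at rate 0.02 with
  near-minimum intensity; scored intensities get N(0, 0.5) noise, rounded
  and clipped.  These rates imply a between-rater presence correlation of
  ≈ 0.74 at the default tic rate, matching the reported median inter-rater
  reliability (0.71).
* **Cohorts**: per-subject slopes γᵢ ~ N(γ, slope_sd²) with defaults 0.44 /
  0.3, producing zero and negative couplings at realistic frequency.  One
  integer seed expands into per-subject substreams
  (`SeedSequence(seed, spawn_key=(i, stream))`), so cohorts are bit-
  reproducible and order-independent.
* **Clinical scores**: linear-Gaussian transforms of each subject's true
  severity (z-scored across the cohort) with configurable linkage ρ:
  `score_z = ρ·z(measure) + √(1-ρ²)·ε`, rescaled to plausible ranges.  Used
  only for correlation-recovery tests.

What the simulator does **not** emulate: between-subject variation in
baseline tic rate and urge usage of the scale (real tic frequencies span
11–98%), non-stationarity and habituation within a session, tic clustering
beyond urge coupling, rater drift, or missing-audio patterns.  Passing
recovery/calibration tests therefore demonstrates correctness of the
estimators under the assumed generative structure, not robustness to every
feature of clinical recordings.

## Operating characteristics and a known caveat

With no coupling, the per-subject logistic and linear tests are calibrated
(≈ 5% significant at α = 0.05 over 500 simulated subjects).  The Pearson
correlation between urge and instantaneous tic intensity is **not**: both
series are serially correlated (urge by construction of any realistic
slider signal, the intensity by its 11-s smoothing window), so the nominal
t-based p-value dramatically over-rejects (≈ 40–99% depending on the urge
relaxation time; an effective-sample-size argument gives n_eff ≈ n /
Σ_k ρ_x(k)ρ_y(k) ≈ 30 for 280 intervals at the defaults).  The analysis
contract deliberately keeps the plain Pearson test — no autocorrelation-
robust correction is applied — so per-subject "significant correlation"
labels from this measure should be read as descriptive, not inferential.
The regression measures do not share the problem: their response (logistic)
or regressor (linear) is conditionally independent across intervals under
the null, which keeps the conventional variance estimates consistent.

## Numerical choices

* Inner Newton iterations of the Laplace fit are damped by per-subject
  backtracking (the subject-level objective is strictly concave, so damped
  Newton converges from any start); outer optimization is L-BFGS-B over
  fixed effects and the random-effects Cholesky factor, diagonal bounded at
  zero.
* MixedLM fits try lbfgs, then bfgs, then powell, and reject non-finite
  log-likelihoods; if a reduced model ever out-scores the full model that
  nests it, both are refitted with the best of all optimizers.
* Separation in individual logistic fits is detected by non-finite standard
  errors or |β| > 15.
* Problem sizes: calibration uses 500 subjects × 280 intervals; recovery
  200 replicate cohorts of 25 subjects and one 10⁵-interval session; power
  and uniformity 200 replicate cohort pairs at the cohort sizes (25 vs 21).
  At these sizes the Monte-Carlo bands quoted in the tests (3 binomial SE,
  ±0.05 / ±0.10 recovery) are meaningful while the full suite stays fast.

## Limitations

The group logistic estimate carries a small downward bias (~5–8% of the
slope at default settings) from rater misclassification of tic presence —
a real feature of the measurement process, included deliberately in the
recovery experiments.  The simulator's homogeneous baseline tic rate means
the random-intercept variance is genuinely zero, so the maximal group model
is singular by construction on simulated cohorts and the reported fixed
effect usually comes from the documented fallback path.  Clinical-score
generation clips to plausible ranges, mildly attenuating the generator's
nominal linkage at extreme settings.
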