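# Methods

## Model and scope

All thresholds derive from a two-level hierarchical normal model on a
*working scale*: an individual's homeostatic set point `mu_I` is drawn from
`N(mu_pop, sigma_G^2)` and each result from `N(mu_I, sigma_I^2)`, with
`sigma_I^2` absorbing analytical noise. The model's three free quantities are
carried as a `PEBParameters` record — `mu_pop`, `sigma_pop =
sqrt(sigma_G^2 + sigma_I^2)` and the intraclass correlation `b1 =
sigma_G^2 / sigma_pop^2` — together with an explicit scale tag (`log` or
`boxcox` with exponent `lambda`). Every piece of threshold arithmetic
(posterior set point, shrinkage factor, prediction half-width) happens on
the working scale; only the final interval limits are back-transformed.
Keeping the scale explicit in the record prevents the two estimation
pathways, which use different transforms, from being mixed silently.

Key closed forms:

- shrinkage after n prior results: `B_n = b1*n / (b1*n + (1 - b1))`
  (0 at n = 0, b1 at n = 1, → 1 as n → ∞);
- posterior set point: `Y = mu_pop + (x_bar_n - mu_pop) * B_n`;
- prediction half-width: `Z * sqrt(1 - b1*B_n) * sigma_pop`, exact under the
  model, verified by Monte-Carlo coverage tests at n ∈ {0, 1, 5, 9}.

The baseline mean `x_bar_n` uses the `n_use` most recent prior results with
equal weights. Baseline selection is ultimately a clinical decision; equal
weighting of the latest n is the simplest defensible default. The default
confidence level is two-sided 95% (Z = 1.96, configurable). A result exactly
on a limit is not flagged (strict inequality). `b1` estimates that land
slightly outside [0, 1] from noisy regression are clipped with a warning
rather than rejected, so pipelines on small extracts keep running while
surfacing the issue.

No fully-individual interval using only a subject's own variance is
provided, and only symmetric two-sided limits are supported.

## Estimating parameters from routine (LIS-style) data

Stages, each audited by record counts:

1. **Filters.** Results below the assay reporting limit are excluded
   outright (no imputation). For diurnally varying analytes an optional
   window keeps only samples collected 08:00–10:00.
2. **Central-peak population fit** on each patient's chronologically first
   retained result (ties on identical timestamps keep input order). The
   estimator is a two-stage indirect reference-interval fit:
   - *Stage 0 (robust bulk location):* for each Box-Cox exponent on a grid
     (−0.5 to 2.5, step 0.05), the transformed data's central bulk is
     located by iterated truncated moments (start at median/normalized MAD,
     window at ±2 SD, truncation-corrected variance); the exponent whose
     bulk is most uniform under the truncated-normal probability-integral
     transform (Cramér–von Mises distance) wins.
   - *Stage 1 (truncated ML):* a fixed original-scale window — the central
     99% of the stage-0 fit — is imposed, and the Box-Cox-normal likelihood
     truncated to that window (Jacobian and truncation mass included) is
     profiled over the exponent (bounded scalar minimization, inner
     Nelder–Mead over location/scale).

   Because pathological results far from the bulk never enter the window,
   the fit tolerates a shifted pathological minority (tested at 20%).
   A structural caveat: the exponent's information lives largely in the
   tails that a central-bulk fit deliberately ignores, so `(lambda, mu,
   sigma)` trade off against each other; the *implied original-scale
   distribution* (quantiles) is estimated much more precisely (~2–3%) than
   the individual parameters. Recovery tests therefore check the exponent
   coarsely and the back-transformed quantiles tightly. Below 500 first
   results the fit refuses; below 5000 it warns.
3. **Central-99% filter**: all results whose transform falls outside
   `mu_pop ± 2.5758 * sigma_pop` are dropped. The cut uses the fitted
   normal, not empirical quantiles. This filter mildly attenuates the
   subsequent slope (selection acts on both pair members); the attenuation
   is inherent to the procedure and stays well inside the ±0.05 recovery
   tolerance at realistic parameters.
4. **Pair construction**: within each subject, consecutive retained results
   form overlapping sequential pairs (a subject with k results contributes
   up to k−1), kept when the gap exceeds 24 h (guards against
   autocorrelation and same-day duplicates). Unsorted input is an error,
   never silently sorted.
5. **Robust slope = B1.** Regression of `x_next` on `x_prev` with free
   intercept (constraining the intercept toward `mu_pop*(1-B1)` would be
   possible but is not done). The estimator is an MM-type scheme built for
   resistance to contaminated pairs on *either* axis:
   - fast least-trimmed-squares initialization: ~50 random two-point lines,
     two concentration steps each, the best five concentrated to
     convergence (multi-start matters — clustered contamination creates
     competing local optima of the trimmed criterion);
   - residual scale from the best-fitting half (normal-consistent), which
     unlike a full-sample MAD is not inflated by the contamination itself;
   - a rejection pass of Tukey-bisquare IRLS at cutoff c = 3.0 (tolerant of
     the moderate scale over-estimate the trimmed criterion produces under
     contamination), then scale re-estimation from the surviving residuals
     and a final efficient pass at c = 4.685 (max 200 iterations, tolerance
     1e-8). A plain M-estimator started from least squares is *not* robust
     to bad-leverage pairs and demonstrably breaks down on spiked cohorts,
     which is why the initialization and scale handling above are part of
     the design rather than an off-the-shelf M-fit.
   - The 95% CI is a percentile bootstrap (default 1999 resamples, seeded)
     that resamples *subjects*, not pairs, so the overlapping pairs of one
     patient stay together and within-subject dependence is respected. The
     point estimate treats pairs as exchangeable.

## Estimating parameters from a biological-variation study

Input is a balanced subjects × visits (× replicates) table. A four-level
outlier cascade runs first, in order, each exclusion logged:

1. *analytical*: with duplicate analyses, samples whose replicate difference
   exceeds a Bonferroni-adjusted bound on the pooled analytical SD
   (`sd_a*sqrt(2)*z_{1-α/2k}`, iterated) are dropped; without replicates the
   step is skipped with an audit note;
2. *participant mean*: Reed criterion — an extreme subject mean is excluded
   when its gap to the nearest mean exceeds one third of the range,
   iterated from both ends;
3. *individual trend*: subjects whose per-visit means show a linear drift at
   p < 0.01 are excluded;
4. *homogeneity of within-subject variance*: Bartlett's test on
   (log-transformed) within-subject residuals at level 0.05; while it
   rejects, the subject with the largest residual variance is removed.
   Cochran's C is available as an option. Intra-step tie-breaking (which
   subject leaves first) is by largest variance; the published cascades
   leave this open.

Fewer than three surviving subjects is an error. Re-running the cascade on
its own output excludes nothing further (tested).

Variance components then come from nested mean squares
(`MS_rep = s_A^2`, `MS_visit = s_A^2 + r*s_I^2`,
`MS_subj = s_A^2 + r*s_I^2 + r*v*s_G^2`, method of moments), in one of two
modes:

- **CV-ANOVA**: results scaled by each subject's mean, so within-level
  components read directly as squared CV fractions; the between-subject CV
  comes from the relative variance of raw subject means minus the
  within-contribution `(CV_I^2+CV_A^2)/(v*r)`;
- **ln-ANOVA**: components on natural-log values, converted by
  `CV = sqrt(exp(s^2) - 1)`.

The two modes agree within ~5% for CVs up to ~15%, where both
approximations hold. Designs missing more than 20% of cells are refused
(the decomposition assumes near-balance). Negative method-of-moments
between-subject components are truncated to zero with a warning. CV_A is an
input from quality-control data unless replicates allow estimating it; the
within-subject CV is always reported net of CV_A. The population mean is
taken as supplied (typically the routine-data population fit
back-transformed) or defaults to the study grand mean.

Conversion to PEB parameters is on the natural-log scale, where
proportional (constant-CV) variation becomes additive:
`sigma_I^2 = ln(1 + (CV_I^2 + CV_A^2)/1e4)`, `sigma_G^2 = ln(1 +
CV_G^2/1e4)`, `b1 = sigma_G^2/(sigma_G^2 + sigma_I^2)`. Analytical noise is
folded into the within-subject component because routine results contain it.

## Evaluation modes

`flag_series` judges each result of a subject's series under one of five
families: `ri_pop` (fixed population interval, the n = 0 case), `rcv_pair`
(baseline = previous result, n = 1), `ri_per_dynamic` (n grows with each
result; the first result is evaluated at n = 0 so every result is evaluable
and denominators match across modes), `rcv_ln_formula` (classical lognormal
RCV from CV_I and CV_A, centered on the previous result) and `rcv_ratio`
(empirical 2.5/97.5 percentile band of result ratios, calibrated once on a
separate pair set and then applied). Reports carry per-subject flag counts
and the overall flagged percentage.

## Synthetic cohorts

The generator draws exactly the hierarchical model above on the working
scale (log by default; Box-Cox by exponent), using one seed sequence with
independent per-subject sub-streams, so cohorts are bit-reproducible and
individual subjects stable under config edits. Defaults emulate a designed
biological-variation study: 30 subjects, 10 weekly visits collected
08:00–10:00, albumin-like CVs (CV_G 6.0%, CV_I 2.3%, CV_A 1.8%, mean 4.522
g/dL). On top it can layer: a persistently shifted pathological subgroup
(set-point shift, default 4 population SDs — persistent shifts are what
threaten population fits; transient spikes are a separate option used for
robust-regression tests), censoring below a reporting limit (censored
results are labelled and excluded by default readers), collection times
scattered across the day (so the diurnal filter has something to do), and a
heteroscedastic subgroup whose within-subject SD is multiplied by a factor.
CVs map to working-scale SDs via `ln(1 + CV^2/1e4)` on the log scale and by
the delta method (`sigma ≈ (CV/100)*mu^lambda`) on a Box-Cox scale.

What passing tests on these cohorts do *not* show: real serial results have
drifting set points, seasonal and circadian structure, autocorrelation
beyond the 24-h spacing rule, non-Gaussian tails after transformation, and
CV_I heterogeneity across patients. The heteroscedasticity failure-mode test
probes exactly the last point: inflating CV_I threefold for half the cohort
while evaluating with common-CV parameters raises the dynamic flag rate from
~5% to well above 10% — a reminder that locally verifying calibration is
part of deploying personalized intervals, not an optional extra.

## Numerical choices and problem sizes

- Box-Cox at exponent 0 is the exact log branch, never a small-exponent
  approximation; transform round-trips are identities to 1e-10 relative.
- Degenerate inputs fail loudly: non-positive values under a log/Box-Cox
  scale name the offending value; constant series, zero-variance baselines
  and empty tables raise typed errors.
- The calibration suites use 300 seeded replicates of 30 × 10 cohorts per
  parameter set (mean flag rate within 3 binomial SEs of 5%); the
  acceptance script reports 100 replicates per target. Pipeline-recovery
  tests use 2500 subjects × 3 visits (5000 pairs); robustness-dominance
  tests use 100 replicates of 400-subject cohorts with 15% contaminated
  pairs. These sizes make sampling error small relative to the asserted
  tolerances while keeping the default suite fast.
- All randomness flows from explicit seeds; identical input and seed give
  bit-identical parameters, cohorts and reports.

## Known limitations

- A common CV_I across patients is assumed; heteroscedastic analytes
  (e.g. cortisol-like behaviour) over-flag, as the failure-mode test shows.
- The central-peak fit identifies the Box-Cox exponent only up to the
  bulk-parametrization trade-off discussed above.
- The central-99% filter attenuates the slope slightly; at extreme
  intraclass correlations combined with heavy censoring the ±0.05 recovery
  margin could be consumed.
- Bootstrap CIs for the slope and the CV CIs are constructions of this
  package; published tables built from other CI methods are not directly
  comparable.
- No age/sex partitioning beyond a pass-through subgroup column, no set
  point drift modelling, and no multi-analyte joint thresholds.
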