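# Methods

This note documents the models, the synthetic generator, the numerical
choices behind the state-space comparison, and what the validation studies
do and do not establish.

## Behavioral model

Go finishing times are ex-Gaussian,
`RT = N(μ + Δ·[task = SST] + πc, σ) + Exp(τ)`, with defaults μ = 230 ms,
σ = 30 ms, τ = 55 ms (so the Go-only PA mean is μ + τ = 285 ms), proactive
slowing Δ = 100 ms in the stop-signal context, and a per-coil RT penalty
πc (0 for PA₁₂₀, 20 ms for AP₃₀ — TMS pulse parameters differ between coil
orientations and delay responses slightly). Between participants these means
vary normally (e.g. μ ~ N(230, 30), Δ ~ N(100, 25), SSRT ~ N(220, 20)).
These values are anchored to the published group behavioral table of the
experiment the pipeline targets; σ and τ are the package's choice of a
realistic within-subject split of simple-RT variability.

Stop trials follow the independent horse race: the response escapes
inhibition iff `go RT ≤ SSD + SSRT`, with SSRT constant per participant by
default (optional Gaussian jitter via `ssrt_sd_ms`). A tie counts as a
response; ties have measure zero under continuous RTs and the convention
fixes determinism. The SSD staircase starts at 150 ms and moves ±50 ms per
stop outcome within [100, 250] ms; updates at a bound clip rather than wrap
or terminate, which keeps the tracker well-defined.

Two properties of this tracking design matter for interpretation:

- **Bound pinning.** A participant's 50% point is `median go RT − SSRT`.
  When parameter sampling puts it outside [100, 250] ms the staircase sits
  at a bound and long-run inhibition is not 50% for that participant (the
  same effect that makes real per-coil inhibition rates deviate from 50%).
  The tracker-convergence study therefore uses the canonical parameters,
  for which the PA equilibrium is ≈48.6% and the AP equilibrium ≈51.3%
  (discreteness of the four-level SSD grid), averaging to ≈50%.
- **Start transient.** Over only 35 stop trials the 150 ms start biases the
  mean SSD toward 150, which inflates mean-method SSRT by ~5–15 ms on top
  of the method's inherent skew bias (mean > median of ex-Gaussian RTs).
  Estimator-recovery studies therefore discard a burn-in
  (`simulate_stop_trials(..., burn_in=...)`) so the staircase is sampled at
  convergence; the protocol-faithful estimate reported by
  `summarize_behavior` retains the transient, as any real 35-trial block
  does.

## Excitability model

A trial's MEP amplitude is `baseline × g(t_rel) × ε`, where
`t_rel = RT − TMS time` is the lead time before the response and ε is
lognormal with unit median (so the median normalized amplitude is exactly
the gain; the mean is `gain·exp(s²/2)` with `s² = ln(1 + CV²)`, CV = 0.5
by default). The ramp g equals 1 for `t_rel ≥ 150 ms`, rises linearly
(logistic optionally) and plateaus at a coil-specific gain (defaults 3.0
for PA₁₂₀, 2.4 for AP₃₀) at the response. Baseline (catch) trials and
non-responding trials use g = 1. Because g is locked to the response, the
SST's slower RTs delay the cue-locked rise by the RDE while response-locked
profiles stay identical across tasks — the qualitative signature of
proactive inhibition operating by delaying the trigger to move rather than
slowing the rise itself. An optional per-task gain override
(`rise_gain_sst` / `sst_gain_scale`) plants a task-dependent PA/AP
weighting for sensitivity studies.

What the generator does **not** emulate: trial-history effects (post-stop
slowing), stop-trial MEP dynamics (stop-trial MEPs are generated but never
analyzed, mirroring the analysis), genuine EMG physiology beyond a biphasic
MEP and a noise burst, pre-TMS background-EMG screening, or visual-inspection
preprocessing. Passing tests therefore certify the analysis chain's
statistical behavior under a plausible data-generating process, not the
biology of any particular dataset.

## Preprocessing rules

Omissions: go trials with RT > 1,000 ms (strictly) or no response. Burst
exclusion: TMS at or after the EMG burst onset; for tabular data the onset
is `RT − 50 ms` (configurable `motor_time_ms`); for traces a threshold
detector (rectified signal > k·baseline SD sustained ≥ 5 ms, k = 3) stands
in for visual inspection. Response-locked lead times are binned half-open
[lower, upper); leads outside [50, 350) ms are excluded (`out_of_range` —
a lead under 50 ms implies TMS inside the burst given electromechanical
delay). Baseline normalization divides by the participant × coil mean of
catch-trial MEPs; a participant without a positive baseline for a coil is
dropped for that coil with a logged reason. Bins with fewer than 2 trials
are dropped from trajectories and bootstrap pools (one trial defines no
state estimate). Mean SSD uses all presented stop trials by default (the
mean-method convention); `ssd_scope="successful"` is available.

## State-space comparison and its null

Per participant, task and alignment, the binned PA and AP means form a
trajectory; per-bin Euclidean and cosine distances compare the SST and
Go-only trajectories ("real" arm). The "simulated" arm estimates what those
distances would be if both tasks shared one law, using only Go-only trials.

The default null construction (`mode="split"`) randomly partitions each
participant × coil × bin pool into two disjoint halves. Marginally the two
half-means are means of independent samples from the bin's true
distribution — no plug-in scale estimate is involved — and their difference
is rescaled by the known factor
`λ = sqrt((1/n_SST + 1/n_Go)/(1/n₁ + 1/n₂))` so its sampling variance
equals that of the real pair of per-task bin means (the SST arm's per-bin
counts are matched via `match_counts`). Design history, for the record:

- Comparing one resample against the original trajectory (`vs_original`)
  underestimates null distances by ~√2 (variance σ²/n instead of 2σ²/n).
- Two with-replacement resamples (`resample`) match the variance after a
  `sqrt(n/(n−1))` rescale but keep a distribution-shape-dependent shortfall
  in E[distance] (the resampled SD's expectation is below σ by a factor
  that depends on kurtosis), which no single scale correction removes for
  mixture-shaped bins.
- Re-partitioning the pooled trials of both tasks (`permute`) is exactly
  calibrated in every moment but loses essentially all power: under a true
  task difference the pooled cells absorb the effect into the null.

For the mixed model the simulated arm enters as **one** replicate per
participant × bin (`summarize="single"`): averaging over replicates smooths
only the simulated arm, and any concave transform (the log below) then
separates the two arms under the null. Replicate means
(`summarize="mean"`) remain available for plots and summaries, and
`summarize="full"` keeps every replicate.

The distance model is `distance ~ TIME * ANALYSIS_TYPE` with a participant
random intercept, fitted by REML with Wald chi-square tests per term on
**sum-to-zero contrasts** (so each term's test is marginal, the type-III
convention of the R mixed-model ecosystem). Distances are positive,
scale-like quantities whose dispersion grows with their mean, so the
distance models log-transform by default; raw-scale distances are
heteroscedastic across time bins and the marginal contrast is then
anticonservative under a homoscedastic model.

Measured operating characteristics (Monte Carlo, 16 participants,
full-size blocks): the Euclidean ANALYSIS_TYPE comparison rejects at 5.0%
and 4.5% in two independent 200-repetition null runs, and an oracle check
(simulated arm replaced by a genuinely independent Go-only-law block)
rejects at exactly 5.0%. The cosine comparison is also near-nominal under
the null, but its absolute power against plantable PA/AP weighting
differences at these trial counts is low (~10–20% even when the SST's AP
rise is removed entirely); the sensitivity of the cosine comparison is
therefore validated directionally (mean log-ratio of real to simulated
cosine distances > 0 under planted weighting) rather than as a rejection
rate. Users should read single-experiment cosine (and marginal Euclidean)
p-values with that power in mind.

## Inference details

Mixed models use statsmodels MixedLM (REML; lbfgs with powell/cg retries;
non-convergence is flagged on the result, and degenerate covariance falls
back to manually assembled per-term Wald statistics). The normality rule is
an automated surrogate for QQ inspection: log-transform iff the OLS residual
skewness of the fixed-effects structure exceeds 1.0 (configurable) and the
response is strictly positive. Tukey family correction for paired contrasts
uses the studentized-range distribution (q = |t|·√2 with the timepoint
family size); Bonferroni is available as a fallback. The rise onset is the
earliest timepoint whose Tukey-adjusted paired contrast against the cue is
significant with a positive excitability difference, per task, on
participant bin means averaged over coils.

## Problem sizes used by the validation studies

Type-I calibration: 200 repetitions of a full-size experiment (16
participants × 2 coils × 2 tasks, 105 go trials, 15 MEPs/timepoint) with
single-replicate nulls. Signature recovery: 15 repetitions of the default
generator. Tracker convergence: 2,000 stop trials per participant × coil.
Sensitivity: 6 repetitions with the SST's AP rise removed. These counts
balance Monte-Carlo precision against the cost of re-simulating complete
experiments and are the package's standing choices.

## Known limitations

- The mean-method SSRT inherits the skew bias of ex-Gaussian RTs and the
  staircase's start transient; both are documented above rather than
  corrected, because the estimator is defined by the published procedure.
- The bootstrap null is variance-matched per cell but cannot reproduce
  every higher-order moment of the real distances at very small per-bin
  counts; the burst-exclusion rule thins late cue-locked bins most (mean
  Go-only RT ~285 ms leaves few analyzable 250/300 ms MEPs), exactly where
  distances are largest.
- The automated preprocessing rules (burst detector, skewness rule) are
  codified stand-ins for visual inspection and should be recalibrated
  before use on real recordings.
- With the default generator the response-locked trajectories are equal
  across tasks by construction, so response-locked distance comparisons are
  null; only cue-locked distances carry the proactive-inhibition signal.
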