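# Methods

## The observer model

All simulated decisions come from equal-variance Gaussian signal detection.
For temporal interval discrimination (TID), a trial presents a standard
(100 ms) and a comparison (100 + Δt ms) interval in random order; each
interval is perceived with additive Gaussian noise of standard deviation
σ_m (ms), so the probability of reporting the comparison longer is

    P(Δt) = (1 − λ) · Φ(Δt / (σ_m √2)) + λ/2,

with lapse rate λ (default 0.02, range [0, 0.1]).  The √2 arises from
comparing two independently noisy percepts.  The effective modality noise
decomposes into a supramodal (central) and a modality-specific component,

    σ_m = scale_m · gain_m · √(σ_central² + σ_m,specific²),

with defaults σ_central = 12 ms, σ_aud = 10 ms, σ_vis = 29 ms.  These give
lapse-free thresholds (half interquartile range of the probit,
0.6745·σ_m·√2 ≈ 0.954 σ_m) of ≈14.9 ms auditory and ≈29.9 ms visual — the
≈2:1 precision ratio characteristic of the two modalities.  `scale_m` is a
static per-subject factor (log-normal, log₁₀ SD 0.15) generating log-normal
between-subject threshold variation; `gain_m` is the learning state.

Tone frequency discrimination uses the same 2IFC architecture with noise SD
`freq_jnd` (Weber fraction, default 0.05) on log frequency.  The contrast
same–different task draws a unit-variance internal difference signal with
mean 0 (same) or `contrast_sens` (different) and an unbiased criterion at
`contrast_sens`/2, so the recoverable d′ equals `contrast_sens`
(default 1.2).

## Learning and transfer

The model is a *calibration* of the published effect structure, not a
mechanistic claim — no generative observer model accompanies the behavioral
literature this emulates.  Learning acts multiplicatively per training
session on the trained task's noise:

* TID training in modality m: `gain_m ← gain_m (1 − ρ_m)` with per-session
  rate ρ chosen so five sessions produce the calibrated trained-task
  improvements, 0.30 log₁₀ units auditory (ρ_aud = 1 − 10^(−0.06) ≈ 0.129)
  and 0.20 log units visual (ρ_vis ≈ 0.088).
* The untrained modality m′ receives `gain_m′ ← gain_m′ (1 − ρ_m)^g`, where
  the direction-specific gate g ∈ [0, 1] is the fraction of the trained
  log-threshold improvement expressed cross-modally.  Single training:
  g_av = 0.40 (audition→vision, giving the calibrated 0.12 = 0.4 × 0.30
  partial transfer — 60% of the 0.20 direct visual training effect) and
  g_va = 0 (no vision→audition transfer).  Double training opens the
  relevant gate to 1: the untrained modality expresses the full trained
  log improvement, the signature of a conceptual, precision-standardized
  supramodal representation (expected transfers 0.20 vis→aud and 0.30
  aud→vis, i.e. "complete" relative to direct training, which is how the
  behavioral claim is framed).
* Frequency-discrimination practice shrinks `freq_jnd` by
  1 − 10^(−0.17/4) ≈ 0.093 per session (0.17 log units over the observable
  4-step span between the first and last training session); contrast
  practice adds 0.21 to `contrast_sens` per session (0.84 d′ over the same
  span).  Orthogonal-task practice alone never touches the TID gains.

Per-subject heterogeneity: learning rates jittered with relative SD 0.3
(truncated to [0, 0.45]), threshold scales and `freq_jnd` log-normal
(log₁₀ SD 0.15), `contrast_sens` log-normal (SD 0.1).

## Procedures

* **Constant stimuli (TID).**  Six signed Δt levels (auditory ±6.7, ±13.4,
  ±20.1 ms; visual ±6.7, ±20.1, ±33.5 ms), 10 repetitions per level per
  60-trial block, 5 blocks per threshold estimate; presentation order a fair
  coin per trial.  The level set is scaled once per subject by the subject's
  baseline scale factor before the pre-test (emulating the experimenter
  widening the levels when a subject's correct rates span too little of the
  psychometric range) and held fixed thereafter; without this, subjects far
  from the default range produce heavy-tailed threshold estimates.
* **Staircase (FD).**  Start Δf = 0.50; divide by 2 after every correct
  response until the first error; thereafter 3-down-1-up with factor 1.414
  (down after 3 consecutive correct, up after each error, streak reset on
  every level change and error — standard transformed up-down semantics).
  Exactly 60 trials, phase-1 trials counting toward the total; threshold =
  arithmetic mean of the last 40 levels (a geometric option exists because
  the steps are multiplicative).  The rule equilibrates where
  P(correct)³ = 0.5, i.e. ≈79.4% correct; simulated tracks land at ≈79.5%.
* **Contrast blocks (CD).**  60 trials, stratified 48 same / 12 different;
  same-trial contrast uniform on [0.15, 1]; different pairs differ by 50%
  (c₂ = 1.5 c₁, c₁ redrawn until c₂ ≤ 1, direction randomized).  Scored by
  d′ with rates clamped to [1/(2N), 1 − 1/(2N)].
* **Sessions.**  Seven sessions: pre-test, five training sessions, post-test.
  Pre/post sessions measure every tested task with 5 constant-stimuli
  blocks.  Single-training sessions run 16 blocks of the trained task;
  double-training sessions run 10 + 10 strictly alternating blocks.
  Observer state evolves between training sessions.  FD/CD improvements are
  measured between the first and last training session; TID improvements
  between pre- and post-test.

## Estimation and statistics

The psychometric function is fitted by trial-level Bernoulli maximum
likelihood (Newton–Raphson on the two-parameter logistic; equivalent to a
logistic regression of "comparison reported longer" on Δt).  No lapse
parameter enters the fitted model, matching the two-parameter analysis
convention; the small resulting threshold bias is shared by pre and post
fits and largely cancels in the improvement scores.  The threshold is
ln 3 / k, identically half the interquartile range of the fitted curve.
Perfectly separated data (possible only for near-noiseless responders) are
flagged with the threshold reported at the smallest absolute level rather
than fitted.  A least-squares-on-proportions fallback is provided for
comparability.

Improvements are log₁₀(pre/post).  Group inference: two-tailed one-sample
t-tests (Cohen's d = mean/SD = t/√n), one-way between-subject ANOVA with
η² = SS_between/SS_total (checked against df₁F/(df₁F + df₂) to machine
precision), pairwise contrasts with the pooled ANOVA error term (Welch
variant emitted alongside, since the contrast convention of the source
analyses is ambiguous) and Bonferroni correction, Shapiro–Wilk normality
checks, and a sample-size search that iterates n from 2 using exact
noncentral-t power (no normal approximation): d = 1.34, α = 0.05,
power 0.80 → n = 7.

## What the generator does and does not emulate

It emulates: the 2:1 auditory/visual precision ratio, log-normal
between-subject thresholds, the calibrated group-mean improvements and their
condition dependence (partial asymmetric transfer under single training,
complete transfer under double training, null controls), trial-level binary
responses consistent with the logistic/probit psychometric model, and the
exact block/trial bookkeeping of the design.  It does not emulate:
within-session fatigue or warm-up, feedback-driven criterion shifts, the
900-ms inter-pair gap or fixation timing (treated as constants), individual
outliers, or any neural mechanism — passing tests validate the analysis
machinery and the calibrated effect structure, not a theory of timing.
Between-subject improvement SDs are somewhat tighter than typical human
groups because only learning-rate jitter and trial-sampling noise contribute.

## Numerical choices and limitations

* All randomness flows from `numpy.random.Generator` streams spawned per
  condition and per subject from a single seed; identical config + seed
  gives byte-identical trial logs and reports.
* Newton iterations stop at step < 1e-12 (≤100 iterations); fits with
  k ≤ 0 are refused rather than silently inverted.
* The full 49-subject, ~305k-trial replication runs in a few seconds on one
  CPU; test-suite simulations use 300–1000 replicates per property, sized to
  keep Monte-Carlo error well below the asserted tolerances.
* Replication probability of the weakest effect: the audition→vision
  single-training transfer (0.12 log units at n = 7) has subject-level
  d ≈ 1.4 once trial-sampling noise of the 300-trial threshold estimates is
  included, so its one-sample-t power — hence the probability that a full
  replication reproduces that component of the significance pattern — is
  ≈0.8 and is bounded by the design itself, not by simulation fidelity.
  The corresponding long-run pattern-rate check in the acceptance suite
  documents this honestly and fails for that single component.
* The printed-value arithmetic checks use only internally consistent
  worked examples; one published (t, d) pair is mutually inconsistent at
  the printed precision and is excluded from the checks.
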