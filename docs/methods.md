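# Methods

This note documents the models, conventions and numerical choices behind
`dyadkit`, and what the bundled simulator does and does not emulate.

## The coding model

A session is a time-ordered stream of 15 behavior codes: 13 point events,
one dyadic duration state (SA, the shared activity), and an engagement
attribute (ENG, levels 1–3) that annotates shared activities rather than
counting as a behavior of its own.  The inventory resolves an apparent
tension between "15 codes" and the code table by modeling 13 point codes
plus SA as a duration state plus ENG as a numeric attribute.

**Pairing.**  A response answers the *most recent unanswered* initiation by
the opposite partner whose valid-response set contains it.  An open
initiation is marked *ignored* as soon as a newer (non-affect) initiation
by either partner occurs, the SA state changes (start or stop), or the
window ends — whichever comes first.  There is no fixed response window by
default (`max_latency_s` is available).  Affect codes (CD→TR) are paired on
a separate channel so that inserting or deleting them never perturbs
interaction pairing — a tested invariant.  Two initiations at the same
timestamp are ordered by input row order, deterministically.

**Interaction units and shared activities.**  An IU is a successful
outside-SA exchange of type TP-CA, CI-TI or CP-TA.  Each SA is credited to
the *latest* IU whose response precedes its start (none intervening, by
construction).  A terminator (CX/CE/TE) inside the span or within 2 s
after its end (configurable annotation-jitter tolerance) labels the
termination; otherwise the label is `window_end`.  Mid-codes are the point
events strictly inside the span, excluding the terminator and ENG.  TW is
treated as an in-SA widening wherever it occurs; a TW outside any SA is
paired normally and flagged in diagnostics.

## Descriptor conventions

- `N_TOT` counts every coded event including SA occurrences but not ENG
  attributes; per-code proportional frequencies therefore sum to 1.
- `P_CA`-style proportions use `N_TOT` as the denominator.
- `CPM` divides by the *actual* coded window length, not a nominal value.
- `R_SYNC = n_sync / n_pairs` counts every non-affect initiation in
  `n_pairs`; `n_sync` counts answered (accepting/recognizing) exchanges.
  Refusals are excluded by default (`include_refusals` flag) — a refusal
  acknowledges the bid without attuning to it.  Affect pairs (CD-TR) are
  excluded from both counts.
- `SR_UDI` divides CA event counts by TP+TW event counts regardless of
  context.
- `ENG` is the unweighted mean of per-SA mean engagement levels
  (duration-weighting available via a flag).
- Any descriptor whose denominator is zero is `None` — missing values
  propagate, they are never coerced to 0.

## Reliability

Per-code count reliability uses ICC(A,1) (McGraw & Wong): the
single-measure, two-way, absolute-agreement intraclass correlation,

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),

with the one-sided test of H₀: ρ ≤ ρ₀ based on
F\* = MSR/(a·MSC + b·MSE), a = kρ₀/(n(1−ρ₀)),
b = 1 + kρ₀(n−1)/(n(1−ρ₀)), df1 = n−1 and a Satterthwaite (fractional)
denominator df.  The "absolute agreement" reading is anchored to the
fractional denominator degrees of freedom this test produces on the
10-video, two-coder design; a consistency ICC would not produce them.
Zero-variance rating matrices are reported as ICC = 1 with a degenerate
flag.  Stream alignment for κ is greedy nearest-in-time bipartite matching
within a 2 s tolerance (code-agnostic); unmatched events enter the
confusion matrix against a `nil` margin.  Event-aligned κ is the default;
per-code κ is one-vs-rest on the full matrix.

## Inference

Differences are screened with Shapiro–Wilk at α = 0.05 (Levene across
groups when applicable); the paired *t* on differences is used when the
gate passes, otherwise the Wilcoxon signed-rank test (V = sum of positive
ranks), exact for n ≤ 25 without zero differences and otherwise the normal
approximation with continuity correction and tie-corrected variance.  The
"paired Welch" phrasing sometimes seen for this design is internally
contradictory (Welch's correction applies to independent samples); the
standard paired *t* reproduces the design's df = n−1.

Effect sizes: r² = t²/(t²+df) for *t* results.  For Wilcoxon results the
convention (Z/√n)² from the standardized V is used and labeled as such; no
published formula exists for that case and the value is a convention, not
a validated reproduction.

**Bayes factors.**  The one-sample JZS BF places a Cauchy(0, √2/2) prior
on the standardized effect (the conventional paired-test default),
computed by adaptive quadrature over the mixing variable g at relative
tolerance 1e-6; it is symmetric in the sign of t and monotone in |t|.  The
correlation BF uses the exact sampling-density kernel of r with a
stretched-beta prior on ρ; the default width κ = 1/3 ("medium") was chosen
because it reproduces published values of this BF family to ~1% across a
range of (r, n) checked during development.  The regression BF is the
Zellner–Siow mixture-of-g-priors factor against the intercept-only model,
scale √2/4 for continuous covariates, also by quadrature.  Evidence labels
follow the Jeffreys bands as revised by Lee & Wagenmakers (1–3 anecdotal,
3–10 moderate, 10–30 strong, 30–100 very strong, >100 extreme; mirrored
below 1).

## Model selection

All 2^p − 1 subsets (p ≤ 20 hard cap) are scored by their regression BF;
the maximal-BF subset is pruned for multicollinearity: take the top-VIF
predictor X1, find its most correlated partner X2, drop X1 if the design
without it brings VIF(X2) ≤ 4, otherwise drop whichever of the pair is
most correlated with any third predictor; iterate until max VIF ≤ 4.
Backward elimination then iteratively refits and drops the highest-p
predictor with p ≥ 0.1.  BIC uses the Gaussian-MLE convention
−2·logLik + log(n)·(p+2) (intercept, slopes and error variance all
counted), which is ranking-equivalent to n·ln(RSS/n) + (p+2)·ln(n).

RF-based RFE runs 5-fold CV repeated 10 times; within each training
resample predictors are ranked by permutation importance and nested
subsets are scored on the held-out fold (RMSE, R², MAE).  The chosen size
is the smallest whose mean RMSE is within 5% of the best.  Forest
hyperparameters are fixed: 500 trees, ⌊p/3⌋ features per split, minimum
leaf 5; all resample indices derive from the supplied seed.

## The synthetic cohort

The generator is a semi-Markov event process: competing exponential clocks
for outside-SA initiations; Bernoulli responses after log-normal latencies;
successful IUs launch an SA with fixed probability after an exponential
delay; SA durations are log-normal; interior widenings arrive at an
exponential rate and are accepted with fixed probability; termination codes
and ENG levels are categorical draws; streams truncate at the window end.
Distributional families are modeling choices — only means/SDs of the
emulated condition are constrained — and the T0 defaults and T1 shifts
were moment-matched (to within a few percent on most descriptors) to the
baseline and post-intervention condition of a 24-dyad, 20-minute-session
early-intervention cohort.  One residual, structural mismatch is R_SYNC:
the emulated condition's printed overall synchrony rate exceeds the value
implied by its own printed component success rates, so the generator
reproduces the components (SR_TPCA, SRTWCA_SA, SR_CITI) and the T0→T1
direction of R_SYNC rather than its absolute level.

Each dyad draws a persistent parameter offset (its interaction style)
shared by both timepoints, giving realistic between-dyad descriptor spread
while paired contrasts cancel it.  Simulated outcomes (rMC, LR, ADOS-SA)
are linear in the dyad's true parameters plus Gaussian noise.

What the simulator does *not* emulate: therapist turnover, within-session
nonstationarity (fatigue, warm-up), annotation errors and coder
disagreement, overlapping or nested activities, and any dependence of
response probabilities on history.  Passing calibration/recovery tests
therefore demonstrate that the pipeline is correct under the stated
generative assumptions, not that real sessions satisfy them.

## Numerical choices and problem sizes

- Quadratures: `scipy.integrate.quad`, relative tolerance 1e-6; failures
  raise rather than degrade silently.  Test oracles use dense-grid Riemann
  sums on the compactified variable u = g/(1+g).
- Degenerate inputs: all-zero paired differences, zero-variance rating
  matrices, single-category confusion matrices and zero-variance targets
  are warnings or typed errors, never NaNs.
- Tie-breaks are deterministic everywhere (input row order for equal
  timestamps; smallest-|Δt|-first, then time, then row order in
  alignment).
- Test problem sizes: pairing oracle on 500 random streams of ≤30 events;
  type-I calibration on 2000 zero-shift cohorts of 24 dyads; contrast-sign
  recovery on 100 shifted cohorts; model-support recovery on 100
  synthetic-regression replicates (n = 48, 4 true of 8 candidates); RFE
  unit tests use reduced forests (30–150 trees, 2–3 repeats) while the
  library default remains 500 trees × 5×10 CV.

## Known limitations

- The correlation-BF prior width is a convention; published values of this
  family were reproduced to ~1% but one published comparison point differs
  by ~4%, consistent with rounding of the printed r.
- The Wilcoxon effect-size convention (Z/√n)² is not validated against any
  published value (none is derivable).
- `expected_code_mix` is exact only when accepted widenings are disabled;
  otherwise interior counts use a renewal approximation, and window
  truncation is ignored in all cases (long-window limit).
- The sequencer assumes non-overlapping shared activities and rejects
  overlap instead of resolving it.
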