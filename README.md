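# dyadkit

Quantitative micro-coding of dyadic child–therapist interaction for early
autism-spectrum intervention research.

Observational studies of naturalistic developmental behavioral intervention
annotate video-recorded play sessions with a time–event code inventory: the
therapist proposes (TP) or widens (TW) an activity, the child accepts (CA),
refuses (CR) or ignores; the child signals intentionality (CI) that the
therapist may catch (TI); successful initiation–response pairs (interaction
units, IUs) can launch a *shared activity* (SA) — a sustained, reciprocal
interplay state carrying a child-engagement level (ENG ∈ {1,2,3}) and
ending either by therapist/child closure (TE/CE) or unilateral child
withdrawal (CX). `dyadkit` turns such annotation streams into quantitative
session descriptors and runs the statistics that this study design needs.

The package provides:

- **`dyadkit.ethogram`** — the 15-code inventory, session data model, and a
  BORIS-style tabular annotation dialect (`read_events` / `write_events`),
  plus developmental outcome indices: rMC = MA/CA (mental over chronological
  age) and the learning rate LR = ΔMA/Δt (LR = 1 ≙ typical pace).
- **`dyadkit.sequencer`** — pairing of initiations with responses
  (most-recent-unanswered rule), interaction units, shared-activity
  segmentation with termination labels, synchrony counting and
  sparsity screening (drop codes with SD > mean across sessions).
- **`dyadkit.descriptors`** — the full session indicator vector: counts
  (N_TOT, N_SYNC, N_UDI), proportions (P_CA, P_CX, P_SA), IU-type and
  success rates (R_TPCA, SR_TPCA, R_SYNC, SR_UDI, …), latencies and
  durations (LATENCY_TPCA, LATENCY_SA, DURATION_SA, …), interaction
  complexity (N_BETWEEN_SA), code rate (CPM) and mean engagement (ENG).
- **`dyadkit.reliability`** — inter-coder stream alignment, Cohen's κ, and
  the single-measure two-way absolute-agreement intraclass correlation
  ICC(A,1) with a one-sided test against a non-zero null ρ₀
  (F\* = MSR/(a·MSC + b·MSE), Satterthwaite fractional df).
- **`dyadkit.inference`** — Shapiro–Wilk/Levene gating, paired *t* /
  Wilcoxon signed-rank comparisons, effect size r² = t²/(t²+df), Pearson
  tests, and default Bayes factors by quadrature: the JZS (Cauchy-prior)
  *t*-test BF and a stretched-beta-prior correlation BF.
- **`dyadkit.modeling`** — Zellner–Siow all-subset regression BF selection,
  VIF-based multicollinearity pruning (threshold 4, pair rule at r = 0.600),
  backward elimination at p ≥ 0.1, OLS diagnostics (F, RSE, adjusted R²,
  BIC, Cook's distance, Durbin–Watson), and random-forest recursive feature
  elimination under 5×10 repeated cross-validation with a 5% RMSE
  parsimony tolerance.
- **`dyadkit.synthetic`** — a semi-Markov session generator and paired
  T0/T1 cohort simulator with known ground truth, so every stage is
  testable without clinical recordings.
- **`dyadkit.cli`** — `dyadkit simulate | extract | reliability | compare |
  model`.

## Worked example

```python
import numpy as np
from dyadkit import (SessionRecord, AnnotatedEvent as E,
                     compute_descriptors, jzs_ttest_bf, effect_size_r2)

session = SessionRecord("demo", [
    E(0, "TP"), E(3, "CA"),                      # proposal accepted after 3 s
    E(5, "SA", stop_s=100),                      # shared activity, 95 s
    E(60, "TW"), E(63, "CA"), E(100, "CX"),      # widening accepted; child exits
    E(120, "CI"), E(122, "TI"),                  # intentionality caught
    E(125, "SA", stop_s=300),
    E(200, "ENG", modifier=1), E(250, "ENG", modifier=2),
    E(300, "TE"),                                # therapist closes
], window_len_s=600)

d = compute_descriptors(session)
print(d.n_tot, d.n_udi, d.p_ca, d.r_sync, d.duration_sa, d.eng)
# 10 2 0.2 1.0 135.0 1.5

t = 2.669                      # paired-t statistic for a 24-dyad contrast
print(round(effect_size_r2(t, 23), 3), round(jzs_ttest_bf(t, 24), 3))
# 0.236 3.72
```

The session contains 10 coded events, 2 successful interaction units, a
child-acceptance proportion of 0.2, perfect initiation–response synchrony,
a mean shared-activity duration of 135 s and mean engagement 1.5.  The last
line converts a paired *t* statistic into its variance-explained effect
size and its default Bayes factor: r² = 0.236, BF₁₀ ≈ 3.7 (moderate
evidence for a change).

A full pipeline on synthetic data:

```sh
dyadkit simulate --seed 1 --n-dyads 24 --out cohort/
dyadkit extract cohort/ --out descriptors.csv
dyadkit compare descriptors.csv --out contrasts.csv
dyadkit model descriptors.csv cohort/outcomes.csv --target rMC --out model.json
```

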