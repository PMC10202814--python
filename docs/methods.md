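# Methods

This note documents the modelling choices, defaults and known limitations of
`trajrisk`, in the spirit of a model-description appendix.

## Problem setting

The package predicts occurrence of a low-incidence cancer within incremental
horizons (3, 6, 12, 36, 60 months) after an *assessment date*, from the
time-ordered sequence of level-3 ICD diagnosis codes recorded up to that
date. The unit of training and evaluation is the **partial trajectory**: a
contiguous prefix of a patient's history ending at an assessment date. Using
every prefix of length ≥ 5 as a separate sample both augments the data and
forces the model to learn from assessments made long before diagnosis, not
only from the symptom-laden months just before it.

## Cohort construction

- **Eligibility.** Patients need at least 5 admissible events. For cancer
  patients an endpoint is admissible iff it is strictly before the cancer
  diagnosis; for controls iff it is at least 24 months before the end of
  their records. The control buffer guards against contaminating the
  negative class with patients whose undiagnosed cancer surfaced just after
  their records end.
- **Labels.** yₜ = 1 iff the cancer date falls within t calendar months of
  assessment (calendar-month addition with day-of-month clamping; a fixed
  30-day month would drift by nearly two months over the 60-month horizon).
  Labels are therefore non-decreasing step functions of t.
- **Loss masking.** The per-sample normalizer N_T counts unmasked horizons:
  5 for controls, ≤ 5 for cancer trajectories. For cancer trajectories the
  default convention (`mask_mode="first_positive"`) keeps every pre-diagnosis
  horizon (label 0) and the first horizon covering the diagnosis (label 1),
  masking longer horizons: each cancer trajectory then contributes every
  informative negative and exactly one positive, and never trains on
  horizons entirely past the diagnosis. The alternative reading — all five
  horizons unmasked — is available via `mask_mode="all"`.
- **Exclusion windows.** `apply_exclusion_window` deletes a cancer patient's
  events in [cancer − k months, cancer) for k ∈ {3, 6, 12}; controls are
  untouched. Exclusion precedes the length filter, so heavily excluded
  patients can drop out of the cohort entirely. The event sets nest:
  12-month exclusion ⊆ 6 ⊆ 3 ⊆ 0. When two exclusion conditions are
  compared, the patient-level split is computed once on the unexcluded
  cohort and reused, so both models face the same held-out patients.
- **Splits.** Train/dev/test = 80/10/10 at the patient level; all of a
  patient's trajectories share a split.
- **Balanced batches.** Each training batch holds ⌈b/2⌉ cancer and ⌊b/2⌋
  control trajectories; the minority class is resampled with replacement.
  One epoch covers the negative class once (capped by `batches_per_epoch`).
- **Time-to-cancer** is reported in mean months (days / 30.4375). At bin or
  horizon edges this can disagree with the calendar-month label arithmetic
  by less than a day; the labels are authoritative.

## Model

- **Embedding.** Tokens are (system, level-3 code) pairs — codes from
  different ICD revisions are distinct tokens, never semantically merged.
  Embedding dim default 24; the padding index embeds to zero and is frozen.
- **Temporal encoding.** For each event, cos(u/Tₖ) is evaluated for u = age
  at diagnosis (in days) and u = gap since the previous event (days), over
  128 periods Tₖ geometrically spaced between 1 day and 36,500 days (~100
  years) — clinically meaningful scales from day-resolution visit patterns
  to lifetime age effects. The 256 features are linearly projected to the
  embedding dimension and combined **multiplicatively** with the token
  embedding (weight projection initialized near identity: small weights,
  unit bias). An additive variant is available (`temporal_mode="additive"`),
  since the attention-literature convention this adapts is additive; the
  multiplicative default follows the "weights for each disease token"
  reading. `temporal_mode="none"` gives a purely order/content-based model.
- **Encoders.** `bag_of_codes` (masked mean pooling; order-invariant, no
  temporal weighting by construction of its head), `mlp` (pooling + one
  feed-forward layer), `gru` (final hidden state, default 1 layer × 32
  units), `transformer` (multi-head self-attention stack with residuals,
  masked-mean pooled; no layer normalization at these widths). Padding
  positions contribute nothing in any architecture.
- **Head.** Fingerprint ⊕ age-at-assessment (scaled by 1/110 years) → one
  hidden layer → 5 logits → sigmoid. `bag_of_codes` uses a single linear
  layer. With `monotone_head=True` the logits accumulate softplus
  increments, guaranteeing p̂₃ ≤ p̂₆ ≤ … ≤ p̂₆₀. The default is OFF: the
  target step function is monotone, but monotonicity of the *score* is left
  to the data rather than imposed, and the per-horizon evaluation does not
  require it.
- **Loss.** Masked cross-entropy normalized per sample by N_T, averaged over
  the batch, plus λ₂‖Θ‖₂ — the L2 *norm* of all parameters, not its square,
  matching the printed objective; the decomposition loss(λ₂) − loss(0) =
  λ₂‖Θ‖₂ holds exactly. Probabilities are clipped to [1e−7, 1 − 1e−7]
  before the logs.
- **Optimization.** Adam (lr 1e−3 default), early stopping on development
  AUPRC at the 36-month horizon (patience 5), best checkpoint restored.
  The selection metric, horizon and optimizer are package defaults — the
  kind of detail a methods section rarely pins down — and are configurable.
  Trajectories longer than `max_seq_len` (default 300) keep their most
  recent events. All randomness flows from a single integer seed; training
  histories are bitwise reproducible on a fixed machine.
- **Numerics.** Forward and backward passes run on a small reverse-mode
  autodiff engine over float64 NumPy arrays (`trajrisk.autodiff`). Gradients
  are exact (verified against finite differences to 1e−4 relative); there
  is no stochastic rounding, so determinism is trivial.

## Evaluation

Per prediction interval h: a trajectory is a positive iff its cancer
diagnosis falls within h months of assessment. AUROC uses the ties-at-half
convention; AUPRC is step-wise (non-interpolated) average precision.
Bootstrap CIs use 200 resamples with replacement (percentile 2.5/97.5);
single-class resamples are redrawn up to 10 times, then counted as failures
(> 50% failures aborts). RR(n) = precision of the top-n set / incidence;
ties at the cut are broken by stable score-descending order, so RR is
deterministic. RR(all) = 1 exactly and RR ≤ 1/incidence everywhere. The F1
operational point is found by exhaustive sweep over distinct scores, ties
resolved toward the lowest threshold. Evaluation is trajectory-level by
default (performance numbers are computed over trajectories); a
patient-level mode (max score per patient) is provided for
surveillance-style accounting. The `surveillance_scenario` helper does the
program-design arithmetic: flagging top-n of a cohort at a given PPV yields
round(n × PPV) expected true positives.

## Attribution

Integrated gradients with respect to the **output of the embedding layer**
(gradients cannot flow into integer token indices), for the 36-month output,
along the straight path from a zero-embedding baseline (the age channel is
interpolated from a zero baseline simultaneously). The path integral uses a
midpoint Riemann sum, default 128 steps; all steps are evaluated as one
batch, one backward pass. Per-event scores sum the per-dimension
attributions over embedding dimensions; completeness (attributions sum to
F(x) − F(baseline)) holds within 1% at 128 steps and tightens with more.
Cohort-level tables sum raw signed scores per (token, time-to-cancer bin)
over cancer trajectories — bins 0–6, 6–12, 12–24, 24–36 months by default —
with a per-occurrence normalized view alongside, since either convention is
defensible for ranking features.

## Synthetic cohorts

The generator emulates the statistics that matter to this pipeline, not
real nosology:

- **Regimes.** `dk_like`: median ~22 codes over ~23 years of observation
  (long, sparse national-registry histories); `va_like`: median ~188 codes
  over ~12 years (short, dense EHR histories). Event counts are
  Poisson–lognormal mixtures; spans lognormal around the regime median.
- **Background codes** follow a Zipf-like popularity law (exponent 1.2)
  over a 200-token vocabulary.
- **Cancer onset** follows a discrete monthly hazard h_m = h₀ ×
  ∏(multipliers of risk codes present by month m); h₀ is set so a code-free
  patient observed for the regime's median span reaches the configured
  baseline incidence (default 0.05%), which with the default planted risk
  codes (four codes, multipliers 15/15/8/8, carried by 8% of patients each,
  planted in the first 60% of observation) lands overall incidence near
  0.3% — the low-incidence regime the evaluation machinery assumes.
  Configs implying > 5% expected incidence are rejected.
- **Late-symptom codes** (three, by default) are emitted only within ~6
  months before onset — the prodrome that data exclusion removes. A
  reserved cancer code is written at the diagnosis date, and records end
  1–12 months after diagnosis.
- Identical config + seed ⇒ byte-identical output files.

What passing tests on these cohorts shows: the pipeline can recover planted
multiplicative risk structure and lead-time profiles at realistic incidence
and trajectory shapes, and the exclusion experiment moves in the expected
direction. What it does not show: performance on real registries, whose
coding practices, administrative artifacts, censoring patterns and
correlated comorbidity structure the generator deliberately does not model.

## Experiment harness and problem sizes

`trajrisk.experiments.exclusion_experiment` runs the paired comparison
(train with and without a 6-month exclusion window, same split, same
vocabulary) on one simulated cohort and reports held-out 36-month AUROC plus
symptom-code recovery in the 0–6-month attribution bin. Default problem
size: 10,000 patients per cohort, GRU with embedding 24 / hidden 32,
sequence cap 48 events, 100 balanced batches of 64 per epoch, ≤ 8 epochs
with patience 3 — sizes at which a replicate trains in about a minute on
one CPU while leaving the planted signal comfortably learnable. At ~0.3%
incidence a 10,000-patient replicate occasionally leaves the 10% test split
without a single positive 36-month trajectory; `replicate_seeds` therefore
walks cohort seeds deterministically and skips replicates with fewer than 3
evaluable positives in either condition — a degeneracy guard on the
evaluation set, applied before any model is trained.

## Known limitations

- No bundled ICD ontology or cross-revision mapping tables; `map_code_system`
  consumes a caller-supplied equivalence table.
- The transformer omits layer normalization; at the default widths this is
  benign, but very deep configurations would want it.
- Bootstrap CIs are percentile intervals; no BCa correction.
- The generator's hazard is piecewise-constant monthly and code effects are
  multiplicative and permanent once acquired; real risk factors wax and wane.
- Sex is generated and stored but not used as a model input.
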