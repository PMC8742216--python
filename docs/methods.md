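# Methods

This document describes the modelling choices in `akipredict` in enough
detail to re-derive every number the toolkit produces. The companion
[README](../README.md) shows how to run the pipeline; this file explains
what each stage computes and why.

## 1. Problem setting

The toolkit predicts hospital-acquired acute kidney injury (AKI) from
routinely collected laboratory results, with a fixed lead time: at least
48 hours before the first creatinine measurement that defines AKI. The
unit of analysis is the hospital admission. Each analyzable admission
yields exactly one sample — a 7-day window of lab values ending 48 hours
before the outcome anchor — and one binary label.

## 2. KDIGO labeling (`akipredict.kdigo`)

AKI is detected from serial serum creatinine alone (the urine-output
criterion is not used because urine output is rarely charted outside
critical care). A creatinine measurement at time `t` with value `v`
qualifies as AKI-defining if either:

- **relative**: `v >= 1.5 * r` for some reference value `r` measured in
  `(t - 7 days, t)`, or
- **absolute**: `v > r + 26.5 umol/L` (0.3 mg/dL) for some reference in
  `(t - 48 h, t)`.

The episode baseline is the minimum creatinine inside the widest
qualifying look-back window. Staging follows KDIGO 2012: stage 1 at
1.5–1.9x baseline or a qualifying absolute rise, stage 2 at 2.0–2.9x,
stage 3 at >= 3.0x or creatinine >= 353.6 umol/L. Qualifying points
within 7 days of an episode's onset are absorbed into that episode
(the episode's stage is the maximum over absorbed points); a fresh
qualifying pair strictly after the episode's last qualifying point
starts a new episode.

`detect_aki` runs in `O(n log n)` per series using a sliding-window
minimum, but its contract is the quadratic all-pairs definition above.
The test suite checks equivalence against a literal all-pairs
enumeration on roughly 10^4 adversarial toy series (exhaustive over all
series of length <= 3 on a value/gap grid, plus random longer grid
series), which is what caught a datetime-precision bug during
development.

An admission is labeled positive if its first *analyzed* episode begins
more than 48 hours after admission (hospital-acquired); earlier onsets
mark the admission as community AKI and exclude it.

## 3. Cohort construction (`akipredict.cohort`)

Five exclusion rules run in order; the first match is recorded as the
reason, so reported counts are disjoint:

1. `short_stay` — discharged within 48 h of admission.
2. `community_aki` — earliest AKI onset within 48 h of admission.
3. `ckd5` — ESKD diagnosis code, admission eGFR < 15, or a
   dialysis-access procedure code.
4. `prior_rrt_no_recovery` — prior renal replacement therapy procedure
   code with admission eGFR < 30.
5. `no_labs` — no laboratory results at all.

eGFR uses the 2009 CKD-EPI creatinine equation without the race
coefficient, on the first creatinine drawn within 48 h of admission.
All thresholds and code patterns live in `CohortConfig` and can be
overridden from YAML. Exclusion is per admission, not per patient.

## 4. Featurization (`akipredict.features`)

- **Anchor**: for positive admissions, the onset time of the first
  analyzed episode; for controls, the last serum creatinine measurement.
  Anchoring controls at a lab draw rather than at discharge keeps the
  window geometry of cases and controls comparable, so the model cannot
  score on bookkeeping artifacts.
- **Window**: features come from `(anchor - 48 h - 7 d, anchor - 48 h]`,
  binned into seven 24-hour bins (most recent bin last). Everything in
  the final 48 hours before the anchor is discarded — this is the
  prediction blackout that enforces the lead time.
- **Values**: per-bin mean of each analyte; a parallel mask matrix
  records which (bin, analyte) cells held at least one measurement.
- **Normalization**: per-analyte min–max scaling to [0, 1], with the
  min/max estimated on the *training split only* and frozen into the
  `FeatureVocabulary`; validation/test values are clipped into [0, 1].
- **Split**: 80/10/10 by deterministic shuffle under a seed, with
  largest-remainder rounding so the three parts always partition the
  cohort (20 732 admissions split as 16 585 / 2 073 / 2 074). An
  optional grouped mode keeps all admissions of one patient in one
  split.

## 5. The TITV model (`akipredict.titv`)

TITV ("time-invariant / time-variant") is an interpretable recurrent
architecture whose prediction decomposes exactly into per-(analyte,
time-bin) contributions. For analyte `f` with training-set mean
measurement value `u_f`, missingness rate `m_f`, and per-sample
measured fraction `u` and mean `m`:

1. **Time-invariant gate.** A small shared MLP reads the per-sample
   summary `[u, m, z_u, z_m]` (the z-scores clipped at +/-4) and emits a
   per-analyte gate `gamma_f = 2 * sigmoid(h_g @ v_g + g_skip * z_u +
   g_base_f) in (0, 2)`: analytes whose sampling pattern is unusual for
   this patient can be amplified or attenuated before the recurrence.
2. **Deviation coding.** Observed values enter as deviations from the
   training mean, `Xc = (X - x_mean) * M`, and each *observation* adds a
   learned per-analyte offset `delta_f`: `x~ = gamma * Xc + delta * M`.
   The fact that a test was ordered is itself a feature.
3. **Recurrence and attention.** A bidirectional GRU over the seven
   bins produces hidden states; a time-only attention head yields
   weights `a_t` (softmax over bins). Attention is over time only —
   feature credit comes from the contribution decomposition instead, so
   the two axes of the explanation cannot trade off against each other.
4. **Exact decomposition.** The logit is
   `logit = sum_{t,f} c_tf + b`, with `c_tf = w_f * a_t * x~_tf`.
   Because this identity is structural, per-cell importances need no
   post-hoc approximation: `beta_f = sum_t |c_tf| / sum_{t,f} |c_tf|`
   is the analyte's share of the absolute logit mass, and
   `alpha_tf = a_t / F` distributes the time weights uniformly across
   analytes so both maps are simplex-normalized.

Training minimizes class-weighted binary cross-entropy plus a ramped
entropy penalty on `beta` (encouraging sparse analyte attributions) and
an L1 penalty on `w`, with Adam, gradient clipping, learning-rate decay
and early stopping on validation AUROC. The whole model, including the
reverse-mode autodiff it trains with (`akipredict._autodiff`), is plain
NumPy; a full-model finite-difference gradient check is part of the
test suite.

Baselines: L2-regularized logistic regression on the flattened
(values ++ masks) window, and uni-/bidirectional GRU classifiers without
the interpretable decomposition.

### Deviations from the usual attention-RNN recipe

These are deliberate and documented in the README as well:

- the gate is bounded in (0, 2) rather than unbounded softplus — large
  gates and small recurrent weights are unidentifiable, and the bound
  keeps gradients stable on small cohorts;
- inputs are deviation-coded with an explicit per-observation offset,
  separating "was measured" from "measured high/low";
- attention is time-only with uniform spread across analytes; feature
  attribution comes from the exact contribution identity instead of a
  feature-attention head.

## 6. Evaluation (`akipredict.evaluation`)

- AUROC (scikit-learn's `roc_auc_score`, i.e. the tie-corrected
  Mann–Whitney pair statistic) with a seeded bootstrap percentile CI;
  the test suite checks it against an independent brute-force
  pair-counting implementation.
- A threshold sweep over alert thresholds reports, per threshold, the
  confusion matrix, precision (flagged when undefined), recall, F1, and
  the number of alerts; the operating point with the highest F1 (lowest
  threshold on ties) is highlighted. This is the alert-burden view:
  e.g. a low threshold may recover 60% of cases at the cost of ~6 false
  alerts per true alert, while a higher one trades recall for ~2.

## 7. Synthetic EHR generator (`akipredict.synthetic`)

The generator produces `admissions.csv`, `labs.csv` and a `truth.json`
with the planted ground truth, so every claim the pipeline makes can be
checked against a known answer.

- Admission demographics, stay lengths and per-analyte ordering
  frequencies are drawn from skewed parametric families; analytes are
  log-normal around physiological centers (30-analyte panel plus
  condition-specific extras such as `vancomycin_level` and `nt_probnp`).
- AKI cases (default prevalence 4.4% of the analyzable cohort, onset
  median around day 6) receive a planted creatinine trajectory that
  crosses the KDIGO thresholds, plus one of four *archetypes* (sepsis,
  cardiac, nephrotoxic, multi-organ) that shifts its signal analytes by
  `effect_size_sd` standard deviations, ramping up toward onset. The
  signal fraction is evaluated at the actual draw hour, and sick
  patients are also sampled more often (ordering–outcome coupling), as
  in real EHR data — both effects are suppressed when the effect size
  is zero.
- Controls are given the same stay geometry as cases (a pseudo-anchor
  drawn from the same onset law, with a final creatinine draw at it) so
  that window geometry alone carries no label information.
- Admissions matching each exclusion rule are planted deliberately, so
  the cascade's counts can be asserted exactly.
- A `signal_in_prediction_window_only` switch moves all archetype
  signal inside the 48-hour blackout. A leak-free pipeline must score
  at chance on such a cohort; this canary is one of the acceptance
  tests.
- `effect_size_oracle` reports the AUROC of an oracle that knows the
  planted signal analytes and reads them over the same feature window —
  an upper bound used to judge how much of the available signal the
  trained model recovers. Its controls are anchored at the last
  creatinine draw, matching the pipeline, so draw-count asymmetries do
  not leak into the bound.

## 8. Numerical and reproducibility choices

- Every stochastic step (generator, split, parameter init, minibatch
  order, bootstrap) takes an explicit seed; repeated runs are
  byte-identical.
- Creatinine is carried in umol/L throughout; mg/dL inputs are converted
  on read (1 mg/dL = 88.4 umol/L).
- Timestamps are `datetime64[ns]` end to end; comparisons avoid
  lossy unit conversions (a ns→µs truncation bug is pinned by a
  regression test).
- The stochastic acceptance criteria (planted-signal recovery and the
  leakage canary) are asserted on the mean over five fixed seeds, which
  is deterministic; per-seed bands at this cohort size (~21 test
  positives, null AUROC SD ≈ 0.065) would fail regularly even for a
  perfect model.

## 9. Limitations

- The generator's physiology is parametric and stationary; it does not
  model interventions, transfers between units, or assay changes.
- Only the creatinine KDIGO criteria are implemented; urine output and
  renal-replacement initiation are out of scope.
- The TITV attributions explain the model's logit exactly, but exact
  attribution is not causal attribution: correlated analytes can share
  or swap credit.
- Min–max normalization is robust here because the generator has no
  gross outliers; real deployments may prefer winsorized or rank-based
  scaling.
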