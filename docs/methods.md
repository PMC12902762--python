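# Methods

## The tiered screening procedure

`tierscreen` implements a three-tier adaptive screening battery for common
mental-health problems (depression, anxiety, post-traumatic stress,
insomnia) in refugee populations, together with the machinery used to
validate such a procedure against a clinical reference standard.

The battery builds on 56 items from five validated Likert scales:

| Tier | Scale | Items | Range/item | Cutoff (positive if ≥) |
|---|---|---|---|---|
| 1 | RHS-13 (general distress) | 13 | 0–4 | 11 |
| 2 | PHQ-2 (depression gate) | 2 | 0–3 | 2 |
| 2 | GAD-2 (anxiety gate) | 2 | 0–3 | 2 |
| 2 | PCL-5 short form (PTSD gate) | 4 | 0–4 | 5 |
| 2 | ISI-7 item 7 (insomnia gate) | 1 | 0–4 | 2 |
| 3 | PHQ-9 | 9 | 0–3 | 10 |
| 3 | GAD-7 | 7 | 0–3 | 10 |
| 3 | PCL-5 | 20 | 0–4 | 32 |
| 3 | ISI-7 | 7 | 0–4 | 11 |

All scores are plain item sums (none of these instruments reverse-codes),
dichotomised as positive iff score ≥ cutoff.  Tier 1 is a gateway: a
negative outcome terminates the session after 13 items.  Tier 2 presents
all four short gates together (9 items); if every gate is negative the
session ends at 22 items.  Otherwise Tier 3 presents, for each positive
gate, the remainder of the corresponding full scale — the gate items are
embedded in their full scales and are never asked twice; their responses
carry over into the full-scale score.  A disorder screens positive only
when all three tiers are positive: distress gateway, the disorder's gate,
and the full scale at its severity cutoff.

Item-burden accounting uses the four full scales (43 items) as baseline,
since that is the non-adaptive comparator: a Tier-1-negative respondent
answers 13 items (69.8% reduction), a single-gate anxiety path 27 items
(37.2% reduction), and a respondent positive everywhere answers all 56
(a 30.2% *increase*, the price of the added distress screener).

Everything above is configuration (`itap_default.yaml`), not code: item
ranges, tier membership, short-form maps and cutoffs can all be
overridden.  The published source of the 4-item PCL-5 short form does not
list its item numbers; the default config uses items 1, 4, 7 and 10 (one
per DSM-5 symptom cluster) as a documented, replaceable choice, and no
logic depends on which four items are mapped.

## Design choices in the engine

* Tier-2 gate decisions are made only after all 9 gate items are answered;
  there is no within-tier adaptivity (the tier design specifies tier-level
  outcomes only).
* Item order within a tier is the configuration order; no randomisation.
* Sessions are append-only event logs: responses can never be revised, and
  a session replays bit-identically from its JSON log (the log carries a
  battery-config hash so replay under a different battery is refused).
* Missing responses are an error; a permissive dataset mode drops the
  respondent with a warning.  Nothing is ever imputed.

The retrospective simulator (`tiersim.simulate_tiered`) re-implements the
tier logic directly over complete response tables, deliberately
independent of the stateful engine; the two implementations are asserted
equal on large random batches, which guards both.

## Accuracy statistics

For each disorder the screen outcome is compared with a reference label in
a 2×2 table.  Sensitivity, specificity, PPV, NPV and accuracy are reported
as percentages with Wald 95% confidence intervals, p ± 1.96·√(p(1−p)/m) on
each metric's own denominator m, clipped to [0, 100].  The Wald interval
was chosen because it reproduces the bounds conventionally printed in
validation reports of this kind; its undercoverage for extreme p and small
m is documented (an empirical-coverage test asserts 90–97% coverage at
n = 70, p = 0.8) rather than corrected.  One consequence of computing
rather than transcribing: the depression sensitivity lower bound renders
as 85.4 where reports conventionally print 85.5 — the value is 85.448
before rounding.

Cohen's κ = (p_o − p_e)/(1 − p_e) measures chance-corrected agreement; it
is undefined (and flagged, never coerced) when both classifications are
constant.  Metrics with zero denominators are likewise reported as
explicit "undefined" flags.  Rounding — percentages to 1 decimal, κ to 2,
half up — happens only in the reporting layer; stored values keep full
precision.

The anxiety outcome is a single collapsed flag on both sides: one
anxiety scale stands in for panic disorder, agoraphobia, social anxiety
and generalised anxiety, and the reference label is the OR of those
diagnoses.

Pooled positive identification is Σtp / Σ(tp+fn) across the four
disorders.  Per-individual correctness counts, for each respondent, how
many of the four calls agree with the reference (0–4) and splits the
failed calls into false positives and false negatives.  The cutoff sweep
evaluates plain full-scale dichotomisation at candidate cutoffs (e.g. the
insomnia scale's proposed 8 / 11 / 14); it is not re-run through the tiers.

## The synthetic cohort generator

No participant-level data are available for studies of this kind, so the
generator emulates the *structure* such cohorts report:

* a 5-dimensional latent severity vector (distress + four disorders) per
  respondent, standard multivariate normal with correlation matrix R;
* reference diagnosis d true iff latent_d > Φ⁻¹(1 − prevalence_d), then
  flipped with probability `diagnosis_noise` (default 0.05) so index test
  and reference disagree the way two imperfect measures do;
* item responses as thresholded Gaussians,
  y = λ·latent + √(1−λ²)·ε, cut at per-scale category thresholds, so the
  marginal distribution of y is standard normal and thresholds are
  interpretable as population quantiles.

Defaults (frozen after a one-off calibration run, not tuned afterwards):
prevalences 0.286 / 0.243 / 0.286 / 0.371 (depression, anxiety, PTSD,
insomnia), latent correlation 0.80 between disorders with a 0.85 distress
row (positive definite), loading λ = 0.78, and thresholds chosen so the
default spec's mean scale scores land near the means such cohorts report
(≈ 21.6 / 9.9 / 8.3 / 30 / 11.6 for RHS-13 / PHQ-9 / GAD-7 / PCL-5 /
ISI-7).  At n = 5000 this yields Cronbach α of 0.89–0.96 per scale and
inter-scale Pearson r of 0.70–0.80 — inside the 0.70–0.89 band reported
for real cohorts of this kind; α and r are emergent from λ and R, never
set directly.

Determinism: one integer seed feeds `numpy.random.SeedSequence`, which
spawns independent PCG64 streams for latents, item noise and label flips;
the same spec and seed reproduce a cohort exactly on any platform.

What the generator does **not** model: missing responses, acquiescence and
other response styles, differential item functioning across languages,
and any real-data covariance beyond the single-factor-per-scale structure.
Tests passing on synthetic cohorts therefore demonstrate the correctness
of the procedure and its statistics, not the field performance of the
instruments.

## Problem sizes used in the checks

The whole-stack checks run at sizes chosen to make sampling noise
negligible relative to their tolerance bands: engine/simulator equivalence
on 1000 random complete response vectors (exact equality), accuracy
metrics against a per-respondent recount on 500 random cohorts, parameter
recovery through generate → simulate → evaluate at n = 2000 with a
high-separation spec (λ = 0.95, no label noise; sensitivity ≥ 90% per
disorder), and generator calibration at n = 5000.

## Known limitations

* Wald intervals (see above); no bootstrap or score intervals.
* No ROC/AUC machinery: gateway cutoffs are taken as given, only a fixed
  cutoff sweep is provided.
* The reference standard here is always a label vector; interviewer
  behaviour, safety protocols and user-experience items are out of scope.
* κ is unweighted binary agreement; no multi-rater or weighted variants.
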