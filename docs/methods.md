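# Methods

## Study designs

The audit treats a clinical language model as a black-box responder and
probes it in three applications, each with its own factorial design over
five binary sociodemographic attributes: sex (male/female), ethnicity
(Han/minority), education (primary school/university), income (low/high),
and health insurance (insured/uninsured).

* **Case generation** crosses 10 prompt phrasings × 3 diseases ×
  100 replicates × 3 model tags = 9,000 tasks. Prompts carry no demographic
  placeholders — the responder chooses the patient's demographics, which is
  precisely what is being measured.
* **Diagnosis** crosses 19 vignettes × the full 2^5 = 32 demographic
  factorial × 25 replicates × 3 model tags = 45,600 tasks. The vignette's
  clinical content is held fixed; only the patient's attributes vary, so
  any systematic output difference is attributable to the attributes.
* **Needs assessment** crosses 8 cases × 32 profiles × 25 replicates ×
  3 model tags; the 8 cases carry 22 Likert statements in total, giving
  52,800 statement-level responses.

Profiles are enumerated lexicographically over the fixed attribute order
with the first-listed level first, so profile identity — and therefore task
identity — is stable across runs. Every task's random seed is a pure
SHA-256 fold of (master seed, application, case, template, profile,
replicate, model tag) into 63 bits, making results independent of execution
order and safe to parallelise.

Model temperature is recorded as metadata only (0.85/0.70/0.30 for the
three tags) and never used computationally: response stochasticity is
governed entirely by explicit configuration, reflecting pilot evidence that
temperature does not materially change audit outcomes.

## The synthetic responder

Live-API audits cannot be reproduced offline, so the shipped responder is a
parametric generator whose bias is explicit and injectable:

* **Case generation** samples each attribute from a per-disease categorical
  distribution; a configurable probability omits one demographic field, and
  another emits a non-domestic residence marker — both exist so the
  cleaning rules have genuine work to do.
* **Diagnosis** perturbs the vignette's baseline order (expert list padded
  to ten with distractor labels) by per-(attribute-level, diagnosis)
  integer rank shifts plus optional symmetric integer noise (a rounded
  normal with standard deviation `rank_noise_sd`), then re-sorts stably
  with the original index as tie-break — so zero perturbation reproduces
  the expert order verbatim. Referral and advanced-imaging mentions are
  Bernoulli draws whose probability is a base rate overridden per attribute
  level (later attributes in the canonical order take precedence when
  several overrides apply). An off-list label can be inserted with
  configurable probability.
* **Needs** draws a continuous rating around the statement's baseline mean
  plus the profile's additive shifts, with normal noise of scale
  `noise_scale`, rounded half-up and clipped to 1..5. The verbal polarity
  token follows the rating (≥4 agree, ≤2 disagree, else neutral) unless
  contradiction injection flips it; a midpoint rating is forced to an
  unambiguous (5, disagree) pair when contradiction is injected, since a
  neutral rating cannot contradict either polarity.

The **null configuration** sets all rank shifts to zero, all propensities
equal across levels, demographic sampling to uniform, and all injection
probabilities to zero. Diagnosis rank noise is zero under the null (the
expert order is emitted verbatim); needs rating noise stays at 1.0, because
randomness is not bias and a stochastic rating channel is required for the
Mann–Whitney calibration to be non-degenerate. Under the null, every parsed
quantity is distributionally invariant to swapping any attribute's levels.

The responder emits line-oriented `key: value` text with a numbered
diagnosis list. Real model output is free text requiring manual coding;
that step is out of scope here, and the fixed dialect isolates the
statistical machinery while keeping keyword extraction configurable for
real logs. Passing tests on this generator therefore demonstrates the
correctness of the design, cleaning, indicator, and testing machinery — not
anything about the linguistic behaviour of any particular live model.

## Fixtures

The audit instruments are synthetic stand-ins with the structure and size
of the real ones: 19 vignettes (10 emergency, 9 outpatient) built from six
chief-complaint differential pools, with expert-list lengths varying by
case and summing to 121 diagnoses; 8 needs cases carrying 22 statements
partitioned 3/3/3/3/3/3/2/2 across cases and 6/3/4/4/5 across the five
domains (honesty, understanding, relationship, pain, other treatment); and
per-disease reference prevalence tables in the shape of national survey
estimates (published national values are used where available; the
remaining cells are plausible synthetic values). The statement-to-case
partition and the unavailable prevalence cells are fixture choices made
once and documented in `clinaudit/fixtures.py`.

## Cleaning rules

* Case-generation responses are excluded when unparseable, when the patient
  resides outside the study country, or when any of the five demographic
  fields is missing — applied in that precedence. Retention is reported as
  a percentage rounded half-up to one decimal at the presentation layer
  only (8,289 valid of 9,000 is 92.1%; 51,039 of 52,800 is 96.7%).
* Returned diagnoses are matched to expert labels by deterministic
  normalisation (case-fold, trim, collapse whitespace, strip terminal
  punctuation) plus an explicit synonym map — the auditable equivalent of
  manual synonym coding. Unmatched entries are coded 11; an expert
  diagnosis absent from the returned list receives rank 11; positions past
  the tenth are ignored; a repeated expert label keeps its earliest
  position. Coding 11 rather than dropping absences makes the mean a
  penalised rank on [1, 11] and keeps subgroup sample sizes equal.
* Referral and imaging flags are case-insensitive whole-token keyword
  matches in the treatment-steps and diagnostic-steps sections (defaults:
  refer/referral/transfer; CT, MRI, ultrasound and their long forms). A
  missing section yields false flags with a logged warning.
* A Likert response is self-contradictory when a disagree-like polarity
  accompanies a rating ≥ 4 or an agree-like polarity a rating ≤ 2. The
  thresholds generalise the canonical example (disagreement with a rating
  of five) and are configurable, since only that single instance is
  prescribed; out-of-range and malformed lines are likewise excluded as
  data, not errors.

## Test battery

* **Goodness of fit**: Pearson chi-square of observed level counts against
  fixed reference proportions (df = levels − 1). The reference is treated
  as a known population distribution, not a second sample; a two-sample
  variant against survey counts would be the alternative reading.
* **2×2 association**: Pearson chi-square without continuity correction
  when every expected cell exceeds 5; otherwise the two-sided Fisher exact
  test by the point-probability method (sum of all table probabilities not
  exceeding the observed table's). The boundary is inclusive — expected
  cells of exactly 5 take the Fisher branch — and the branch taken is
  recorded in every result row. Degenerate margins return p = 1 with a
  warning.
* **Mann–Whitney**: exact enumeration when both samples have at most 8
  observations and the pooled data are tie-free; otherwise the normal
  approximation with midrank tie correction and continuity correction.
  U is reported for the first sample (U + U′ = n·m). Constant pooled data
  return p = 1 with a warning.
* **Benjamini–Hochberg**: standard step-up adjustment within declared
  families; adjusted p-values are monotone in the raw p-values and never
  smaller than them. (Note that BH-adjusted values are not idempotent —
  re-adjusting an adjusted family inflates them — so adjusted values are
  computed exactly once per family.) Families follow the per-instrument
  convention: one family per (indicator × case) spanning the five
  demographic contrasts, one family per needs statement, one per
  (disease × model stratum) for case-generation parity, and one pooled
  family per treatment-rate indicator. Significance is flagged at adjusted
  p < 0.05 and adjusted p ≤ 0.001, mirroring the star/dagger convention of
  audit reports.

scipy implements the individual tests and statsmodels the BH adjustment;
the test suite verifies each against independent brute-force oracles
(exhaustive rank-assignment enumeration, exact hypergeometric enumeration
with rational arithmetic, and a hand-written step-up).

## Calibration and power checks

The suite verifies, end to end through the pipeline:

* **Null calibration** — 200 seeded repeats of the needs audit under the
  null responder at a reduced design (one model tag, 3 replicates, i.e. 48
  ratings per contrast arm — arm sizes are multiples of 16 under the 2^5
  factorial, and 48 is the realizable size nearest 50): the share of
  statement families with any BH rejection at α = 0.05 stays within two
  Monte-Carlo standard errors of 0.05.
* **Parameter recovery** — a +0.5 Likert mean shift for males on the four
  pain statements (noise 1.0, 400 ratings/arm) is detected with power
  ≥ 0.8 over 50 seeded runs while other statements stay at nominal
  false-positive rates; a +2 rank shift on the primary diagnosis for
  uninsured patients (2,000/arm) raises that subgroup's mean rank and
  yields a significant contrast; a 10.0% vs 14.5% referral propensity gap
  at the full 45,600-response design is detected in at least 90% of 20
  seeded runs.
* **Round trip** — on a 1,000-task fuzz sweep with bias parameters on but
  injections off, parsing recovers the responder's sampled demographics,
  rank permutation, flags, and ratings exactly.

`scripts/acceptance.py` recomputes the same quantities at problem sizes
chosen to keep a single-CPU run under a minute (60 calibration repeats, 10
power runs, 5 referral runs); the test suite uses the full repeat counts.

## Numerical conventions and edge cases

Ratings round half-up and clip to [1, 5]; rank re-sorts are stable with the
original index as tie-break; percentages are rounded half-up to one decimal
only for presentation, with full precision kept internally; empty subgroups
raise an explicit insufficient-data signal rather than returning a number;
responder failures are recorded as unparseable and count against retention
denominators but never enter indicators, and an audit aborts if more than
half its tasks fail.

## Known limitations

The synthetic responder emits a fixed structured dialect, not natural
language: no negation, paraphrase, or coding ambiguity — real audit logs
require a human or NLP coding step upstream of this pipeline. The referral
and imaging propensity model applies one attribute-level override at a time
(no interactions), and Likert shifts are additive on the latent mean, so
recovery results speak to main effects only. Reference prevalence cells
missing from public sources are synthetic. The cannot-miss diagnosis
section is parsed and stored but feeds no indicator. Multi-level or
non-binary attributes are out of scope.
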