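# Methods

This document states the model implemented by `dietsub`, the default
parameters and their units, the scope of the synthetic-cohort generator,
and the numerical conventions used throughout. It makes no empirical
claims beyond what the package itself computes.

## 1. Data model

**Diet diaries.** A dataset holds a roster of children (id, age in
months; the supported window is 36–72 months, grouped into the strata
37–48, 49–60 and 61–72) and a table of diary entries
`(child_id, day, food_id, amount_g)` over a fixed number of diary days
(default 4). Children present on the roster with no recorded meal are
excluded at load time and counted in `n_excluded`. Amounts are grams of
food *as consumed*; beverages are treated at density 1 g/mL, so grams
and millilitres are interchangeable.

**Composition.** Each food carries an 18-component profile per 100 g:
energy (kcal), carbohydrate, protein, fat (g), calcium, potassium (mg),
iron, zinc (mg), iodine (µg), vitamin A (µg RE), B1, B2, B6 (mg), B3
(mg NE), B9 (µg DFE), B12 (µg), C (mg) and D (µg). A component can be
*missing* (not analysed at source, written `/` in the CSV files).
Missing flags propagate through addition and scaling: a sum involving a
missing component is itself flagged, and its numeric value is a lower
bound built from the measured parts. Powdered foods carry a
reconstitution factor `f ∈ (0, 1]`; their as-consumed profile is the
per-100 g powder profile multiplied by `f` (default for the fortified
milk powder: 0.147, i.e. 14.7 g powder per 100 mL of prepared drink).

**Soft-drink categories.** Seven categories define the substitution
target set: carbonated, fruit/vegetable, protein (milk-containing)
drinks, tea drinks, botanical drinks, flavored drinks, and solid-form
drinks. Protein drinks flagged `dairy_drink` form the dairy subset
reported separately.

## 2. Substitution model

A scenario is `(name, substitute_food_id, target_categories)`. Applying
it re-points every diary entry whose food lies in the target categories
at the substitute, leaving `amount_g`, day and child untouched. Three
preset models substitute soymilk (model 1), cow's milk (model 2), and
the fortified milk powder for preschool children (model 3).

Consequences used as test invariants:

- **Mass conservation** — per child-day total grams are unchanged.
- **Non-consumer fixed point** — children without target-category
  entries have identical records and intakes afterwards.
- **Idempotence** — applying a scenario twice equals applying it once
  (the substitute must not itself lie in the target categories; that is
  rejected at validation).
- **Commutation** — scenarios over disjoint category sets commute.
- **Dominance** — if substitute A's as-consumed profile dominates B's
  component-wise, every child's post-substitution intake under A
  dominates that under B, and inadequacy prevalence is monotone
  accordingly.

## 3. Intake and adequacy

Mean daily intake per child is `Σ entries profile(food) · amount/100`
divided by the number of diary days (days with no entries count as
zero). Adequacy uses the EAR cut-point method against packaged Chinese
DRI values for ages 4–6 years applied across the full 37–72-month
window: a child is *inadequate* for a nutrient iff mean daily intake is
**strictly below** the reference value (EAR for most nutrients, AI for
potassium). Energy and fat carry reference type `none` and are never
evaluated for adequacy. Prevalence percentages use half-up rounding to
2 decimals (e.g. 178/676 → 26.33).

## 4. Statistics

- **Wilcoxon signed-rank** (paired intakes): zero differences are
  discarded by default (Pratt handling available). With ≤ 25 effective
  pairs and no tied absolute differences the exact null distribution is
  used; otherwise the normal approximation without continuity
  correction.
- **McNemar** (paired inadequacy flags): with fewer than 25 discordant
  pairs, the exact two-sided binomial test on the discordant split;
  otherwise the continuity-corrected chi-square with 1 df. No
  discordant pairs ⇒ p = 1.
- **Kruskal–Wallis** (amounts or changes across groups): tie-corrected
  H with the asymptotic chi-square reference, or a seeded Monte-Carlo
  permutation reference `p = (1 + #{H* ≥ H}) / (1 + R)`.
- **Pearson chi-square** (consumer share by age band): no continuity
  correction; a warning is emitted when any expected count is below 5,
  and degenerate tables (a zero marginal) are reported as not
  applicable rather than tested.
- **Letters** — six pairwise comparisons are labelled a
  (before vs model 1), b (before vs 2), c (before vs 3), d (1 vs 2),
  e (1 vs 3), f (2 vs 3); a letter is printed on the second group's row
  when p < α strictly (default α = 0.05).

Small-sample exact paths are verified in the test suite against
independent brute-force oracles: full 2ⁿ sign enumeration for Wilcoxon,
full discordant-split enumeration for McNemar, and exhaustive
permutations for Kruskal–Wallis at n ≤ 7.

**Type-I-error calibration.** An identity substitution (substitute with
the substitute's own profile) changes nothing, so every paired test on
such a null cohort is a deterministic fixed point (p = 1, zero
effective pairs) — there is no sampling distribution to calibrate
there. Nominal-level behaviour is therefore checked by drawing from
each test's own null: paired normal noise for Wilcoxon (n = 60),
independent Bernoulli states for McNemar (n = 3500 pairs),
equal-distribution groups for Kruskal–Wallis (3 × 25), and
independence-holding tables for chi-square (676 children, 2 × 3). Over
2000 seeded replicates each, the rejection rate at α = 0.05 must lie
within 3 binomial standard errors of 0.05 (≈ [0.035, 0.065]).

## 5. Synthetic cohort generator

`CohortSpec` defaults describe the emulated survey frame:

| parameter | default | meaning |
|---|---|---|
| `n_children` | 676 | cohort size |
| `strata_sizes` | (224, 226, 226) | children per age stratum |
| `diary_days` | 4 | diary window length |
| `consumption_prob` | (0.2277, 0.2345, 0.3274) | P(child consumes any soft drink), per stratum |
| `dairy_share` | 0.7472 | share of consumers whose drink is a dairy drink |
| `amount_p25`, `amount_median`, `amount_p75` | 25, 40, 75 g/d | consumer mean-daily-amount targets |
| `drink_day_prob` | 0.5 | P(drink day \| consumer), independent days |

Mechanics: ages are drawn uniformly within each stratum. Background
diet comes from a pool of ~20 staple foods plus a multivitamin
supplement, each with (child-probability, day-probability, mean grams,
gamma shape) habit parameters, scaled by a child-level log-normal
appetite multiplier (σ = 0.35) that creates realistic between-child
spread. Soft-drink consumers draw a mean daily amount from a log-normal
and split it evenly over their drink days, so the diary-window mean
recovers the drawn amount exactly.

**Amount distribution fit.** A two-parameter log-normal cannot match
three quantiles; the generator matches the quartiles:
`μ = (ln P25 + ln P75)/2`, `σ = (ln P75 − ln P25)/(2 z₀.₇₅)`. The
implied median is `√(P25·P75) ≈ 43.3 g/d`, about 8% above the 40 g/d
target median — an acknowledged approximation error of the
quartile-matched fit. Recovery tests assert the quartiles at their
targets and the median at its implied value.

**What the generator does and does not emulate.** It reproduces the
survey's marginal structure (stratum sizes, consumer shares, dairy
share, amount quartiles) and produces adequacy prevalences of the right
order for the headline nutrients, because the background pool was built
from typical staple-food compositions. It does *not* reproduce the
survey's joint intake distribution, food-level correlations,
seasonality, or reporting error, and its nutrient prevalences should
not be read as estimates of any real population. The `null_cohort`
variant points every soft-drink entry at a drink whose profile equals a
chosen substitute's, giving an exact no-effect ground truth.

## 6. Numerical conventions

- Percentages and printed medians use decimal half-up rounding
  (`round_half_up`), not banker's rounding.
- Quantiles use linear interpolation (`numpy` `method="linear"`),
  matching the sort-based oracle in the tests.
- p-values below 0.001 print as `<0.001`; otherwise 3 decimals.
- All randomness flows through `numpy.random.default_rng(seed)`; for a
  fixed seed, generated cohorts are byte-identical and the pipeline's
  rendered outputs are reproducible. Run metadata (seed, α, software
  version, SHA-256 configuration hash over records, composition,
  scenarios and reference values) is written next to every report.

## 7. Limitations

- Entry-level substitution keeps each drink occasion's mass; it does
  not model behavioural substitution (children drinking more or less of
  the replacement), energy compensation elsewhere in the diet, or
  palatability.
- The 1 g/mL density convention slightly mis-weights dense or solid
  drink forms.
- Missing composition cells make post-substitution totals lower bounds
  for the affected components (notably vitamin C and D for the liquid
  substitutes); comparisons on those components should be read with
  that in mind.
- The EAR cut-point method assumes intake and requirement are
  independent and requirement distributions are symmetric; it is a
  prevalence estimator, not an individual diagnosis.
- A 4-day diary mean is a noisy estimate of usual intake; no
  measurement-error deattenuation is applied.
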