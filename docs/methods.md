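# Methods

This note documents the models and procedures implemented in `edlos`, the
choices made where the design was genuinely open, and what the synthetic
testbed does and does not establish about real hospital data.

## Problem and outcome

For patients admitted to a hospital ward through the emergency department
(ED), we predict at transfer time whether the total stay — ED hours plus
the subsequent ward stay — will be **long** (≥ 7 days).  The 7-day cut
sits near the cohort median, so the two classes are roughly balanced and
accuracy is a meaningful headline metric; the threshold is configurable
(`SrfParams.long_stay_threshold_days`) for sites whose median differs
(e.g. a 6-day reading).  Stays whose post-ED ward portion lasted ≤ 2 days
are excluded: very short stays follow different dynamics and would
dominate an otherwise long-tailed distribution.

## Concept extraction

Notes are processed in three steps.

1. **Sub-text splitting** on sentence punctuation (`. ! ? ;`) and
   newlines.  Clause-level ("proposition") splitting is deliberately not
   attempted; the sentence is the scope unit throughout.
2. **Context classification** into four categories — patient/family ×
   affirmation/negation — by cue lexicons applied at sentence scope.
   The two axes fire independently: any family cue makes the subject
   "family", any negation cue makes the polarity "negation", and cue-free
   (neutral) text is patient-affirmation.  This is a NegEx-style
   rule classifier; the cue inventories are configuration (small English
   and French defaults ship with the package) rather than a claim about
   any particular production system.  Sentence scope will over-negate
   sentences like "no fever but abdominal pain"; this is a known,
   accepted simplification.
3. **Exact most-precise matching** in patient-affirmation sub-texts only.
   Terms and text are normalized identically (case-fold, accent-fold,
   whitespace-collapse) and a term matches only at word-token boundaries,
   so "pain" never matches inside "painting".  When candidate matches
   overlap, longer terms claim their tokens first (ties: earliest start,
   then concept id) and tokens are consumed once per scan, making the
   matcher deterministic.  The matched set is then reduced to its most
   precise members: a concept that is a proper ancestor of another match
   is dropped.  A matched non-leaf with no matched descendant is *kept*
   as matched rather than refined toward a leaf — refining would invent
   specificity the text does not state.

Stay-level output is binary presence over the union of a stay's
patient-affirmation sub-texts; counts are not kept.

The thesaurus is a single-parent hierarchy loaded from TSV.  Real
meta-thesauri are multi-hierarchies; restricting to one parent keeps
ancestor queries unambiguous and is a documented limitation — any
licensed vocabulary subset exported to the TSV shape can be dropped in.

## Feature engineering

* **srf filter.**  For each concept, `a`/`c` count the long/short
  *training* stays containing it and
  `srf = log2(2 + max(a/max(1,c), c/max(1,a)))`, a symmetric variant of
  relevance frequency with floor 1.  The cutoff derives from a prevalence
  threshold p: `log2(2 + (1-p)/p)`, i.e. 1.688 at p = 0.45; concepts at
  or below the cutoff are discarded.  Computing the counts on the
  training split only (rather than the full cohort) avoids leaking the
  test outcome through feature selection; the selected set is then frozen
  for the test transform.
* **ICD-10 roll-up.**  A code appearing in fewer than 5 training stays is
  replaced by its parent (one character shorter), never below 3
  characters.  Pooling is re-checked after every demotion, so a parent
  rescued by the counts of a child already rolled into it is not demoted
  further.  Demotion order is deterministic: longest code first, ties
  lexicographic; the iteration runs to a fix-point.  Test-time codes
  unseen in training map onto their longest known prefix, else encode as
  all zeros.
* **CCMU** becomes a single numeric column (digits unchanged, D → 6,
  P → 0).  The letter-to-number substitution implies an ordinal reading,
  which we follow; one-hot treatment is the obvious alternative and would
  only change how the forest splits the variable.
* **Recent-visit flag**: 1 iff the patient has another ED admission in
  the half-open window [entry − 7 d, entry).
* **Short-term ED activity index**: for each stay, the count k of cohort
  ED admissions in [entry − 7 d, entry), rescaled by the cohort's 1st and
  9th deciles of k (empirical quantiles, linear interpolation): 0 below
  d1, 1 above d9, linear in between.  If d1 = d9 the index degenerates to
  a constant 0.5 with a logged warning.  Both window features use
  operational timestamps only, never the outcome, so they are computed
  cohort-wide before the split.
* **Assembly.**  Gender, zip code (zips under 5 training occurrences pool
  into an "other" bucket, mirroring the ICD rarity rule), ward, GEMSA and
  rolled ICD codes are one-hot; concepts are multi-hot; age, ED LOS,
  CCMU, the flag and the index pass through numerically.  Unseen
  categories at transform time encode to all-zero rows in their block.

## Models and evaluation

Random forests are used because the feature space is high-dimensional,
binary-heavy and collinear (co-occurring concepts), with interaction-
shaped decision regions that linear or kernel models capture poorly.
Both models share one 80/20 split (|train| = round(0.8 n)); each is tuned
independently by uniform random search — 50 draws by default over
`n_estimators` ∈ [50, 500], `min_samples_split` ∈ [5, 50] (the lower
bound of 5 keeps splits possible on infrequent diagnosis codes) and
`min_samples_leaf` ∈ [1, 20] — scored by mean accuracy over 3 CV folds
that are fixed per model run and shared across all candidates.  These
range bounds are this package's reconstruction of a conventional forest
search space and are fully configurable.  The winner is refit on the full
training split; prediction is majority vote at 0.5 with no calibration.

Reported per model: confusion counts and recall, specificity, precision,
accuracy and F1 (long stay = positive), plus per-metric deltas, the
concordance (fraction of test stays with identical predictions, with the
2×2 agreement table), ranked impurity-based feature importances, and the
chosen hyperparameters.  The intensive-care subgroup analysis repeats the
entire procedure (own split, own tuning) within ICU-ward stays.  The
split is simple random by default — the 7-day threshold makes classes
near-balanced — with stratification available as an opt-in.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes;
its defaults are the study conditions: 5,000 stays over
2019-01-01..2019-09-24, post-ED ward stay log-normal
(location log 5.0, scale 0.8 on the log-day scale) truncated at > 2 days,
ED LOS log-normal with median 7.2 h, giving a total-LOS median ≈ 6 days
and ≈ 44% long stays; one ubiquitous concept at 98.3% prevalence; a mean
of ≈ 17 planted concepts per note; 15%/5% negated/family-context
mentions; 13% of stays given a same-patient prior visit within 7 days;
7.6% intensive-care stays; seasonally modulated arrivals so the activity
index varies.

A standard-normal latent severity ties everything together: it shifts
log-LOS linearly (`severity_effect`, default 0.8 log-days per SD — one SD
of severity multiplies LOS by ≈ 2.2, a strong but noisy link), raises the
planting probability of the informative concept leaves (logit shift 1.5
per SD), tilts the ICD-10 code distribution, and shifts age, CCMU, GEMSA
and the ICU probability.  With `severity_effect = 0` the outcome is pure
log-normal noise and no feature carries signal — the null-calibration
condition.  Concepts are planted only on thesaurus *leaves*, so a note's
ground-truth set is an antichain and extraction can be checked for exact
set equality; non-leaf terms still occur in text as substrings of their
children's terms, which exercises most-precise reduction.

What the generator does **not** emulate: realistic clinical language
(sentences are template-rendered), misspellings and abbreviations,
multi-parent vocabularies, clause-level negation scope, informative
missingness, and care-process feedback (e.g. crowding influencing LOS).
Passing tests therefore establish the correctness and internal
consistency of the pipeline — extraction exactness, leakage-free feature
fitting, metric identities, determinism, learnability when signal exists
and honest chance-level behaviour when it does not — not clinical
performance on real EHRs, whose headline numbers depend on data
unavailable here.

## Numerical and reproducibility choices

* One master seed derives all stage seeds (FNV-hashed stage names through
  `numpy.random.SeedSequence`, kept below 2³¹); two runs with the same
  config and seed produce byte-identical artifacts and manifests.
* Deciles and quantiles use numpy's linear-interpolation empirical
  quantile.
* Random-search ties keep the first-sampled candidate; overlapping match
  ties and demotion order are deterministic as described above.
* Degenerate inputs fail loudly (non-positive LOS, illegal CCMU symbols,
  codes shorter than 3 characters, single-class CV folds) rather than
  being silently coerced; the activity-index d1 = d9 case is the one
  soft fallback.
* Problem sizes in the shipped tests: unit and property tests run on a
  400-stay cohort; the learnability and null-calibration checks run the
  full 5,000-stay, 50-iteration configuration once each, which completes
  in a few minutes on a single CPU.
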