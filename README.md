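# edlos

Hospital length-of-stay (LOS) prediction for patients admitted through an
emergency department (ED), comparing what structured data (triage and
diagnosis codes) and unstructured data (clinical concepts extracted from
free-text ED notes) each contribute.  The package is aimed at health-data
scientists and hospital analytics teams who want a tested, reproducible
reference pipeline for this comparison, exercised end to end on a synthetic
EHR cohort with ground-truth annotations.

## What it does

The target is the binary **long stay** class, total LOS ≥ 7 days (the
cohort's approximate median, so classes are balanced).  Two random-forest
classifiers are trained on a shared 80/20 split:

* **structured model** — common features (age, gender, zip code, ED LOS,
  recent-visit flag, short-term ED activity index, post-ED ward) plus CCMU
  triage (digits kept, `D`→6, `P`→0), GEMSA, and the ICD-10 primary
  diagnosis rolled up the hierarchy until each surviving code has ≥ 5
  stays or 3 characters;
* **unstructured model** — the same common features plus a multi-hot block
  of clinical concepts extracted from the ED notes.

Concept extraction splits each note into sub-texts on punctuation,
classifies each sub-text into patient/family × affirmation/negation with
sentence-scope cue lexicons (neutral counts as affirmation), and keeps
exact, word-boundary matches of thesaurus terms in *patient-affirmation*
sub-texts only, reduced to the most precise concepts (a matched ancestor
of a matched concept is dropped).  High-prevalence concepts are filtered
by the symmetric relevance frequency

```
srf = log2(2 + max(a / max(1, c), c / max(1, a)))
```

where *a* and *c* count the long and short training stays containing the
concept; concepts with srf ≤ log2(2 + 55/45) = 1.688 (the 45% prevalence
threshold) are non-relevant.  Each model is tuned independently by random
search (50 draws over `n_estimators`, `min_samples_split` ≥ 5,
`min_samples_leaf`) scored by mean accuracy over 3 shared CV folds.

Because no public cohort exists for this design, the package ships a
first-class synthetic generator: ~5,000 ED-admitted stays over a
nine-month window, long-tailed LOS (median ≈ 6 days) driven by a latent
severity, notes with ~17 planted concepts (one at ~98% prevalence),
negated and family-context sentences, and ~13% of stays with a recent
prior visit.  The planted ground truth makes the extraction pipeline
exactly testable.

## Worked example

`python examples/04_compare_models.py` (1,000 stays, small search budget)
prints:

```
train/test: 800/200, majority-class rate 55.0%

metric        structured  unstructured  delta (pts)
recall            52.2%        58.9%        +6.67
specificity       76.4%        80.0%        +3.64
precision         64.4%        70.7%        +6.28
accuracy          65.5%        70.5%        +5.00
f1                57.7%        64.2%        +6.57

concordance: 74.0% of test stays got the same prediction
```

Both models clear the 55% majority baseline, the note-based model a bit
more clearly here, and the concordance line shows how often the two agree
on the same patient.  `examples/01–03` walk the generator, the extraction
steps and the individual feature operations with commentary.

The same pipeline is available as a CLI:

```
edlos run-all --out run/ --seed 42        # simulate -> extract -> features -> compare
edlos simulate --out run/ --seed 42       # individual stages, plus
edlos extract / features / compare / validate / show-config
```

Every run is a deterministic function of the master seed; `run-all`
writes a manifest with per-artifact checksums, and two runs with the
same seed are byte-identical.

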