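# Methods

## The phenotyping model

`adhdpheno` implements a deterministic, rule-based phenotyping algorithm for
pediatric ADHD and eleven psychiatric or related comorbidities (anxiety,
autism, major depression, ODD, conduct disorder, tic disorder, Tourette
syndrome, schizophrenia/psychosis, bipolar disorder, mild/moderate
intellectual disability, learning disability) over longitudinal EHR
extracts.  The algorithm is multi-source on purpose: pediatric EHR charts
are fragmented, and any single evidence stream (diagnosis codes,
prescriptions, or abstracted notes) misses real cases.  A subject qualifies
for a condition when any of five paths holds, each demanding more than one
"hit" on distinct calendar days:

1. at least `min_distinct_days` (default 2) distinct diagnosis days with a
   qualifying ICD-9/ICD-10-CM code;
2. at least two distinct qualifying medication days;
3. one diagnosis day and one medication day on *different* calendar days;
4. one medication day plus an abstraction hit;
5. one diagnosis day plus an abstraction hit.

Paths 2–3 apply only where a medication criterion is clinically meaningful
(ADHD, anxiety, schizophrenia, bipolar).  The multi-hit requirement is the
algorithm's main defense against stray codes and against keyword false
positives in notes.

Key temporal/filtering rules:

* **Minimum diagnosis age (ADHD).** Diagnosis events before the fourth
  birthday never count, consistent with pediatric practice guidelines.  Age
  is whole completed years at the *event* date; for the control age floor it
  is completed years at the record's extraction date.  The reference dates
  are configurable because source systems differ on this convention.
* **Gap window (major depression, bipolar disorder).** The two qualifying
  diagnosis days must include at least one pair separated by 30–180 days
  (inclusive).  *Any* pair of distinct days may satisfy the window:
  requiring all pairs inside it would reject long-followed true cases.
* **Per-event medication exclusions.** Orders filed under the EHR
  pharmacologic classes "cardiovascular agents" or "analgesics" never count
  (clonidine ordered for hypertension is not ADHD evidence), and
  benzodiazepines never count toward anxiety (commonly peri-procedural in
  children).  The class filter is per event, not per patient, so a patient
  can hold both excluded clonidine orders and countable stimulant orders.
* **Case exclusion precedence.** Any diagnosis consistent with neuronal
  damage, CNS neoplasm or infection, severe/profound intellectual
  disability, or TBI removes the subject from the case pool regardless of
  other evidence; the triggering prefixes are reported.
* **Controls.** Age ≥ 8 at extraction (below that, ADHD may simply not have
  been diagnosable yet), no psychiatric/neurological codes, medications or
  keyword mentions, no chromosomal anomalies or genetic syndromes.  Learning
  disability and mild/moderate ID codes do **not** disqualify controls.
* **Status partition.** Every subject gets exactly one of case / control /
  excluded; subjects with some psychiatric evidence but no full
  qualification land in the excluded pool.

### Text mining

The note matcher is deliberately primitive: case-insensitive whole-phrase
matching on word boundaries, no stemming, no fuzzy matching, and no negation
handling — "patient does not have ADHD" yields a phenotype hit.  This is a
faithful model of simple keyword abstraction search; the multi-hit inclusion
criteria are the compensating control.  A config flag reserves room for a
negation filter but defaults off, because the ablation behaviour of the
pipeline (keywords adding no cases) is only meaningful under the primitive
matcher.

### Confidence scoring

Each ADHD case receives `total = diag_days + med_days + abs_phenotype +
abs_medication + therapy` (the last three 0/1) and a source count in 1..5.
High: total ≥ 20, or total > 9 with 4–5 sources, or (> 9 diagnosis days or
> 9 medication days) with 2–3 sources.  Low: diag + med = 2 with total < 3,
or zero diagnosis days, total < 10, > 2 medication days and no abstraction
sources.  Moderate: the rest.  The high and low predicates are disjoint
(the test suite proves this by exhausting diag/med ∈ 0..40 × all indicator
combinations), so evaluation order is cosmetic.  "No abstraction sources"
is read as both abstraction indicators zero; therapy participation is *not*
an abstraction source by default (it is not located in the psych
abstraction), with a flag to flip that reading.  The score measures
evidence accumulation, not severity.

### Ablation

The search-method comparison re-runs the *unchanged* engine under evidence
channel masks (diagnosis codes; structured medications; phenotype-keyword
note hits; all note hits), rather than maintaining separate code paths.
Counts are therefore guaranteed consistent with the full pipeline, and
monotone as channels are added.

### Validation

PPV is estimated by drawing review samples without replacement from
algorithm-positive strata (per condition, per ADHD+comorbidity combination,
and the control stratum) and comparing against a gold-standard table — the
generator's planted labels in simulation, a chart-review adjudication file
in real use; one interface for both.  Intervals are exact Clopper–Pearson:
review samples of ~15 are far too small for normal approximations.

## The synthetic cohort generator

The generator emulates a pediatric biorepository extract: ages truncated
normal (mean 11, SD 6, range 1–21), ~51.4% male, a fixed extraction date,
and per-patient condition labels with odds-multiplier coupling of each
comorbidity to ADHD.  Planted positives receive event streams that satisfy
the shipped rules by construction (ADHD diagnosis days after age 4,
depression/bipolar day pairs inside the 30–180-day window, benzodiazepine
orders planted as non-counting).  ADHD records come in four shapes:
standard (≥ 2 diagnosis days), medication-only (no ICD codes at all —
fragmentation), single-diagnosis-plus-medication, and abstraction-only
(one code plus a medication mention in a note).  Qualifying day counts are
`minimum + NegativeBinomial(r = 1.2, mean 5)`: overdispersed visit counts
are the norm in longitudinal pediatric records, and the published source
offers no per-case day-count distribution, so this is an implementer
choice recorded in config.

Noise knobs, all zero by default (*clean mode*):

* `noise_single_code_rate` — a stray psychiatric code on a truly
  unaffected patient (neither case- nor control-compatible);
* `negation_fraction` — negated keyword phrases in notes, exercising the
  matcher's negation blindness; combined with a stray code this produces
  genuine false-positive cases;
* `case_false_positive_rate` — planted algorithm-positive records whose
  gold adjudication is negative (what chart review catches);
* `silent_record_rate` — true cases with no structured evidence (care
  received elsewhere), which contaminate the control pool;
* `exclusion_code_rate`, `benign_ld_code_rate` — exclusionary diagnoses
  and innocuous learning-disability codes (these are *not* noise: gold
  labels stay consistent with them).

In clean mode the planted labels are exactly identifiable, and the test
suite asserts sensitivity = specificity = PPV = 1 for all 12 conditions on
a 5,000-patient cohort.  What that does and does not show: it validates the
engine's logic against the generator's contract, not the algorithm's
accuracy on real charts — real EHRs have coding idiosyncrasies, cross-system
fragmentation and note styles the generator does not model.  Notes are
planted so that phenotype-keyword sentences accompany fully coded
diagnoses while medication mentions accompany prescriptions; hence in clean
mode the keyword channel adds no cases over the diagnosis channel, which is
the behaviour the ablation is designed to surface.

Default code/keyword/medication lists are curated stand-ins for
institution-specific supplementary tables (which are not public).  They are
kept pairwise disjoint across conditions — e.g. mood stabilizers under
bipolar, antipsychotics under schizophrenia only — so that planted evidence
is unambiguous; real formularies overlap, and a site deploying the pipeline
should substitute its own lists via the YAML config.

The `preset_paper_like` configuration calibrates marginals to a published
pediatric cohort's structure: ADHD planted at 11% of subjects, ~54% of ADHD
cases comorbid with anxiety the most coupled (~27% of ADHD cases), ~69%
abstraction availability, 11.5% medication-only ADHD records, a 5%
chart-review false-positive rate and an 18% silent-record rate.  Because
comorbidities are conditionally independent given ADHD in the generator,
the non-anxiety conditional prevalences are jointly scaled so the isolated
fraction lands near 46%; per-condition percentages are therefore
calibration, not targets.

## Numerical and design notes

* ICD codes normalize to uppercase with a single dot after the third
  character; dotless extract dialects ("31401") and dotted rules ("314.")
  therefore match stably.  Normalization is idempotent.
* Percentages in report tables round half-up (`decimal`), matching printed
  clinical tables; floating-point bankers' rounding would differ on exact
  halves.
* Dates are calendar dates throughout; "distinct days" means distinct
  dates, so same-day duplicate events collapse everywhere.
* Review sampling and the generator use `numpy.random.default_rng` seeded
  explicitly; identical configs give byte-identical cohort files.
* Degenerate inputs: empty event tables are valid (zero events, no error);
  an empty ADHD case list yields an all-zero confidence distribution with a
  warning; an empty review stratum yields an empty sample with a warning;
  a zero denominator in `percent` raises.
* Problem sizes in the shipped tests and the acceptance script (cohorts of
  1,500–6,000 patients, review samples of 250–400) were chosen so every
  binomial check is informative while a full run stays interactive on one
  CPU.

## Known limitations

* No negation or context handling in text mining (by design; see above).
* No RxNorm/SNOMED normalization: drug matching is lowercase exact-name,
  class labels are the EHR's own strings.
* No adjudication of which diagnosis is "primary" for comorbid cases.
* The comorbidity coupling model is single-factor (ADHD); clustering among
  comorbidities themselves is not modeled.
* Confidence-class proportions produced by the preset depend strongly on
  the assumed day-count distribution and should not be read as estimates of
  any real cohort's mix.
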