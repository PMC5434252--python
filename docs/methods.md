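# Methods

This note documents the models, rules, and design choices behind `sdrec`,
in the spirit of a statistical package's methods appendix: what is computed,
under which conventions, and what the synthetic data does and does not show.

## The record model and its two access structures

A record is a patient (demographics: age, sex, education level, years since
diagnosis, treatment regimen) plus a strictly date-ordered sequence of
visits; a visit holds symptom observations, medication orders (dose, unit,
frequency, timing), and lab results. One visit per calendar date: the date
is the session key. Dates are Gregorian ISO 8601 throughout; calendar
display conventions (e.g. Jalali) are a rendering concern left outside the
engine.

The **session view** partitions one visit's entries into three fixed
columns — *symptoms and diseases*, *medication*, *lab tests*. The first
column merges the schema categories `symptoms` and `medical_history`:
patients do not distinguish a reported symptom from a standing diagnosis
when browsing a visit, and the merged column is the only mapping consistent
with keeping the other two columns homogeneous. The partition is lossless:
every recorded entry appears in exactly one column (property-tested over
1,000+ random visits).

The **topic timeline** is the per-item chronology. Its value is the lab
value for lab items, the dose for medication orders, and a 0/1 presence
flag for symptoms and diseases. The rendered view adds a trend label
computed from the first vs last point: `n/a` with fewer than two points,
`stable` when the relative change |(last − first)/first| ≤ 5%, otherwise
`rising`/`falling`. The 5% threshold is a documented display constant, not
a clinical claim; it exists so the label is exact and testable. A
first value of zero falls back to the sign of the last value.

## The minimum dataset

The MDS is the closed catalogue of recordable items: five categories
(demographic, symptoms, medical_history, medication, lab_tests), each item
with a stable slug id, display label, value kind (`flag`, `coded`,
`quantity`), a unit exactly when the kind is quantity, and an inclusive
reference range for lab items only. Reference ranges live in the schema —
not in the content library — so lab interpretation has a single source of
truth and works even for items without authored content.

The packaged fixture carries 110 items split 10/25/15/45/15. The item
*names* are synthesized but clinically plausible (common diabetes symptoms,
oral hypoglycemics and insulins, standard chemistry panels); the counts and
category structure are the load-bearing part. No mapping to ICD/ATC/LOINC
is attempted — ids are package-local slugs used as join keys between
records and content.

## Content entries and validation

A content entry per item provides: ordered *general levels* (each a list of
named sections), a *tailored template*, slot bindings, and applicability
conditions. Required sections per category:

| category | required sections |
| --- | --- |
| symptoms | definition, diagnostic_symptoms, causes, advice |
| medication | side_effects, dosage, administration_and_use |
| lab_tests | definition, normal_range, patient_status |
| medical_history | definition, causes, advice |

The first three follow the question concepts patients actually raise about
each group; the disease structure is a minimal consistent choice (diseases
attract the same "what is it / why / what do I do" questions as symptoms,
minus the diagnostic checklist). Demographic items carry no content.

Validation is *total*: `validate_entry` returns a deterministic issue list
(missing sections per level, unbound template slots, category mismatches,
unknown ids) and never raises on parseable input; `load_library` rejects
documents with any issue. The condition language is a flat AND-list of
(field, op, value) comparisons with ops eq/ne/lt/le/gt/ge/present/absent —
no OR or nesting, which keeps authoring and evaluation trivially auditable.
An unresolvable field makes comparison ops false, `present` false, and
`absent` true.

Because no published content corpus exists, `build_placeholder_library`
synthesizes a full-coverage English placeholder library from any MDS; it is
first-class, validated content (round-trips through serialize/load) used by
the tests, the CLI default, and any caller that needs structural coverage
before authoring. All text handling is plain Unicode with no
locale-dependent formatting, so Persian or any RTL corpus substitutes
without engine changes.

## The tailoring engine

The **patient profile** (the user model) is a read-only projection of the
record as of a visit date: demographics, the latest lab value and latest
medication order per item, and per-item exposure counts. Condition fields
range over exactly these paths (`age`, `regimen`, `labs.<id>.value`,
`medications.<id>.dose_value`, `exposure.<id>`, …) — a deliberately
record-bounded vocabulary.

For one recorded item at one visit, `explain_item` produces:

* **level selection** — `level_used = min(1 + prior, L)` where `prior` is
  the number of *earlier visits at which the item was recorded* and L the
  entry's level count. Counting recorded visits (rather than document
  generations) makes leveling a pure function of the record, hence
  reproducible; it is non-decreasing per item across a patient's visits and
  capped at L.
* **general tier** — the sections of `general_levels[level_used]`, included
  only when every condition holds. A failed condition yields status
  `not_applicable`: the item is still shown with its tailored tier (the
  record view must list what was recorded), only the canned text is
  withheld.
* **tailored tier** — the template rendered by slot substitution.
  Slots use Python-format syntax (`{slot}`, `{{` for a literal brace),
  parsed with `string.Formatter`. A slot bound to a whole lab result or
  medication order renders as "value unit" ("170.9 mg/dL"); one bound to a
  bare numeric field renders the number alone, locale-free (decimal point,
  no thousands separator), so templates control their own phrasing.
  *Strict* mode (default) raises on any missing value — printed booklets
  must not ship silent blanks; *lenient* mode substitutes a visible
  `[missing: slot]` marker. For lab items with a reference range the engine
  appends the interpretation sentence to the tailored tier.
* **lab interpretation** — trichotomy below/within/above with *inclusive*
  boundaries (a value equal to either bound is within range, matching
  clinical convention for "normal range"); degenerate ranges (low ≥ high)
  are rejected. Status is monotone in the value for a fixed range.

`generate_document` maps this over every recorded item of every visit in
date order (symptoms, then medications, then labs within a visit). Items
without a library entry are collected into a missing-content appendix
rather than silently dropped. The document is a pure function of
(record, library, MDS, mode): byte-identical inputs give byte-identical
output, and no item ever appears that is not in the record (the tailoring
guarantee). Correctness of the assembly is checked against an independent
brute-force enumeration of (visit × item × content) outcomes over an
exhaustive grid of small records.

## Rendering

Views are emitted from a common block structure to Markdown or HTML.
Anchors use explicit `<a id="exp-<date>-<item>">` targets so session-view
links resolve inside the booklet built from the same record in either
format. The booklet orders: title, table of contents, one section per visit
with one subsection per explanation (general tier before tailored tier),
appendix last. Rendering never rewrites explanation text (substring
containment is tested). Print/PDF conversion is left to external tools.

## Quality-checklist aggregation

Ratings are 1–5 integers over item groups {symptoms, diseases, drugs,
tests} and one criterion family — clinician {accuracy, simplicity,
usefulness, adequacy} or patient {comprehensibility, practicality,
essentiality, novelty}; the two families share all machinery. Per-cell
statistics are the arithmetic mean and the **population** standard
deviation (divisor n): with three raters per cell the divisor choice is
material, is not externally fixed, and is therefore isolated in one line of
`aggregate_ratings` and documented here. Summary totals are unweighted
means of the four cell means per row/column, kept at full precision and
**truncated** (floored) at one decimal for display — truncation, not
round-half-up, is the rule under which all eight published totals of the
clinician table are consistent with their sixteen cells (e.g. 4.475 → 4.4,
4.95 → 4.9), and the tests verify all eight. The floor applies a 1e-9
guard so means exactly representable at one decimal are not pushed down by
binary float noise. Inter-rater reliability statistics are out of scope.

## Synthetic cohort

`generate_cohort` emulates the pilot cohort profile so the whole pipeline
is testable without real data:

| parameter | default | why |
| --- | --- | --- |
| age | uniform integers 58–68 | mean exactly 63, support inside the reported 57–68 range; the simplest distribution consistent with the reported mean and range |
| regimen | drug + insulin with p = 5/8 | the pilot's 5 of 8 patients |
| education | below diploma with p = 5/8 | the pilot's 5 of 8 patients |
| years since diagnosis | Normal(12, 4), clipped to [1, age] | reported mean 12; SD chosen as a plausible spread |
| visits per patient | uniform integers 2–4 | a short pilot-scale follow-up window |
| symptom prevalence | 0.12 per item per visit | yields a few symptoms per visit over 40 symptom/history items |
| labs per visit | 5–8, always FBS and HbA1c | core diabetes monitoring plus a rotating panel |
| FBS | Normal(150, 30) mg/dL, drift −3/visit | plausibly elevated diabetic values; mild improvement under care |
| other labs | Normal(mid + width/4, width/4) from the item's reference range | skews values high so all three interpretation branches occur |

All draws flow through one `numpy.random.default_rng(seed)` stream (with
per-patient child seeds), giving byte-identical cohorts for a fixed seed
across platforms. Insulin-regimen patients always carry at least one
insulin order; drug-only patients never do.

What the generator does **not** emulate: disease progression or treatment
effects (the drift is cosmetic), correlations between labs, seasonal or
adherence effects, missingness patterns of paper records, or the ambiguous
"affliction with consequences" cohort variable. Consequently, passing
tests demonstrate engine correctness (validation, partitioning, tailoring,
determinism) — not clinical realism of the generated trajectories, and not
content quality, which requires authored corpora and human raters.

## Numerical and degenerate-input conventions

* Reference-range boundaries inclusive; `low < high` enforced at schema
  load and again at interpretation.
* Quantities render via `str(int)` for integral values, else `%.10g`.
* Empty records produce empty (but well-formed) documents and booklets;
  empty session columns render as "(none recorded)" rather than vanishing.
* `add_visit` is functional — it returns a new record and can never leave
  the original in a half-updated state; duplicate visit dates are errors.
* Ties in leveling cannot occur (exposure counting is integer); template
  rendering has no ordering freedom, so documents are reproducible without
  any tie-break rules.

## Problem sizes

The default test suite and the acceptance script use cohorts of up to
10,000 patients for demographic convergence checks (binomial 99% CI on the
insulin fraction, ±0.5 years on mean age) and a few hundred records for
behavioural property sweeps; the exhaustive document-assembly oracle runs
over all per-visit item subsets from a fixed 6-mask set at 1–3 visits
(258 records per regimen). These sizes make every statistical check
well-powered while keeping a full run in well under a minute.

## Known limitations

* The condition vocabulary is a superset guess constrained to record
  fields; deployed systems may need richer predicates (e.g. value deltas).
* One content entry per item: variants (several insulins sharing prose)
  must duplicate entries.
* The booklet's "visual abstract" is a table plus trend label, not a plot.
* No authentication, doctor/patient mode switching, messaging, or mobile
  delivery — engine only.
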