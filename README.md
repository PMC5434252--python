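# sdrec — self-describing diabetes medical records

`sdrec` is a tailoring engine for patient education grounded in the medical
record. The idea: every item a clinician records at a diabetes visit — a
symptom, a drug order, a lab result — should be *self-describing* for the
patient who reads it, linking to a two-tier explanation:

1. a **general tier** of pre-authored ("canned") content about the item,
   retrieved from a content library when its applicability conditions hold
   against the patient's profile, with a level of detail that deepens as the
   item recurs across visits;
2. a **tailored tier** generated by shallow, fill-in-the-blank natural
   language generation: a sentence template whose named `{slot}` blanks are
   filled from that patient's own record ("Take 10 units of Insulin Regular
   once daily, before breakfast."). For a lab result the tier also embeds a
   reference-range interpretation — the value *v* is classified against the
   item's normal range *(low, high)* as **below** (*v* < low), **within**
   (low ≤ *v* ≤ high, boundaries inclusive), or **above** (*v* > high).

It is aimed at clinical-informatics researchers and developers building
patient-accessible EMR views and print-based tailored education materials,
particularly for chronic-disease (diabetes) care.

## What's inside

| module | role |
| --- | --- |
| `sdrec.mds_schema` | the diabetes **minimum dataset**: a validated catalogue of 110 recordable items in five categories (10 demographic, 25 symptoms, 15 medical history, 45 medication, 15 lab tests), with per-item value semantics, units, and lab reference ranges |
| `sdrec.record_model` | longitudinal patient records (visits with symptoms, medication orders, lab results), plus the two patient access structures: the **session view** (one visit partitioned into symptoms-and-diseases / medication / lab-tests columns) and the **topic timeline** (one item's chronology) |
| `sdrec.content_library` | per-item education content: leveled general sections (symptoms need definition/diagnostic symptoms/causes/advice; drugs need side effects/dosage/administration; labs need definition/normal range/patient status), a slot template, and AND-list applicability conditions |
| `sdrec.tailoring_engine` | condition evaluation, lab interpretation, slot filling (strict or lenient), per-item explanations, and whole-document assembly |
| `sdrec.record_views` | deterministic Markdown/HTML rendering: session view, topic timeline with a trend label (stable when the first-to-last relative change is ≤ 5%), and the printable booklet with table of contents and missing-content appendix |
| `sdrec.quality_eval` | 1–5 Likert checklist aggregation into an item-group × criterion matrix of means and population SDs, summarized with unweighted totals truncated to one decimal for display |
| `sdrec.synthetic_cohort` | seeded generation of records emulating the pilot cohort (mean age 63, 5/8 on drug + insulin, 5/8 below-diploma education, ~12 years since diagnosis) |
| `sdrec.taxonomy` | the need-analysis question taxonomy: nine thematic categories of patient questions, four of them answerable from the record |

## Worked example

Generate a synthetic patient, then ask for the explanation of their fasting
blood sugar:

```bash
$ sdrec simulate --n 1 --seed 4 --out demo
wrote 1 records to demo (mean age 65.00)
$ sdrec explain demo/synthetic-00000.yaml fbs
# Fasting blood sugar (FBS) (2016-11-11) [ok]

General explanation (level 2):
- definition: Definition for Fasting blood sugar (FBS): placeholder explanation text. More detailed follow-up material for repeat readers.
- normal range: Normal range for Fasting blood sugar (FBS): placeholder explanation text. More detailed follow-up material for repeat readers.
- patient status: Patient status for Fasting blood sugar (FBS): placeholder explanation text. More detailed follow-up material for repeat readers.

About you:
Your result for Fasting blood sugar (FBS) on 2016-11-11 was 170.9 mg/dL. Your value of 170.9 mg/dL is above the normal range (70-100 mg/dL).
```

Reading the output: by 2016-11-11 this patient had already had FBS explained
at earlier visits, so the general tier is served at level 2 (the deeper
follow-up material). The tailored tier is the filled template plus the
range interpretation: 170.9 mg/dL exceeds the 70–100 mg/dL reference range,
hence **above**. The packaged content is English placeholder prose — the
engine treats text as opaque Unicode, so authored content in any language
(including right-to-left scripts) drops in unchanged.

The topic timeline shows the same item's chronology with a trend label
computed from the first vs last value (here +37%, hence *rising*):

```bash
$ sdrec timeline demo/synthetic-00000.yaml fbs
# Timeline: Fasting blood sugar (FBS)

| Date | Value |
| --- | --- |
| 2016-06-18 | 124.4 mg/dL |
| 2016-08-17 | 224.9 mg/dL |
| 2016-09-25 | 128.2 mg/dL |
| 2016-11-11 | 170.9 mg/dL |

Trend: rising
```

`sdrec booklet demo/synthetic-00000.yaml -o booklet.md` assembles the full
personalized document — every recorded item of every visit, in date order,
with a table of contents and an appendix of items lacking content — ready
for printing. `sdrec qa ratings.csv` aggregates quality-checklist scores,
and `sdrec validate` / `sdrec session` cover record validation and the
per-visit view.

## Scope notes

The package models the record engine, content pipeline, and rendering; it
deliberately excludes GUI/web serving, authentication, appointment
scheduling, deep NLG (aggregation, referring expressions), and psychological
tailoring dimensions. See `docs/methods.md` for the design rationale and
limitations.
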