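import datetime as dt
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdrec import (
    Condition,
    Demographics,
    MedicalRecord,
    TailoringError,
    evaluate_conditions,
    explain_item,
    fill_template,
    generate_document,
    interpret_lab,
)
from sdrec.tailoring_engine import PatientProfile, format_quantity, prior_exposure

from conftest import make_visit


@pytest.fixture
def profile(toy_record, mds):
    return PatientProfile.from_record(toy_record, mds)


class TestEvaluateConditions:
    def test_empty_conjunction_is_true(self, profile):
        assert evaluate_conditions([], profile) is True

    def test_single_comparison(self, profile):
        cond = Condition(field="regimen", op="eq", value="drug_plus_insulin")
        assert evaluate_conditions([cond], profile) is True

    def test_conjunction_fails_when_one_term_fails(self, profile):
        # age 63 satisfies the first term; regimen drug_plus_insulin fails the second
        conds = [
            Condition(field="age", op="ge", value=60),
            Condition(field="regimen", op="eq", value="drug_only"),
        ]
        assert evaluate_conditions(conds, profile) is False

    def test_missing_field_fails_comparisons_but_satisfies_absent(self, profile):
        assert evaluate_conditions([Condition(field="labs.tsh.value", op="gt", value=1)], profile) is False
        assert evaluate_conditions([Condition(field="labs.tsh.value", op="absent")], profile) is True
        assert evaluate_conditions([Condition(field="labs.fbs.value", op="present")], profile) is True

    def test_numeric_threshold_on_latest_lab(self, profile):
        # latest FBS is 150 (second visit), not 130
        assert evaluate_conditions([Condition(field="labs.fbs.value", op="gt", value=140)], profile)


class TestInterpretLab:
    @pytest.mark.parametrize(
        "value, expected",
        [(85, "within"), (130, "above"), (100, "within"), (70, "within"), (69.9, "below")],
    )
    def test_classification_with_inclusive_boundaries(self, value, expected):
        assert interpret_lab(value, (70, 100)).status == expected

    def test_message_names_status_and_range(self):
        interp = interpret_lab(130, (70, 100), unit="mg/dL")
        assert "above" in interp.message
        assert "70-100 mg/dL" in interp.message

    def test_degenerate_range_is_an_error(self):
        with pytest.raises(TailoringError):
            interpret_lab(50, (100, 100))

    def test_trichotomy_and_monotonicity_over_sweep(self):
        low, high = 70.0, 100.0
        statuses = []
        for value in [low + 0.5 * k for k in range(-30, 91)]:
            status = interpret_lab(value, (low, high)).status
            assert status in ("below", "within", "above")
            statuses.append(status)
        # monotone in value: below* within* above*
        order = {"below": 0, "within": 1, "above": 2}
        ranks = [order[s] for s in statuses]
        assert ranks == sorted(ranks)
        assert set(statuses) == {"below", "within", "above"}

    @settings(derandomize=True, max_examples=200)
    @given(
        value=st.floats(-1e6, 1e6, allow_nan=False),
        low=st.floats(-1e3, 1e3, allow_nan=False),
        width=st.floats(0.1, 1e3, allow_nan=False),
    )
    def test_status_consistent_with_value_everywhere(self, value, low, width):
        interp = interpret_lab(value, (low, low + width))
        if value < low:
            assert interp.status == "below"
        elif value > low + width:
            assert interp.status == "above"
        else:
            assert interp.status == "within"


class TestFillTemplate:
    def test_direct_substitution(self):
        text, slots = fill_template(
            "Take {dose} units of {drug} {timing}.",
            {"dose": "dose", "drug": "drug", "timing": "timing"},
            {"dose": 10, "drug": "Insulin Regular", "timing": "before breakfast"},
        )
        assert text == "Take 10 units of Insulin Regular before breakfast."
        assert slots["dose"].value == "10"

    def test_template_without_slots_is_identity(self):
        text, slots = fill_template("Nothing to fill here.", {}, {})
        assert text == "Nothing to fill here."
        assert slots == {}

    def test_doubled_braces_render_literally(self):
        text, _ = fill_template("literal {{x}} and {a}", {"a": "a"}, {"a": 1})
        assert text == "literal {x} and 1"

    def test_strict_mode_missing_value_names_the_slot(self):
        with pytest.raises(TailoringError, match="dose"):
            fill_template("Take {dose}.", {"dose": "entry.dose_value"}, {"entry": {}})

    def test_lenient_mode_substitutes_visible_marker(self):
        text, _ = fill_template(
            "Take {dose}.", {"dose": "entry.dose_value"}, {"entry": {}}, mode="lenient"
        )
        assert "[missing: dose]" in text

    def test_no_unresolved_slots_remain_in_strict_mode(self, toy_record, library, mds):
        doc = generate_document(toy_record, library, mds, mode="strict")
        for exp in doc.all_explanations():
            assert "{" not in exp.tailored_text.replace("{{", "")


class TestFormatQuantity:
    @pytest.mark.parametrize(
        "value, expected",
        [(10, "10"), (10.0, "10"), (4.5, "4.5"), (1234.5, "1234.5"), (True, "yes")],
    )
    def test_locale_free_rendering(self, value, expected):
        assert format_quantity(value) == expected


class TestExplainItem:
    def test_insulin_explanation_has_both_tiers(self, toy_record, library, mds):
        exp = explain_item(toy_record, dt.date(2016, 6, 1), "insulin_regular", library, mds)
        assert exp.status == "ok"
        assert exp.general_sections  # drug sections: side effects, dosage, use
        assert {s.name for s in exp.general_sections} == {
            "side_effects", "dosage", "administration_and_use",
        }
        assert exp.tailored_text == "Take 10 units of Insulin Regular once daily, before breakfast."
        assert set(exp.slots_used) == {"dose", "unit", "drug", "frequency", "timing"}

    def test_lab_tailored_tier_embeds_interpretation(self, toy_record, library, mds):
        exp = explain_item(toy_record, dt.date(2016, 6, 1), "fbs", library, mds)
        assert "130 mg/dL" in exp.tailored_text
        assert "above" in exp.tailored_text

    def test_level_advances_with_repeat_exposure(self, toy_record, library, mds):
        # the blood-sugar entry has two general levels; FBS is recorded at both visits
        first = explain_item(toy_record, dt.date(2016, 6, 1), "fbs", library, mds)
        second = explain_item(toy_record, dt.date(2016, 7, 1), "fbs", library, mds)
        assert (first.level_used, second.level_used) == (1, 2)
        assert first.general_sections != second.general_sections

    def test_level_is_capped_at_max_level(self, demographics, library, mds):
        visits = tuple(
            make_visit(dt.date(2016, 6, 1 + 7 * i), lab_specs=[("cholesterol_total", 210, "mg/dL")])
            for i in range(4)
        )
        rec = MedicalRecord(patient_id="p", demographics=demographics, visits=visits)
        levels = [
            explain_item(rec, v.date, "cholesterol_total", library, mds).level_used for v in visits
        ]
        assert levels == [1, 2, 2, 2]
        assert levels == sorted(levels)  # non-decreasing across successive visits

    def test_missing_content_is_a_signal_not_a_crash(self, toy_record, library, mds):
        stripped = library.model_copy(
            update={"entries": {k: v for k, v in library.entries.items() if k != "polyuria"}}
        )
        exp = explain_item(toy_record, dt.date(2016, 6, 1), "polyuria", stripped, mds)
        assert exp.status == "content_missing"
        assert exp.general_sections == () and exp.tailored_text == ""

    def test_failed_conditions_yield_not_applicable_with_tailored_tier(self, library, mds):
        # drug-only patient with an insulin order: insulin canned text is gated out
        demo = Demographics(age=60, sex="male", education_level="diploma_or_above",
                            years_since_diagnosis=5, regimen="drug_only")
        visit = make_visit(dt.date(2016, 6, 1), med_specs=[("insulin_regular", 8, "units")])
        rec = MedicalRecord(patient_id="p", demographics=demo, visits=(visit,))
        exp = explain_item(rec, visit.date, "insulin_regular", library, mds)
        assert exp.status == "not_applicable"
        assert exp.general_sections == ()
        assert "8 units" in exp.tailored_text

    def test_item_not_recorded_at_visit_is_an_error(self, toy_record, library, mds):
        with pytest.raises(Exception, match="not recorded"):
            explain_item(toy_record, dt.date(2016, 7, 1), "metformin", library, mds)


class TestGenerateDocument:
    def test_counts_with_full_coverage(self, toy_record, library, mds):
        doc = generate_document(toy_record, library, mds)
        assert len(doc.all_explanations()) == 6  # 4 items visit 1 + 2 items visit 2
        assert doc.missing_content == ()

    def test_missing_content_moves_item_to_appendix(self, toy_record, library, mds):
        stripped = library.model_copy(
            update={"entries": {k: v for k, v in library.entries.items() if k != "polyuria"}}
        )
        doc = generate_document(toy_record, stripped, mds)
        assert len(doc.all_explanations()) == 5
        assert doc.missing_content == ((dt.date(2016, 6, 1), "polyuria"),)

    def test_empty_record_gives_empty_document(self, demographics, library, mds):
        rec = MedicalRecord(patient_id="p", demographics=demographics)
        doc = generate_document(rec, library, mds)
        assert doc.visits == () and doc.missing_content == ()

    def test_relevance_no_content_leaks_in(self, toy_record, library, mds):
        recorded = {i for v in toy_record.visits for i in v.recorded_item_ids()}
        doc = generate_document(toy_record, library, mds)
        assert {e.item_id for e in doc.all_explanations()} <= recorded

    def test_determinism(self, toy_record, library, mds):
        assert generate_document(toy_record, library, mds) == generate_document(
            toy_record, library, mds
        )


# -- brute-force oracle -------------------------------------------------------

GRID_ITEMS = ("polyuria", "hypertension", "metformin", "insulin_regular", "fbs")


def build_grid_record(demographics, masks):
    """One record from a tuple of per-visit item bitmasks over GRID_ITEMS."""
    visits = []
    for i, mask in enumerate(masks):
        chosen = [GRID_ITEMS[b] for b in range(5) if mask >> b & 1]
        visits.append(
            make_visit(
                dt.date(2016, 6, 1) + dt.timedelta(days=30 * i),
                symptom_ids=[c for c in chosen if c in ("polyuria", "hypertension")],
                med_specs=[(c, 500 if c == "metformin" else 10, "mg" if c == "metformin" else "units")
                           for c in chosen if c in ("metformin", "insulin_regular")],
                lab_specs=[("fbs", 120.0 + 10 * i, "mg/dL")] if "fbs" in chosen else [],
            )
        )
    return MedicalRecord(patient_id="grid", demographics=demographics, visits=tuple(visits))


def oracle_explanations(record, library, mds):
    """Independent enumeration of (visit x item x content) outcomes."""
    rows, missing = [], []
    for visit in sorted(record.visits, key=lambda v: v.date):
        ids = (
            [s.item_id for s in visit.symptoms]
            + [m.item_id for m in visit.medications]
            + [l.item_id for l in visit.labs]
        )
        for item_id in ids:
            entry = library.get(item_id)
            if entry is None:
                missing.append((visit.date, item_id))
                continue
            profile = PatientProfile.from_record(record, mds, as_of=visit.date)
            status = "ok" if evaluate_conditions(entry.conditions, profile) else "not_applicable"
            level = min(1 + prior_exposure(record, item_id, visit.date), entry.max_level)
            rows.append((visit.date, item_id, status, level))
    return rows, missing


@pytest.mark.parametrize("regimen", ["drug_only", "drug_plus_insulin"])
def test_document_matches_bruteforce_oracle_on_grid(regimen, library, mds):
    """Exhaustive check over small records: every per-visit item subset from a
    fixed mask set, 1-3 visits, with one grid item lacking library content."""
    demo = Demographics(age=63, sex="female", education_level="below_diploma",
                        years_since_diagnosis=12, regimen=regimen)
    stripped = library.model_copy(
        update={"entries": {k: v for k, v in library.entries.items() if k != "hypertension"}}
    )
    mask_set = (0, 1, 2, 5, 21, 31)
    checked = 0
    for n_visits in (1, 2, 3):
        for masks in itertools.product(mask_set, repeat=n_visits):
            record = build_grid_record(demo, masks)
            doc = generate_document(record, stripped, mds)
            got = [
                (e.visit_date, e.item_id, e.status, e.level_used) for e in doc.all_explanations()
            ]
            want, want_missing = oracle_explanations(record, stripped, mds)
            assert got == want
            assert list(doc.missing_content) == want_missing
            checked += 1
    assert checked == len(mask_set) + len(mask_set) ** 2 + len(mask_set) ** 3
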