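import datetime as dt

import pytest

from sdrec import (
    Demographics,
    LabResult,
    MedicalRecord,
    MedicationOrder,
    SymptomObservation,
    Visit,
    build_placeholder_library,
    load_default_mds,
)


@pytest.fixture(scope="session")
def mds():
    return load_default_mds()


@pytest.fixture(scope="session")
def library(mds):
    return build_placeholder_library(mds)


@pytest.fixture(scope="session")
def demographics():
    return Demographics(
        age=63,
        sex="female",
        education_level="below_diploma",
        years_since_diagnosis=12,
        regimen="drug_plus_insulin",
    )


def make_visit(date, symptom_ids=(), med_specs=(), lab_specs=()):
    """Toy-visit helper: med_specs are (id, dose, unit), lab_specs (id, value, unit)."""
    return Visit(
        date=date,
        symptoms=tuple(SymptomObservation(item_id=i) for i in symptom_ids),
        medications=tuple(
            MedicationOrder(
                item_id=i, dose_value=d, dose_unit=u, frequency="once daily", timing="before breakfast"
            )
            for i, d, u in med_specs
        ),
        labs=tuple(LabResult(item_id=i, value=v, unit=u) for i, v, u in lab_specs),
    )


@pytest.fixture
def toy_record(demographics):
    """Two visits: symptom + two drugs + FBS, then two labs."""
    v1 = make_visit(
        dt.date(2016, 6, 1),
        symptom_ids=["polyuria"],
        med_specs=[("metformin", 500, "mg"), ("insulin_regular", 10, "units")],
        lab_specs=[("fbs", 130, "mg/dL")],
    )
    v2 = make_visit(
        dt.date(2016, 7, 1),
        lab_specs=[("fbs", 150, "mg/dL"), ("cholesterol_total", 210, "mg/dL")],
    )
    return MedicalRecord(patient_id="toy-001", demographics=demographics, visits=(v1, v2))
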