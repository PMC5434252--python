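"""Seeded synthetic patients and longitudinal records.

The generator emulates the pilot cohort profile so every other module is
exercisable without real data: ages uniform on the integers 58-68 (mean 63,
inside the reported 57-68 range), 5/8 of patients on drug-plus-insulin,
5/8 with below-diploma education, years since diagnosis ~ Normal(12, 4)
truncated at >= 1.  Visit trajectories are plausible rather than clinically
calibrated: per-visit Bernoulli symptom draws, standing medications repeated
at every visit, and lab values from per-item normal models with a small
per-visit drift (fasting blood sugar ~ N(150, 30) mg/dL; other labs derived
from their reference ranges).

All randomness flows through one ``numpy.random.default_rng`` stream per
call, so a fixed seed reproduces the cohort byte for byte across platforms.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

from .mds_schema import MinimumDataset, load_default_mds
from .record_model import (
    Demographics,
    LabResult,
    MedicalRecord,
    MedicationOrder,
    SymptomObservation,
    Visit,
)


class LabModel(BaseModel):
    """Sampling model for one lab item: Normal(mean, sd) plus per-visit drift."""

    model_config = ConfigDict(frozen=True)

    mean: float
    sd: float
    drift_per_visit: float = 0.0


class CohortProfile(BaseModel):
    """Study conditions for cohort generation (defaults emulate the pilot)."""

    model_config = ConfigDict(frozen=True)

    age_low: int = 58
    age_high: int = 68  # inclusive; uniform integers -> mean 63
    p_insulin: float = 5 / 8
    p_low_education: float = 5 / 8
    p_female: float = 0.5
    years_since_diagnosis_mean: float = 12.0
    years_since_diagnosis_sd: float = 4.0
    visits_low: int = 2
    visits_high: int = 4  # inclusive
    symptom_prevalence: float = 0.12
    labs_per_visit_low: int = 5
    labs_per_visit_high: int = 8
    lab_models: dict[str, LabModel] = {
        "fbs": LabModel(mean=150.0, sd=30.0, drift_per_visit=-3.0),
        "hba1c": LabModel(mean=7.5, sd=1.0, drift_per_visit=-0.1),
    }

    def model_post_init(self, __context) -> None:
        for p in (self.p_insulin, self.p_low_education, self.p_female, self.symptom_prevalence):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")


def _default_lab_model(item, profile: CohortProfile) -> LabModel:
    """Fallback model from an item's reference range: centred a quarter-width
    above the midpoint (diabetic cohorts skew high), SD a quarter of the width."""
    if item.id in profile.lab_models:
        return profile.lab_models[item.id]
    rr = item.reference_range
    if rr is None:
        return LabModel(mean=1.0, sd=0.1)
    width = rr.high - rr.low
    mid = (rr.low + rr.high) / 2
    return LabModel(mean=mid + 0.25 * width, sd=width / 4)


def _sample_demographics(rng: np.random.Generator, profile: CohortProfile) -> Demographics:
    age = int(rng.integers(profile.age_low, profile.age_high + 1))
    ysd = float(
        np.clip(
            rng.normal(profile.years_since_diagnosis_mean, profile.years_since_diagnosis_sd),
            1.0,
            age,
        )
    )
    return Demographics(
        age=age,
        sex="female" if rng.random() < profile.p_female else "male",
        education_level="below_diploma"
        if rng.random() < profile.p_low_education
        else "diploma_or_above",
        years_since_diagnosis=round(ysd, 1),
        regimen="drug_plus_insulin" if rng.random() < profile.p_insulin else "drug_only",
    )


_FREQUENCIES = ("once daily", "twice daily", "three times daily")
_TIMINGS = ("before breakfast", "after lunch", "before dinner", "at bedtime")
_ORAL_DOSES = (250.0, 500.0, 850.0, 1000.0, 5.0, 10.0, 20.0, 40.0, 80.0)
_INSULIN_DOSES = (6.0, 8.0, 10.0, 12.0, 16.0, 20.0)


def _standing_medications(
    rng: np.random.Generator, demographics: Demographics, mds: MinimumDataset
) -> list[MedicationOrder]:
    med_ids = mds.ids_in("medication")
    insulin_ids = [i for i in med_ids if i.startswith("insulin_")]
    oral_ids = [i for i in med_ids if not i.startswith("insulin_")]
    orders: list[MedicationOrder] = []
    n_oral = int(rng.integers(1, 4))
    for item_id in rng.choice(oral_ids, size=n_oral, replace=False):
        item = mds.get(str(item_id))
        dose = float(rng.choice(_ORAL_DOSES)) if item.unit == "mg" else float(rng.choice((1.0, 2.0)))
        orders.append(
            MedicationOrder(
                item_id=item.id,
                dose_value=dose,
                dose_unit=item.unit or "dose",
                frequency=str(rng.choice(_FREQUENCIES)),
                timing=str(rng.choice(_TIMINGS)),
            )
        )
    if demographics.regimen == "drug_plus_insulin":
        n_insulin = int(rng.integers(1, 3))
        for item_id in rng.choice(insulin_ids, size=n_insulin, replace=False):
            item = mds.get(str(item_id))
            orders.append(
                MedicationOrder(
                    item_id=item.id,
                    dose_value=float(rng.choice(_INSULIN_DOSES)),
                    dose_unit=item.unit or "units",
                    frequency=str(rng.choice(_FREQUENCIES[:2])),
                    timing=str(rng.choice(_TIMINGS)),
                )
            )
    return orders


def generate_record(
    demographics: Demographics,
    n_visits: int,
    profile: Optional[CohortProfile] = None,
    seed: int = 0,
    mds: Optional[MinimumDataset] = None,
    patient_id: str = "synthetic",
) -> MedicalRecord:
    """Generate one longitudinal record with ``n_visits`` ascending visits.

    Each visit draws symptoms item-wise (Bernoulli), repeats the patient's
    standing medications, and samples a subset of labs (always including
    fasting blood sugar and HbA1c) from the per-item lab models.
    """
    if n_visits < 1:
        raise ValueError("n_visits must be >= 1")
    profile = profile or CohortProfile()
    mds = mds or load_default_mds()
    rng = np.random.default_rng(seed)

    symptom_ids = mds.ids_in("symptoms") + mds.ids_in("medical_history")
    lab_ids = mds.ids_in("lab_tests")
    core_labs = [i for i in ("fbs", "hba1c") if i in mds]
    other_labs = [i for i in lab_ids if i not in core_labs]
    medications = _standing_medications(rng, demographics, mds)

    start = dt.date(2016, 6, 1) + dt.timedelta(days=int(rng.integers(0, 60)))
    visits: list[Visit] = []
    date = start
    for visit_no in range(n_visits):
        present = rng.random(len(symptom_ids)) < profile.symptom_prevalence
        symptoms = tuple(
            SymptomObservation(item_id=symptom_ids[i]) for i in np.flatnonzero(present)
        )
        n_labs = int(
            rng.integers(profile.labs_per_visit_low, profile.labs_per_visit_high + 1)
        )
        n_extra = max(0, min(n_labs - len(core_labs), len(other_labs)))
        chosen = core_labs + [str(x) for x in rng.choice(other_labs, size=n_extra, replace=False)]
        labs = []
        for item_id in chosen:
            item = mds.get(item_id)
            model = _default_lab_model(item, profile)
            value = rng.normal(model.mean + model.drift_per_visit * visit_no, model.sd)
            value = float(np.round(max(value, 0.1), 1))
            labs.append(LabResult(item_id=item_id, value=value, unit=item.unit or ""))
        visits.append(
            Visit(date=date, symptoms=symptoms, medications=tuple(medications), labs=tuple(labs))
        )
        date = date + dt.timedelta(days=int(rng.integers(28, 70)))
    return MedicalRecord(patient_id=patient_id, demographics=demographics, visits=tuple(visits))


def generate_cohort(
    n: int,
    profile: Optional[CohortProfile] = None,
    seed: int = 0,
    mds: Optional[MinimumDataset] = None,
) -> list[MedicalRecord]:
    """Generate ``n`` synthetic records under the cohort profile.

    Deterministic under a fixed (n, profile, seed): the same call returns an
    identical cohort.  Insulin-regimen patients always carry at least one
    insulin medication order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    profile = profile or CohortProfile()
    mds = mds or load_default_mds()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        demographics = _sample_demographics(rng, profile)
        n_visits = int(rng.integers(profile.visits_low, profile.visits_high + 1))
        child_seed = int(rng.integers(0, 2**31 - 1))
        records.append(
            generate_record(
                demographics,
                n_visits,
                profile=profile,
                seed=child_seed,
                mds=mds,
                patient_id=f"synthetic-{i:05d}",
            )
        )
    return records


def cohort_summary(records: list[MedicalRecord]) -> dict[str, float]:
    """Headline statistics of a cohort (for the simulate CLI's summary CSV)."""
    n = len(records)
    ages = [r.demographics.age for r in records]
    return {
        "n": n,
        "mean_age": sum(ages) / n,
        "min_age": min(ages),
        "max_age": max(ages),
        "insulin_fraction": sum(
            r.demographics.regimen == "drug_plus_insulin" for r in records
        )
        / n,
        "low_education_fraction": sum(
            r.demographics.education_level == "below_diploma" for r in records
        )
        / n,
        "mean_years_since_diagnosis": sum(r.demographics.years_since_diagnosis for r in records)
        / n,
        "mean_visits": sum(len(r.visits) for r in records) / n,
    }
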