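## Need-analysis question taxonomy: the thematic categories of questions
## diabetic patients asked during clinic observation, with the concepts each
## category breaks into.  record_linked marks the categories that can be
## answered from the patient's own medical record (and therefore drive the
## per-category content structures).
version: question_taxonomy_v1
categories:
  - name: symptoms
    record_linked: true
    concepts: [cause_of_symptom, diagnostic_symptoms, recommendations]
  - name: oral_drugs
    record_linked: true
    concepts: [side_effects, dosage, administration_and_use]
  - name: insulin
    record_linked: true
    concepts: [side_effects, dosage, administration_and_use]
  - name: lab_tests
    record_linked: true
    concepts: [definition, normal_range, patient_status]
  - name: blood_glucose_test
    record_linked: false
    concepts: [self_monitoring, device_use]
  - name: diet
    record_linked: false
    concepts: [meal_planning, food_choices]
  - name: physical_activity
    record_linked: false
    concepts: [exercise_type, exercise_safety]
  - name: psychological_problems
    record_linked: false
    concepts: [stress, mood]
  - name: exposure_to_new_circumstances
    record_linked: false
    concepts: [travel, illness_days, fasting]
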