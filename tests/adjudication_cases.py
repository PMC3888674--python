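"""Handcrafted adjudication fixtures: one subject per rule.

Each case is a patient with records (death certificate, primary-care
codes, hospital episodes, free-text notes) and the exact expected
adjudication: which outcomes fire, through which source, and on which
date.  Deaths default to day 1000; subjects run [0, 4000].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

D = 1000.0  # canonical death day


def _case(name, death=None, cert=None, reads=(), hosps=(), notes=(),
          expect=None, index=0.0, censor=4000.0):
    return {
        "name": name, "death": death, "cert": cert, "reads": list(reads),
        "hosps": list(hosps), "notes": list(notes), "expect": expect or {},
        "index": index, "censor": censor,
    }


# expect: outcome -> (winning_source, event_date); absent outcome must not fire
CASES = [
    _case("cert_narrow_code_all_tiers", death=D, cert="I46", expect={
        "all_cause_mortality": ("death_certificate", D),
        "cardiac_mortality": ("death_certificate", D),
        "scd_primary": ("death_certificate", D),
        "scd_secondary": ("death_certificate", D),
    }),
    _case("cert_subcode_in_narrow_set", death=D, cert="I47.2", expect={
        "all_cause_mortality": ("death_certificate", D),
        "cardiac_mortality": ("death_certificate", D),
        "scd_primary": ("death_certificate", D),
        "scd_secondary": ("death_certificate", D),
    }),
    _case("cert_parent_code_broad_only", death=D, cert="I47.9", expect={
        "all_cause_mortality": ("death_certificate", D),
        "cardiac_mortality": ("death_certificate", D),
        "scd_secondary": ("death_certificate", D),
    }),
    _case("cert_unattended_death_subcode", death=D, cert="R96.1", expect={
        "all_cause_mortality": ("death_certificate", D),
        "cardiac_mortality": ("death_certificate", D),
        "scd_primary": ("death_certificate", D),
        "scd_secondary": ("death_certificate", D),
    }),
    _case("noncardiac_death_all_cause_only", death=D, cert="C34", expect={
        "all_cause_mortality": ("death_certificate", D),
    }),
    _case("suicide_death_fully_excluded", death=D, cert="X70", expect={}),
    _case("discharge_20d_before_blocks_narrow", death=D, cert="I46",
          hosps=[(D - 25, D - 20, "J18")], expect={
              "all_cause_mortality": ("death_certificate", D),
              "cardiac_mortality": ("death_certificate", D),
          }),
    _case("discharge_45d_before_allows_narrow", death=D, cert="I46",
          hosps=[(D - 50, D - 45, "J18")], expect={
              "all_cause_mortality": ("death_certificate", D),
              "cardiac_mortality": ("death_certificate", D),
              "scd_primary": ("death_certificate", D),
              "scd_secondary": ("death_certificate", D),
          }),
    _case("death_during_admission_blocks_narrow", death=D, cert="I46",
          hosps=[(D - 3, D + 1, "J18")], expect={
              "all_cause_mortality": ("death_certificate", D),
              "cardiac_mortality": ("death_certificate", D),
          }),
    _case("certificate_precedes_read_code", death=D, cert="I46",
          reads=[(D + 2, "RyI46")], expect={
              "all_cause_mortality": ("death_certificate", D),
              "cardiac_mortality": ("death_certificate", D),
              "scd_primary": ("death_certificate", D),
              "scd_secondary": ("death_certificate", D),
              "scd_tertiary": ("primary_care", D),
          }),
    _case("read_code_qualifies_without_cert_support", death=D, cert="C34",
          reads=[(D + 3, "RyI46")], expect={
              "all_cause_mortality": ("death_certificate", D),
              "scd_primary": ("primary_care", D),
              "scd_secondary": ("primary_care", D),
              "scd_tertiary": ("primary_care", D),
          }),
    _case("free_text_wins_over_read_earlier_date", death=D, cert="C34",
          reads=[(D + 3, "RyI46")],
          notes=[(D - 5, "family report patient dropped dead in garden")],
          expect={
              "all_cause_mortality": ("death_certificate", D),
              "scd_primary": ("free_text", D - 5),
              "scd_secondary": ("free_text", D - 5),
              "scd_tertiary": ("free_text", D - 5),
          }),
    _case("free_text_alone_qualifies", death=D, cert="C34",
          notes=[(D + 4, "patient died suddenly, unclear circumstances")],
          expect={
              "all_cause_mortality": ("death_certificate", D),
              "scd_primary": ("free_text", D),
              "scd_secondary": ("free_text", D),
              "scd_tertiary": ("free_text", D),
          }),
    _case("exclusion_phrase_vetoes_free_text", death=D, cert="C34",
          notes=[(D + 1, "sudden death - road traffic accident per coroner")],
          expect={
              "all_cause_mortality": ("death_certificate", D),
          }),
    _case("note_outside_three_weeks_ignored", death=D, cert="C34",
          notes=[(D + 25, "patient died suddenly at home")],
          expect={
              "all_cause_mortality": ("death_certificate", D),
          }),
    _case("note_on_window_boundary_counts", death=D, cert="C34",
          notes=[(D - 21, "witnessed sudden cardiac death in surgery")],
          expect={
              "all_cause_mortality": ("death_certificate", D),
              "scd_primary": ("free_text", D - 21),
              "scd_secondary": ("free_text", D - 21),
              "scd_tertiary": ("free_text", D - 21),
          }),
    _case("read_subcode_matches_narrow_set", death=D, cert="C34",
          reads=[(D + 1, "RyI461")], expect={
              "all_cause_mortality": ("death_certificate", D),
              "scd_primary": ("primary_care", D),
              "scd_secondary": ("primary_care", D),
              "scd_tertiary": ("primary_care", D),
          }),
    _case("read_broad_code_not_narrow", death=D, cert="C34",
          reads=[(D + 2, "RyI21")], expect={
              "all_cause_mortality": ("death_certificate", D),
              "scd_secondary": ("primary_care", D),
              "scd_tertiary": ("primary_care", D),
              # the same record also signals a coronary event
              "chd": ("primary_care", D + 2),
          }),
    _case("certificate_only_fails_registry_tier", death=D, cert="R96",
          expect={
              "all_cause_mortality": ("death_certificate", D),
              "cardiac_mortality": ("death_certificate", D),
              "scd_primary": ("death_certificate", D),
              "scd_secondary": ("death_certificate", D),
          }),
    _case("death_after_censor_ignored", death=3900.0, cert="I46",
          censor=3000.0, expect={}),
    _case("death_before_index_ignored", death=D, cert="I46",
          index=2000.0, expect={}),
    _case("registry_death_without_certificate", death=D, expect={
        "all_cause_mortality": ("death_certificate", D),
    }),
    _case("chd_from_hospital_admission", hosps=[(300.0, 306.0, "I21")],
          expect={"chd": ("hospital", 300.0)}),
    _case("chd_subcode_from_hospital", hosps=[(300.0, 306.0, "I21.4")],
          expect={"chd": ("hospital", 300.0)}),
    _case("chd_from_read_code_alive", reads=[(450.0, "RyI22")],
          expect={"chd": ("primary_care", 450.0)}),
    _case("chd_before_index_ignored", hosps=[(300.0, 306.0, "I21")],
          index=500.0, expect={}),
    _case("earliest_chd_record_wins", hosps=[(700.0, 710.0, "I21")],
          reads=[(400.0, "RyI21")],
          expect={"chd": ("primary_care", 400.0)}),
    _case("ventricular_arrhythmia_from_hospital",
          hosps=[(600.0, 604.0, "I49.0")],
          expect={"ventricular_arrhythmia": ("hospital", 600.0)}),
    _case("other_arrhythmia_code_does_not_fire",
          hosps=[(600.0, 604.0, "I49.9")], expect={}),
    _case("old_hospitalisation_keeps_window_rule", death=D, cert="I46",
          hosps=[(D - 300, D - 290, "K52")], expect={
              "all_cause_mortality": ("death_certificate", D),
              "cardiac_mortality": ("death_certificate", D),
              "scd_primary": ("death_certificate", D),
              "scd_secondary": ("death_certificate", D),
          }),
]


def build_tables():
    """Materialise the cases as patients / events / notes / subjects frames."""
    patients, events, notes, subjects = [], [], [], []
    for i, case in enumerate(CASES):
        pid = i + 1
        patients.append({
            "patient_id": pid, "practice_id": 1, "sex": "F",
            "birth_year": 1940, "registration_date": -500, "data_start": 0,
            "transfer_out": np.nan,
            "death_date": case["death"] if case["death"] is not None else np.nan,
        })
        if case["death"] is not None and case["cert"] is not None:
            events.append({"patient_id": pid, "date": case["death"],
                           "source": "death_certificate", "code": case["cert"],
                           "admission_date": np.nan, "discharge_date": np.nan})
        for day, code in case["reads"]:
            events.append({"patient_id": pid, "date": day,
                           "source": "primary_care", "code": code,
                           "admission_date": np.nan, "discharge_date": np.nan})
        for adm, dis, code in case["hosps"]:
            events.append({"patient_id": pid, "date": adm,
                           "source": "hospital", "code": code,
                           "admission_date": adm, "discharge_date": dis})
        for day, text in case["notes"]:
            notes.append({"patient_id": pid, "date": day, "text": text,
                          "truth_label": "true_scd"})
        subjects.append({"subject_id": i, "patient_id": pid, "cohort": "user",
                         "index_date": case["index"],
                         "censor_date": case["censor"]})
    cols = ["patient_id", "date", "source", "code", "admission_date",
            "discharge_date"]
    return (
        pd.DataFrame(patients),
        pd.DataFrame(events, columns=cols),
        pd.DataFrame(notes, columns=["patient_id", "date", "text", "truth_label"]),
        pd.DataFrame(subjects),
    )
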