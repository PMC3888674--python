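"""Shared fixtures: small simulated table sets and handcrafted-record helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import apcohort as ap


@pytest.fixture(scope="session")
def sim_tables():
    """A moderate simulated dataset reused by read-only tests."""
    cfg = ap.SimConfig(n_patients=5000, seed=3)
    return cfg, ap.simulate(cfg)


def mk_patients(rows: list[dict]) -> pd.DataFrame:
    """Patient registry frame from sparse dicts (sensible defaults)."""
    defaults = {
        "practice_id": 1, "sex": "F", "birth_year": 1950,
        "registration_date": 0, "data_start": 0,
        "transfer_out": np.nan, "death_date": np.nan,
        "smoking": "non", "bmi": 25.0, "alcohol_drug_abuse": 0,
        "diabetes": 0, "suicide_attempt_history": 0,
        "prior_psych_admission": 0, "antidepressant": 0, "anxiolytic": 0,
        "statin": 0, "antihypertensive": 0, "deprivation": 3,
        "psych_diagnoses": "", "_treated": False, "_conf_hazard_mult": 1.0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"patient_id": i + 1, **defaults, **row}
        out.append(rec)
    return pd.DataFrame(out)


def mk_rx(rows: list[dict]) -> pd.DataFrame:
    """Prescription frame from sparse dicts."""
    defaults = {
        "drug_name": "chlorpromazine", "drug_class": "typical",
        "quantity": 56.0, "prescribed_daily_dose": 2.0, "strength": 100.0,
        "_duration": 28.0, "_ddd_mg": 200.0,
    }
    out = [{"patient_id": 1, "date": 0.0, **defaults, **row} for row in rows]
    cols = ["patient_id", "date"] + list(defaults)
    return pd.DataFrame(out, columns=cols) if not out else pd.DataFrame(out)


def mk_events(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "source": "primary_care", "code": "PSY.major_depression",
        "admission_date": np.nan, "discharge_date": np.nan,
    }
    out = [{"patient_id": 1, "date": 0.0, **defaults, **row} for row in rows]
    return pd.DataFrame(out)


def mk_episodes(rows: list[dict]) -> pd.DataFrame:
    """Prescription-episode frame (already standardised doses/durations)."""
    defaults = {
        "patient_id": 1, "ddd_mg": 200.0, "ddd_imputed": False,
        "duration_imputed": False, "drug_class": "typical",
    }
    out = []
    for row in rows:
        rec = {**defaults, **row}
        rec.setdefault("duration_days", rec.get("expected_end", rec["start"] + 28.0) - rec["start"])
        rec.setdefault("expected_end", rec["start"] + rec["duration_days"])
        out.append(rec)
    return pd.DataFrame(out)
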