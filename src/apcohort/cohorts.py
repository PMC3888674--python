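"""Construction of the three analysis cohorts.

* **users** — everyone with an antipsychotic prescription in the study
  window; the index date is the first in-window script, split into
  *incident* (first-ever) and *prevalent* (earlier use on record) users,
  classified by the class of the first antipsychotic prescribed.
* **general-population controls** — up to three per user, matched on sex,
  practice and (within tolerance) year of birth, sharing the user's index
  date, with no antipsychotic use or recorded psychiatric disorder, and at
  least twelve months of data collection before index.
* **psychiatric nonusers** — patients with a recorded psychiatric disorder
  and no antipsychotic use before the first record; indexed at that first
  record and censored at any later first prescription.  Unmatched.

Exclusion rules (conduction/cardiomyopathy at any time; prior
life-threatening ventricular arrhythmia, cardioversion, aborted arrest or
defibrillator implantation before registration or index) are applied to
the assembled cohorts, removing a user's controls along with the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DAYS_PER_YEAR, load_code_sets
from .synth import first_psych_day

logger = logging.getLogger(__name__)

SUBJECT_COLUMNS = [
    "patient_id", "cohort", "index_date", "user_type", "first_class",
    "censor_date", "match_group",
]


class LinkageError(ValueError):
    """A record references a patient that is not in the registry."""


@dataclass
class MatchCriteria:
    """Control-matching tolerances (1:`ratio`, exact calendar time)."""

    age_tolerance: float = 2.0      # years of birth-year difference
    calendar_tolerance: float = 0.0  # days; 0 = control index equals user index
    ratio: int = 3

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.age_tolerance < 0 or self.calendar_tolerance < 0:
            raise ValueError("tolerances must be >= 0")


def _admin_end(patients: pd.DataFrame, study_end: float) -> pd.Series:
    transfer = patients["transfer_out"].astype(float)
    death = patients["death_date"].astype(float)
    end = pd.Series(float(study_end), index=patients.index)
    end = end.where(~(transfer < end), transfer)
    end = end.where(~(death < end), death)
    return end


def identify_users(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    study_start: float = 0.0,
    study_end: float = np.inf,
) -> pd.DataFrame:
    """One subject per patient with an in-window antipsychotic script.

    Index = first prescription date inside ``[study_start, study_end)``;
    a user is *incident* when no prescription of any antipsychotic exists
    before the index date, else *prevalent*.  ``first_class`` is the class
    prescribed at index (ties across classes on the index day resolve to
    the alphabetically first drug name's class, deterministically).
    """
    unknown = ~prescriptions["patient_id"].isin(patients["patient_id"])
    if unknown.any():
        bad = prescriptions.loc[unknown, "patient_id"].iloc[0]
        raise LinkageError(f"prescription for unknown patient_id {bad!r}")

    rx = prescriptions.sort_values(
        ["patient_id", "date", "drug_name"], kind="mergesort"
    )
    in_window = rx[(rx["date"] >= study_start) & (rx["date"] < study_end)]
    if in_window.empty:
        return pd.DataFrame(columns=SUBJECT_COLUMNS)
    first = in_window.groupby("patient_id").first()
    index_date = first["date"]
    first_class = first["drug_class"]

    earliest_any = rx.groupby("patient_id")["date"].min()
    prevalent = earliest_any.reindex(index_date.index) < index_date

    pats = patients.set_index("patient_id")
    end = _admin_end(patients, study_end if np.isfinite(study_end) else np.inf)
    end.index = patients["patient_id"]

    users = pd.DataFrame(
        {
            "patient_id": index_date.index,
            "cohort": "user",
            "index_date": index_date.to_numpy(),
            "user_type": np.where(prevalent.to_numpy(), "prevalent", "incident"),
            "first_class": first_class.to_numpy(),
            "censor_date": end.reindex(index_date.index).to_numpy(),
            "match_group": index_date.index,
        }
    ).reset_index(drop=True)
    dropped = users["index_date"] >= users["censor_date"]
    if dropped.any():
        logger.info("dropping %d users with non-positive follow-up", dropped.sum())
    users = users[~dropped].reset_index(drop=True)
    _ = pats  # kept for symmetry with other builders
    return users


def match_controls(
    users: pd.DataFrame,
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    criteria: MatchCriteria | None = None,
    seed: int = 0,
    study_end: float = np.inf,
) -> pd.DataFrame:
    """Sample matched general-population controls for each user.

    Eligibility at the user's index date: same sex and practice, birth
    year within ``age_tolerance``, no antipsychotic prescription on or
    before index, no recorded psychiatric disorder, index at least twelve
    months after the patient's data collection starts, and index strictly
    inside the patient's observable window.  Up to ``ratio`` controls are
    drawn without replacement within each match group with a seeded
    tie-break; users with fewer eligible candidates keep what exists.
    Controls later prescribed an antipsychotic are censored at that first
    prescription.
    """
    criteria = criteria or MatchCriteria()
    if users.empty:
        return pd.DataFrame(columns=SUBJECT_COLUMNS + ["n_controls_found"])
    rng = np.random.default_rng(seed)

    psych = first_psych_day(patients)
    has_psych = pd.Series(
        np.isfinite(psych.to_numpy()), index=patients["patient_id"]
    )
    first_rx = prescriptions.groupby("patient_id")["date"].min()

    pats = patients.set_index("patient_id")
    end = _admin_end(patients, study_end)
    end.index = patients["patient_id"]

    pool = pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy(),
            "practice_id": patients["practice_id"].to_numpy(),
            "sex": patients["sex"].to_numpy(),
            "birth_year": patients["birth_year"].to_numpy(),
            "data_start": patients["data_start"].to_numpy(dtype=float),
            "end": end.to_numpy(),
            "has_psych": has_psych.to_numpy(),
            "first_rx": first_rx.reindex(patients["patient_id"]).to_numpy(dtype=float),
        }
    )
    pool = pool[~pool["has_psych"]]
    # numpy arrays per (practice, sex) group keep the per-user search cheap;
    # candidates are sorted by patient_id for a deterministic seeded draw
    groups: dict[tuple, dict[str, np.ndarray]] = {}
    for key, g in pool.sort_values("patient_id").groupby(["practice_id", "sex"]):
        groups[key] = {
            "pid": g["patient_id"].to_numpy(),
            "birth": g["birth_year"].to_numpy(dtype=float),
            "data_start": g["data_start"].to_numpy(),
            "end": g["end"].to_numpy(dtype=float),
            "first_rx": g["first_rx"].to_numpy(dtype=float),
        }

    rows: list[tuple] = []
    users_sorted = users.sort_values("patient_id")
    u_practice = pats.loc[users_sorted["patient_id"], "practice_id"].to_numpy()
    u_sex = pats.loc[users_sorted["patient_id"], "sex"].to_numpy()
    u_birth = pats.loc[users_sorted["patient_id"], "birth_year"].to_numpy()

    for (upid, uidx), prac, sx, by in zip(
        users_sorted[["patient_id", "index_date"]].itertuples(index=False, name=None),
        u_practice, u_sex, u_birth,
    ):
        g = groups.get((prac, sx))
        n_found = 0
        if g is not None:
            ok = (
                (np.abs(g["birth"] - by) <= criteria.age_tolerance)
                & (g["data_start"] + DAYS_PER_YEAR <= uidx)
                & (g["end"] > uidx)
                & ~(g["first_rx"] <= uidx)
                & (g["pid"] != upid)
            )
            cand = np.flatnonzero(ok)
            if len(cand):
                take = min(criteria.ratio, len(cand))
                chosen = np.sort(rng.choice(cand, size=take, replace=False))
                n_found = take
                for j in chosen:
                    censor = g["end"][j]
                    crx = g["first_rx"][j]
                    if np.isfinite(crx) and crx > uidx:
                        censor = min(censor, crx)
                    rows.append(
                        (g["pid"][j], "general_control", uidx, None, None,
                         censor, upid, take)
                    )
        if n_found < criteria.ratio:
            logger.debug("user %s matched only %d controls", upid, n_found)
    controls = pd.DataFrame(rows, columns=SUBJECT_COLUMNS + ["n_controls_found"])
    controls = controls[controls["index_date"] < controls["censor_date"]]
    return controls.reset_index(drop=True)


def identify_psych_nonusers(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    study_end: float = np.inf,
) -> pd.DataFrame:
    """Psychiatric-disease cohort without prior antipsychotic use.

    Index = first psychiatric first-record date (incident and prevalent
    disease alike); patients whose first prescription predates the first
    record are excluded; later-treated patients are censored at their
    first prescription.  The cohort is unmatched.
    """
    psych = first_psych_day(patients)
    first_rx = prescriptions.groupby("patient_id")["date"].min()

    pid = patients["patient_id"].to_numpy()
    idx = psych.to_numpy()
    has = np.isfinite(idx)
    rx0 = first_rx.reindex(patients["patient_id"]).to_numpy(dtype=float)
    pre_treated = np.isfinite(rx0) & (rx0 < idx)
    data_start = patients["data_start"].to_numpy(dtype=float)

    end = _admin_end(patients, study_end).to_numpy()
    censor = np.where(np.isfinite(rx0), np.minimum(end, rx0), end)

    keep = has & ~pre_treated & (idx >= data_start) & (idx < censor)
    out = pd.DataFrame(
        {
            "patient_id": pid[keep],
            "cohort": "psych_nonuser",
            "index_date": idx[keep],
            "user_type": None,
            "first_class": None,
            "censor_date": censor[keep],
            "match_group": None,
        }
    )
    return out.reset_index(drop=True)


def apply_exclusions(
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    patients: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove subjects with disqualifying cardiac history.

    Three rules: (1) congenital conduction disorder or advanced
    cardiomyopathy coded at any time; (2) life-threatening ventricular
    arrhythmia / cardioversion / aborted arrest / defibrillator code on or
    before registration; (3) the same codes on or before the index date.
    A removed user takes its orphaned controls with it.  Returns the
    retained subjects and a per-rule exclusion flow.
    """
    if subjects.empty:
        return subjects.copy(), {}
    code_sets = load_code_sets()
    any_codes = set(code_sets["exclusions"]["any_time"]["read"])
    vt_codes = set(code_sets["exclusions"]["pre_registration_and_pre_index"]["read"])

    ev = events[events["code"].isin(any_codes | vt_codes)]
    reg = pd.Series(
        patients["registration_date"].to_numpy(dtype=float),
        index=patients["patient_id"],
    )

    anytime_pids = set(ev.loc[ev["code"].isin(any_codes), "patient_id"])
    vt = ev[ev["code"].isin(vt_codes)]
    first_vt = vt.groupby("patient_id")["date"].min()

    subj = subjects.copy()
    flow: dict[str, int] = {}

    rule1 = subj["patient_id"].isin(anytime_pids)
    flow["conduction_or_cardiomyopathy_any_time"] = int(rule1.sum())

    vt_day = first_vt.reindex(subj["patient_id"]).to_numpy()
    reg_day = reg.reindex(subj["patient_id"]).to_numpy()
    rule2 = np.isfinite(vt_day) & (vt_day <= reg_day)
    flow["ventricular_history_pre_registration"] = int((rule2 & ~rule1).sum())

    rule3 = np.isfinite(vt_day) & (vt_day <= subj["index_date"].to_numpy())
    flow["ventricular_history_pre_index"] = int((rule3 & ~rule1 & ~rule2).sum())

    excluded = rule1 | rule2 | rule3
    removed_users = set(
        subj.loc[excluded & (subj["cohort"] == "user"), "patient_id"]
    )
    orphan = (subj["cohort"] == "general_control") & subj["match_group"].isin(
        removed_users
    )
    flow["orphaned_controls"] = int((orphan & ~excluded).sum())

    kept = subj[~(excluded | orphan)].reset_index(drop=True)
    logger.info("exclusion flow: %s", flow)
    return kept, flow


def build_cohorts(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    events: pd.DataFrame,
    criteria: MatchCriteria | None = None,
    seed: int = 0,
    study_start: float = 0.0,
    study_end: float = np.inf,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Users + matched controls + psychiatric nonusers, post-exclusion."""
    users = identify_users(patients, prescriptions, study_start, study_end)
    controls = match_controls(
        users, patients, prescriptions, criteria, seed=seed, study_end=study_end
    )
    nonusers = identify_psych_nonusers(patients, prescriptions, study_end)
    subjects = pd.concat([users, controls, nonusers], ignore_index=True)
    return apply_exclusions(subjects, events, patients)
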