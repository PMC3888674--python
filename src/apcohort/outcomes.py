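"""Multi-source outcome adjudication.

Outcomes are identified per subject by querying the three record streams
with a fixed precedence: death certificate first, then free text from the
primary-care record, then primary-care (Read-like) codes.  Event dates
follow the source that wins: certificate events use the recorded death
date; free-text events use the earlier of the death date and the note
date; coded events the earlier of the death date and the code date; and
when both a code and a free-text hit exist, the earlier of the two.

Sudden cardiac death (SCD) is adjudicated at three nested tiers:

* **primary** — narrow certificate/code set (cardiac arrest, ventricular
  fibrillation, cardiac-arrest-type codes); the death must look
  out-of-hospital: a hospital discharge within the 30 days before death
  (or death during an admission) disqualifies;
* **secondary** — broad cardiac set; any disqualifying hospitalisation
  record excludes the case (window before death by default; optionally
  any admission on record);
* **tertiary** — broad set restricted to the primary-care record (codes
  and free text); certificates and hospital data are not consulted.

Free-text case finding is rule based: case-insensitive trigger substrings
(and conjunctive pairs) are searched in notes within three weeks of a
death, in practices with above-median free-text volume and after a
configurable start year; a hit is counted as SCD unless an exclusion
phrase in the surrounding 500-character context clearly names another
cause of death.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import (
    FREETEXT_CONTEXT_CHARS,
    FREETEXT_WINDOW_DAYS,
    HOSPITAL_DISCHARGE_RULE_DAYS,
    code_matches,
    icd_for_read_code,
    load_code_sets,
    load_freetext_terms,
)

logger = logging.getLogger(__name__)

OUTCOME_COLUMNS = [
    "subject_id", "patient_id", "cohort", "outcome", "event_date",
    "winning_source",
]

# evidence window for death-linked primary-care codes, same three-week
# window as the free-text search
READ_CODE_WINDOW_DAYS = FREETEXT_WINDOW_DAYS


# ---------------------------------------------------------------------------
# Free-text search
# ---------------------------------------------------------------------------

def eligible_practices(
    freetext: pd.DataFrame, patients: pd.DataFrame
) -> set[int]:
    """Practices with above-median average free-text characters per patient."""
    if freetext.empty:
        return set()
    chars = freetext.assign(n=freetext["text"].str.len())
    by_pid = chars.groupby("patient_id")["n"].sum()
    prac = patients.set_index("patient_id")["practice_id"]
    per_patient = by_pid.groupby(prac.reindex(by_pid.index)).sum()
    n_patients = patients.groupby("practice_id").size()
    avg = (per_patient / n_patients.reindex(per_patient.index)).fillna(0.0)
    med = float(avg.median())
    return set(avg.index[avg > med])


def search_free_text(
    freetext: pd.DataFrame,
    patients: pd.DataFrame,
    start_day: float = -np.inf,
    practices: set[int] | None = None,
    terms: dict | None = None,
) -> pd.DataFrame:
    """Trigger-string search in notes within three weeks of a death.

    Returns one row per matching note: patient_id, date, matched_string,
    context (up to 500 characters either side of the hit) and verdict
    (``scd`` unless an exclusion phrase appears in the context).
    """
    terms = terms or load_freetext_terms()
    triggers = [t.lower() for t in terms["triggers"]]
    pairs = [tuple(p.lower() for p in pair) for pair in terms.get("trigger_pairs", [])]
    exclusions = [e.lower() for e in terms["exclusion_phrases"]]

    if practices is None:
        practices = eligible_practices(freetext, patients)
    pats = patients.set_index("patient_id")
    death = pats["death_date"]
    practice = pats["practice_id"]

    rows: list[dict] = []
    for pid, day, text in freetext[["patient_id", "date", "text"]].itertuples(
        index=False, name=None
    ):
        if pid not in death.index:
            continue
        d = death.loc[pid]
        if not np.isfinite(d) or abs(day - d) > FREETEXT_WINDOW_DAYS:
            continue
        if day < start_day or int(practice.loc[pid]) not in practices:
            continue
        low = text.lower()
        hit = None
        pos = -1
        for t in triggers:
            p = low.find(t)
            if p >= 0:
                hit, pos = t, p
                break
        if hit is None:
            for a, b in pairs:
                pa, pb = low.find(a), low.find(b)
                if pa >= 0 and pb >= 0:
                    hit, pos = f"{a}+{b}", min(pa, pb)
                    break
        if hit is None:
            continue
        c0 = max(0, pos - FREETEXT_CONTEXT_CHARS)
        c1 = min(len(text), pos + len(hit) + FREETEXT_CONTEXT_CHARS)
        context = text[c0:c1]
        verdict = "scd"
        ctx_low = context.lower()
        if any(e in ctx_low for e in exclusions):
            verdict = "not_scd"
        rows.append(
            {
                "patient_id": pid,
                "date": float(day),
                "matched_string": hit,
                "context": context,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "date", "matched_string", "context", "verdict"]
    )


# ---------------------------------------------------------------------------
# Per-patient death evidence
# ---------------------------------------------------------------------------

def _death_evidence(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    matches: pd.DataFrame,
    code_sets: dict,
) -> dict[int, dict]:
    """Collect per-patient evidence for the death-linked outcomes."""
    death = patients.set_index("patient_id")["death_date"]
    dead = death[np.isfinite(death.astype(float))]

    ev = events[events["patient_id"].isin(set(dead.index))]
    ev = ev.sort_values(["patient_id", "date"], kind="mergesort")

    certs_df = ev[ev["source"] == "death_certificate"]
    certs = dict(
        zip(certs_df["patient_id"].to_numpy(), certs_df["code"].to_numpy())
    )

    hosp = ev[ev["source"] == "hospital"]
    h_pid = hosp["patient_id"].to_numpy()
    h_adm = hosp["admission_date"].to_numpy(dtype=float)
    h_dis = hosp["discharge_date"].to_numpy(dtype=float)

    reads = ev[(ev["source"] == "primary_care")].copy()
    reads["icd_equiv"] = reads["code"].map(icd_for_read_code)
    reads = reads.dropna(subset=["icd_equiv"])
    r_pid = reads["patient_id"].to_numpy()
    r_date = reads["date"].to_numpy(dtype=float)
    r_icd = reads["icd_equiv"].to_numpy()

    ft_scd = (
        matches[matches["verdict"] == "scd"]
        .groupby("patient_id")["date"].min().to_dict()
        if not matches.empty
        else {}
    )

    evidence: dict[int, dict] = {}
    for pid, d in dead.items():
        d = float(d)
        info: dict = {"death_day": d, "cert_code": certs.get(pid)}
        a = np.searchsorted(r_pid, pid, side="left")
        b = np.searchsorted(r_pid, pid, side="right")
        if b > a:
            near = np.abs(r_date[a:b] - d) <= READ_CODE_WINDOW_DAYS
            info["read_codes"] = list(
                zip(r_icd[a:b][near].tolist(), r_date[a:b][near].tolist())
            )
        else:
            info["read_codes"] = []
        ft = ft_scd.get(pid)
        info["ft_date"] = float(ft) if ft is not None else None
        a = np.searchsorted(h_pid, pid, side="left")
        b = np.searchsorted(h_pid, pid, side="right")
        if b > a:
            adm, dis = h_adm[a:b], h_dis[a:b]
            in_hospital = np.any((adm <= d) & (dis >= d))
            recent_discharge = np.any(
                (dis >= d - HOSPITAL_DISCHARGE_RULE_DAYS) & (dis <= d)
            )
            info["hosp_near_death"] = bool(in_hospital or recent_discharge)
            info["hosp_any"] = bool(np.any(adm <= d))
        else:
            info["hosp_near_death"] = False
            info["hosp_any"] = False
        evidence[pid] = info
    return evidence


def _scd_candidate(info: dict, icd_set: list[str], use_cert: bool) -> tuple | None:
    """(winning_source, event_date) under the source hierarchy, or None."""
    d = info["death_day"]
    if use_cert and info["cert_code"] is not None and code_matches(info["cert_code"], icd_set):
        return "death_certificate", d
    read_hits = [dt for code, dt in info["read_codes"] if code_matches(code, icd_set)]
    read_date = min([d] + read_hits) if read_hits else None
    if info["ft_date"] is not None:
        date = min(d, info["ft_date"])
        if read_date is not None:
            date = min(date, read_date)  # earlier of code and free text
        return "free_text", date
    if read_date is not None:
        return "primary_care", read_date
    return None


def apply_scd_tiers(
    info: dict,
    code_sets: dict,
    secondary_hospital_mode: str = "window_30d",
) -> dict[str, tuple | None]:
    """Evaluate the three nested SCD definitions on one death's evidence.

    Returns {tier: (winning_source, event_date) or None}.  The primary
    tier requires the death to be out of hospital (no discharge within 30
    days before death, no death during an admission); the secondary tier
    drops cases with a disqualifying hospitalisation record; the tertiary
    tier consults only the primary-care record.
    """
    out: dict[str, tuple | None] = {}
    primary = _scd_candidate(info, code_sets["outcomes"]["scd_primary"]["icd"], True)
    if primary is not None and info["hosp_near_death"]:
        primary = None
    out["scd_primary"] = primary

    secondary = _scd_candidate(info, code_sets["outcomes"]["scd_secondary"]["icd"], True)
    if secondary is not None:
        disqualified = (
            info["hosp_any"]
            if secondary_hospital_mode == "any"
            else info["hosp_near_death"]
        )
        if disqualified:
            secondary = None
    out["scd_secondary"] = secondary

    out["scd_tertiary"] = _scd_candidate(
        info, code_sets["outcomes"]["scd_tertiary"]["icd"], False
    )
    return out


# ---------------------------------------------------------------------------
# Adjudication across subjects
# ---------------------------------------------------------------------------

def _nonfatal_events(
    events: pd.DataFrame, icd_set: list[str]
) -> pd.DataFrame:
    """Qualifying hospital/primary-care records for a nonfatal outcome."""
    hosp = events[events["source"] == "hospital"]
    hosp = hosp[np.fromiter(
        (code_matches(c, icd_set) for c in hosp["code"]), bool, len(hosp)
    )]
    reads = events[events["source"] == "primary_care"].copy()
    reads["icd_equiv"] = reads["code"].map(icd_for_read_code)
    reads = reads.dropna(subset=["icd_equiv"])
    reads = reads[np.fromiter(
        (code_matches(c, icd_set) for c in reads["icd_equiv"]), bool, len(reads)
    )]
    qual = pd.concat(
        [
            hosp[["patient_id", "date"]].assign(source="hospital", rank=0),
            reads[["patient_id", "date"]].assign(source="primary_care", rank=1),
        ],
        ignore_index=True,
    )
    return qual.sort_values(["patient_id", "date", "rank"], kind="mergesort")


def adjudicate(
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    matches: pd.DataFrame,
    patients: pd.DataFrame,
    code_sets: dict | None = None,
    secondary_hospital_mode: str = "window_30d",
) -> pd.DataFrame:
    """First qualifying event per subject and outcome.

    Returns rows (patient_id, cohort, outcome, event_date,
    winning_source) for events inside the subject's ``[index_date,
    censor_date]``; deaths from suicide are excluded from all-cause
    mortality but still end follow-up.  Out-of-window evidence is ignored
    (logged at debug level).
    """
    code_sets = code_sets or load_code_sets()
    evidence = _death_evidence(patients, events, matches, code_sets)
    suicide_set = code_sets["suicide"]["icd"]
    cardiac_set = code_sets["outcomes"]["cardiac_mortality"]["icd"]

    nonfatal = {
        name: _nonfatal_events(events, code_sets["outcomes"][name]["icd"])
        for name in ("chd", "ventricular_arrhythmia")
    }
    nonfatal_by_pid = {
        name: dict(tuple(df.groupby("patient_id"))) for name, df in nonfatal.items()
    }

    subj = subjects.copy()
    if "subject_id" not in subj.columns:
        subj["subject_id"] = np.arange(len(subj))

    rows: list[tuple] = []
    for sid, pid, cohort, idx, censor in subj[
        ["subject_id", "patient_id", "cohort", "index_date", "censor_date"]
    ].itertuples(index=False, name=None):
        info = evidence.get(pid)
        if info is not None:
            d = info["death_day"]
            if idx <= d <= censor:
                is_suicide = info["cert_code"] is not None and code_matches(
                    info["cert_code"], suicide_set
                )
                if not is_suicide:
                    rows.append(
                        (sid, pid, cohort, "all_cause_mortality", d,
                         "death_certificate")
                    )
                if info["cert_code"] is not None and code_matches(
                    info["cert_code"], cardiac_set
                ):
                    rows.append(
                        (sid, pid, cohort, "cardiac_mortality", d,
                         "death_certificate")
                    )
                tiers = apply_scd_tiers(info, code_sets, secondary_hospital_mode)
                for tier, hit in tiers.items():
                    if hit is not None:
                        source, date = hit
                        date = max(date, idx)  # date resolution cannot precede entry
                        rows.append((sid, pid, cohort, tier, date, source))
            elif np.isfinite(d):
                logger.debug("death outside follow-up ignored: patient %s", pid)
        for name, by_pid in nonfatal_by_pid.items():
            q = by_pid.get(pid)
            if q is None:
                continue
            dates = q["date"].to_numpy(dtype=float)
            ok = (dates >= idx) & (dates <= censor)
            if ok.any():
                j = int(np.argmax(ok))
                rows.append(
                    (sid, pid, cohort, name, float(dates[j]),
                     q["source"].to_numpy()[j])
                )
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)
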