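"""Standardised dosing and time-varying exposure timelines.

Each prescription is reduced to a *prescription episode*: a start date, an
expected end (start + estimated duration), and a chlorpromazine-equivalent
defined daily dose (DDD).  The DDD is prescribed daily dose x tablet
strength, converted with the packaged per-drug equivalence table; values
outside the plausible 25-1000 mg range (or incomputable ones) are imputed
from the median of calculable DDDs for the same drug, falling back to the
drug-class median.  Durations are quantity / daily dose, bounded to
1-91.4 days with the same two-level median imputation.

Episodes are then stitched into a labelled timeline per patient:

* **current** — from a prescription's start to 30.4 days (one month) after
  the expected end of treatment; a repeat script starting within that
  grace period extends the same current interval (the patient is assumed
  continuously treated);
* **recent** — from the end of current until 182.4 days (six months) after
  the expected end;
* **past** — any later follow-up, until censoring or a further
  prescription (which reopens current).

Within current intervals, sub-segments carry the dose band of the active
DDD (overlapping scripts sum; the one-month tail carries the dose of the
most recent script) and the band of running cumulative treated time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    CUM_DURATION_EDGES_DAYS,
    DAYS_PER_MONTH,
    DAYS_RECENT_WINDOW,
    DDD_VALID_RANGE_MG,
    DOSE_BAND_EDGES_MG,
    DURATION_VALID_RANGE_DAYS,
    ConfigError,
    load_drug_table,
)

logger = logging.getLogger(__name__)

# last-resort fallbacks when a dataset has no calculable values at all
DEFAULT_DDD_MG = 300.0
DEFAULT_DURATION_DAYS = 28.0

TIMELINE_COLUMNS = [
    "patient_id", "start", "end", "state", "dose_band",
    "cum_duration_band", "drug_class",
]


def dose_band(ddd_mg: float) -> str:
    """Daily-dose band: <200 mg low, 200-399 mg medium, >=400 mg high."""
    if not ddd_mg > 0:
        raise ValueError(f"ddd_mg must be positive, got {ddd_mg}")
    lo, hi = DOSE_BAND_EDGES_MG
    if ddd_mg < lo:
        return "low"
    if ddd_mg < hi:
        return "medium"
    return "high"


def cum_duration_band(cum_days: float) -> str:
    """Cumulative treated-time band: <1 year, 1-3 years, >3 years."""
    lo, hi = CUM_DURATION_EDGES_DAYS
    if cum_days < lo:
        return "<1y"
    if cum_days < hi:
        return "1-3y"
    return ">3y"


# ---------------------------------------------------------------------------
# DDD and duration with two-level median imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationTables:
    """Medians of calculable DDDs and durations (first pass over the data)."""

    ddd_by_drug: dict[str, float] = field(default_factory=dict)
    ddd_by_class: dict[str, float] = field(default_factory=dict)
    duration_by_drug: dict[str, float] = field(default_factory=dict)
    duration_by_class: dict[str, float] = field(default_factory=dict)


def _raw_ddd(rx: pd.DataFrame, drug_table: dict) -> np.ndarray:
    unknown = set(rx["drug_name"].unique()) - set(drug_table)
    if unknown:
        raise ConfigError(f"drugs missing from the conversion table: {sorted(unknown)}")
    factor = rx["drug_name"].map(lambda d: drug_table[d]["cpz_factor"]).to_numpy()
    return (
        rx["prescribed_daily_dose"].to_numpy(dtype=float)
        * rx["strength"].to_numpy(dtype=float)
        * factor
    )


def _raw_duration(rx: pd.DataFrame) -> np.ndarray:
    return rx["quantity"].to_numpy(dtype=float) / rx[
        "prescribed_daily_dose"
    ].to_numpy(dtype=float)


def build_imputation_tables(
    prescriptions: pd.DataFrame, drug_table: dict | None = None
) -> ImputationTables:
    """First pass: per-drug and per-class medians of the calculable values."""
    drug_table = drug_table or load_drug_table()
    tables = ImputationTables()
    if prescriptions.empty:
        return tables
    rx = prescriptions
    cls = rx["drug_name"].map(lambda d: drug_table[d]["class"])

    ddd = _raw_ddd(rx, drug_table)
    lo, hi = DDD_VALID_RANGE_MG
    ok = np.isfinite(ddd) & (ddd >= lo) & (ddd <= hi)
    if ok.any():
        s = pd.Series(ddd[ok])
        tables.ddd_by_drug = s.groupby(rx["drug_name"][ok].to_numpy()).median().to_dict()
        tables.ddd_by_class = s.groupby(cls[ok].to_numpy()).median().to_dict()

    dur = _raw_duration(rx)
    lo, hi = DURATION_VALID_RANGE_DAYS
    ok = np.isfinite(dur) & (dur >= lo) & (dur <= hi)
    if ok.any():
        s = pd.Series(dur[ok])
        tables.duration_by_drug = (
            s.groupby(rx["drug_name"][ok].to_numpy()).median().to_dict()
        )
        tables.duration_by_class = s.groupby(cls[ok].to_numpy()).median().to_dict()
    return tables


def compute_ddd(
    prescription, tables: ImputationTables, drug_table: dict | None = None
) -> tuple[float, bool]:
    """Chlorpromazine-equivalent DDD (mg/day) for one prescription.

    Returns ``(ddd_mg, imputed)``; out-of-range or incomputable values are
    replaced by the drug median, then the class median, then a documented
    package default.
    """
    drug_table = drug_table or load_drug_table()
    drug = prescription["drug_name"]
    if drug not in drug_table:
        raise ConfigError(f"drug missing from the conversion table: {drug!r}")
    pdd = prescription.get("prescribed_daily_dose")
    strength = prescription.get("strength")
    lo, hi = DDD_VALID_RANGE_MG
    if pdd is not None and strength is not None and np.isfinite(pdd) and np.isfinite(strength):
        raw = float(pdd) * float(strength) * drug_table[drug]["cpz_factor"]
        if lo <= raw <= hi:
            return raw, False
    cls = drug_table[drug]["class"]
    for fallback in (tables.ddd_by_drug.get(drug), tables.ddd_by_class.get(cls)):
        if fallback is not None:
            return float(fallback), True
    return DEFAULT_DDD_MG, True


def estimate_duration(
    prescription, tables: ImputationTables, drug_table: dict | None = None
) -> tuple[float, bool]:
    """Estimated days of treatment: quantity / daily dose, bounded 1-91.4."""
    drug_table = drug_table or load_drug_table()
    drug = prescription["drug_name"]
    qty = prescription.get("quantity")
    pdd = prescription.get("prescribed_daily_dose")
    lo, hi = DURATION_VALID_RANGE_DAYS
    if qty is not None and pdd is not None and np.isfinite(qty) and np.isfinite(pdd) and pdd > 0:
        raw = float(qty) / float(pdd)
        if lo <= raw <= hi:
            return raw, False
    cls = drug_table[drug]["class"]
    for fallback in (
        tables.duration_by_drug.get(drug),
        tables.duration_by_class.get(cls),
    ):
        if fallback is not None:
            return float(fallback), True
    return DEFAULT_DURATION_DAYS, True


def episodes_frame(
    prescriptions: pd.DataFrame,
    tables: ImputationTables | None = None,
    drug_table: dict | None = None,
) -> pd.DataFrame:
    """Vectorised episode table for all prescriptions.

    Columns: patient_id, start, expected_end, ddd_mg, ddd_imputed,
    duration_days, duration_imputed, drug_class.  Exact duplicate
    prescriptions are merged (logged).
    """
    drug_table = drug_table or load_drug_table()
    rx = prescriptions.copy()
    dup_keys = ["patient_id", "date", "drug_name", "quantity",
                "prescribed_daily_dose", "strength"]
    n_dup = int(rx.duplicated(subset=dup_keys).sum())
    if n_dup:
        logger.info("merged %d duplicate prescriptions", n_dup)
        rx = rx.drop_duplicates(subset=dup_keys)
    if tables is None:
        tables = build_imputation_tables(rx, drug_table)
    if rx.empty:
        return pd.DataFrame(
            columns=["patient_id", "start", "expected_end", "ddd_mg",
                     "ddd_imputed", "duration_days", "duration_imputed",
                     "drug_class"]
        )

    cls = rx["drug_name"].map(lambda d: drug_table[d]["class"]).to_numpy()

    ddd = _raw_ddd(rx, drug_table)
    lo, hi = DDD_VALID_RANGE_MG
    ddd_ok = np.isfinite(ddd) & (ddd >= lo) & (ddd <= hi)
    drug_med = rx["drug_name"].map(tables.ddd_by_drug).to_numpy(dtype=float)
    cls_med = pd.Series(cls).map(tables.ddd_by_class).to_numpy(dtype=float)
    imput = np.where(np.isfinite(drug_med), drug_med,
                     np.where(np.isfinite(cls_med), cls_med, DEFAULT_DDD_MG))
    ddd_final = np.where(ddd_ok, ddd, imput)

    dur = _raw_duration(rx)
    lo, hi = DURATION_VALID_RANGE_DAYS
    dur_ok = np.isfinite(dur) & (dur >= lo) & (dur <= hi)
    drug_med = rx["drug_name"].map(tables.duration_by_drug).to_numpy(dtype=float)
    cls_med = pd.Series(cls).map(tables.duration_by_class).to_numpy(dtype=float)
    imput = np.where(np.isfinite(drug_med), drug_med,
                     np.where(np.isfinite(cls_med), cls_med, DEFAULT_DURATION_DAYS))
    dur_final = np.where(dur_ok, dur, imput)

    start = rx["date"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "patient_id": rx["patient_id"].to_numpy(),
            "start": start,
            "expected_end": start + dur_final,
            "ddd_mg": ddd_final,
            "ddd_imputed": ~ddd_ok,
            "duration_days": dur_final,
            "duration_imputed": ~dur_ok,
            "drug_class": cls,
        }
    )
    return out.sort_values(["patient_id", "start"], kind="mergesort").reset_index(
        drop=True
    )


def imputation_summary(episodes: pd.DataFrame) -> dict[str, float]:
    """Counts and fractions of imputed DDDs and durations."""
    n = max(len(episodes), 1)
    return {
        "n_prescriptions": int(len(episodes)),
        "n_ddd_imputed": int(episodes["ddd_imputed"].sum()) if len(episodes) else 0,
        "frac_ddd_imputed": float(episodes["ddd_imputed"].sum()) / n if len(episodes) else 0.0,
        "n_duration_imputed": int(episodes["duration_imputed"].sum()) if len(episodes) else 0,
        "frac_duration_imputed": float(episodes["duration_imputed"].sum()) / n if len(episodes) else 0.0,
    }


# ---------------------------------------------------------------------------
# Timeline construction
# ---------------------------------------------------------------------------

def _timeline_rows(
    pid,
    start: np.ndarray,
    exp_end: np.ndarray,
    ddd: np.ndarray,
    cls: np.ndarray,
    censor_date: float,
) -> list[tuple]:
    """Core timeline sweep for one patient (episode arrays sorted by start)."""
    keep = start < censor_date
    if not keep.all():
        start, exp_end, ddd, cls = start[keep], exp_end[keep], ddd[keep], cls[keep]
    if len(start) == 0:
        return []

    # stitch into chains: a script starting within the grace period of the
    # running expected end continues the same current interval
    chains: list[tuple[float, float, list[int]]] = []  # (start, E, member idx)
    for j in range(len(start)):
        if chains and start[j] <= chains[-1][1] + DAYS_PER_MONTH:
            cs, ce, members = chains[-1]
            members.append(j)
            chains[-1] = (cs, max(ce, exp_end[j]), members)
        else:
            chains.append((start[j], exp_end[j], [j]))

    segments: list[tuple[float, float, str, int]] = []  # start, end, state, chain
    for i, (cs, ce, _members) in enumerate(chains):
        nxt = chains[i + 1][0] if i + 1 < len(chains) else np.inf
        cur_end = min(ce + DAYS_PER_MONTH, censor_date)
        if cur_end > cs:
            segments.append((cs, cur_end, "current", i))
        rec_end = min(ce + DAYS_RECENT_WINDOW, nxt, censor_date)
        if rec_end > cur_end:
            segments.append((cur_end, rec_end, "recent", i))
        past_end = min(nxt, censor_date)
        if past_end > rec_end:
            segments.append((rec_end, past_end, "past", i))

    # dose profile inside each chain: sum of DDDs of active scripts, the
    # most recent script's dose during the grace tail
    rows: list[tuple] = []
    cum = 0.0  # cumulative treated (current) days so far
    edges = CUM_DURATION_EDGES_DAYS
    for seg_start, seg_end, state, ci in segments:
        if state != "current":
            rows.append((pid, seg_start, seg_end, state, None, None, None))
            continue
        members = chains[ci][2]
        bounds = {seg_start, seg_end}
        for j in members:
            if seg_start < start[j] < seg_end:
                bounds.add(start[j])
            if seg_start < exp_end[j] < seg_end:
                bounds.add(exp_end[j])
        # cumulative-duration band crossings within this current segment
        for e in edges:
            t_cross = seg_start + (e - cum)
            if seg_start < t_cross < seg_end:
                bounds.add(t_cross)
        pts = sorted(bounds)
        for t0, t1 in zip(pts[:-1], pts[1:]):
            active = [j for j in members if start[j] <= t0 < exp_end[j]]
            if active:
                dose = float(sum(ddd[j] for j in active))
                classes = {cls[j] for j in active}
            else:  # grace tail: most recent script governs
                last = max(
                    (j for j in members if start[j] <= t0),
                    key=lambda j: (start[j], j),
                )
                dose = float(ddd[last])
                classes = {cls[last]}
            band = dose_band(dose) if dose > 0 else None
            cum_band = cum_duration_band(cum + (t0 - seg_start))
            drug_cls = classes.pop() if len(classes) == 1 else "mixed"
            rows.append((pid, t0, t1, "current", band, cum_band, drug_cls))
        cum += seg_end - seg_start

    return rows


def build_timeline(episodes: pd.DataFrame, censor_date: float) -> pd.DataFrame:
    """Exposure timeline for a single patient.

    ``episodes`` holds that patient's prescription episodes (sorted or
    not); the returned intervals are disjoint, ordered, half-open, and
    partition ``[first prescription, censor_date)`` exactly.  Dose and
    cumulative-duration bands are attached to current segments only.
    """
    if episodes.empty:
        return pd.DataFrame(columns=TIMELINE_COLUMNS)
    order = np.argsort(episodes["start"].to_numpy(), kind="stable")
    rows = _timeline_rows(
        episodes["patient_id"].iloc[0],
        episodes["start"].to_numpy(dtype=float)[order],
        episodes["expected_end"].to_numpy(dtype=float)[order],
        episodes["ddd_mg"].to_numpy(dtype=float)[order],
        episodes["drug_class"].to_numpy()[order],
        float(censor_date),
    )
    return pd.DataFrame(rows, columns=TIMELINE_COLUMNS)


def build_timelines(
    episodes: pd.DataFrame, censor_by_patient: pd.Series
) -> pd.DataFrame:
    """Timelines for many patients (censor dates indexed by patient_id).

    One pass over the episode table grouped by contiguous patient blocks;
    all rows are assembled into a single frame at the end.
    """
    if episodes.empty:
        return pd.DataFrame(columns=TIMELINE_COLUMNS)
    eps = episodes.sort_values(["patient_id", "start"], kind="mergesort")
    pid = eps["patient_id"].to_numpy()
    start = eps["start"].to_numpy(dtype=float)
    exp_end = eps["expected_end"].to_numpy(dtype=float)
    ddd = eps["ddd_mg"].to_numpy(dtype=float)
    cls = eps["drug_class"].to_numpy()
    uniq, first_idx = np.unique(pid, return_index=True)
    bounds = np.append(first_idx, len(pid))
    censor = censor_by_patient
    rows: list[tuple] = []
    for k, p in enumerate(uniq):
        if p not in censor.index:
            continue
        a, b = bounds[k], bounds[k + 1]
        rows.extend(
            _timeline_rows(
                p, start[a:b], exp_end[a:b], ddd[a:b], cls[a:b],
                float(censor.loc[p]),
            )
        )
    return pd.DataFrame(rows, columns=TIMELINE_COLUMNS)
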