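"""Synthetic linked primary-care / hospital / death-registry generator.

Emulates the four record streams of a UK-style linked EHR study —
patient registry, antipsychotic prescriptions, coded clinical events
(primary-care Read-like, hospital ICD-10-like with admission/discharge
dates, death-certificate causes), and short free-text notes near deaths —
with a *known* treatment-effect and confounding structure, so that every
downstream stage (cohort construction, exposure algebra, adjudication,
Poisson estimation, hazard smoothing) can be validated against simulation
truth.

Event times are drawn from piecewise-constant hazards: each cause-level
outcome has a baseline rate (events/person-year) that is multiplied by
``true_rr[outcome]`` (optionally further by dose band) while the patient
is inside a *current exposure* window — a stitched chain of prescriptions
where successive scripts start within the 30.4-day grace period after the
expected end of the previous one — and by per-patient confounder
multipliers.  Death events terminate follow-up; there is no other
competition between outcomes.

All dates are integer day offsets from ``config.origin_date``; intervals
are half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    DOSE_BAND_EDGES_MG,
    SIM_DEATH_OUTCOMES,
    SIM_OUTCOMES,
    ConfigError,
    SimConfig,
    load_code_sets,
    load_drug_table,
    load_freetext_terms,
    read_code_for,
)

# underscore-prefixed columns carry simulation truth and are stripped on export
TRUTH_COLUMNS_PATIENTS = ("_treated", "_conf_hazard_mult")
TRUTH_COLUMNS_RX = ("_duration", "_ddd_mg")
TRUTH_COLUMNS_NOTES = ("truth_label",)  # held out from the pipeline, kept in file

_GENERAL_HOSP_CODES = ["J18", "K52", "N39", "S72", "I50", "E11"]
_OTHER_DEATH_CODES = ["C34", "C50", "C61", "J18", "J44", "G30", "K70", "N18"]
_CARDIAC_NONSUDDEN_CODES = ["I21", "I25", "I20", "I70.9", "I51.6", "I11.9"]
_SUICIDE_DEATH_CODES = ["X60", "X70", "X78"]


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    """Independent, reproducible stream per generation stage."""
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def _group_exclusive_cumsum(values: np.ndarray, group_ids: np.ndarray) -> np.ndarray:
    """Exclusive cumulative sum within consecutive groups (flat layout)."""
    cs = np.cumsum(values)
    out = np.empty_like(cs)
    out[0] = 0.0
    out[1:] = cs[:-1]
    is_first = np.empty(len(values), dtype=bool)
    is_first[0] = True
    is_first[1:] = group_ids[1:] != group_ids[:-1]
    # subtract the running total at each group's first element
    base = np.where(is_first, out, 0.0)
    first_idx = np.maximum.accumulate(np.where(is_first, np.arange(len(values)), 0))
    return out - base[first_idx]


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def generate_population(config: SimConfig) -> pd.DataFrame:
    """Simulate the patient registry with covariates and psychiatric history.

    Returns one row per patient.  ``psych_diagnoses`` is serialised as
    ``disease@day|disease@day`` (first-record date per disease);
    underscore columns (treatment-assignment truth, confounder hazard
    multiplier) are internal and stripped when tables are written.
    """
    rng = _rng(config, 1)
    n = config.n_patients
    horizon = config.horizon_days

    patient_id = np.arange(1, n + 1)
    practice_id = rng.integers(1, config.n_practices + 1, size=n)
    sex = np.where(rng.random(n) < 0.58, "F", "M")

    age_at_origin = np.clip(rng.normal(55.0, 20.0, size=n), 18.0, 95.0)
    birth_year = config.origin_date.year - age_at_origin.astype(int)

    registration = rng.uniform(-3 * DAYS_PER_YEAR, 6 * DAYS_PER_YEAR, size=n).astype(int)
    data_start = np.maximum(registration, 0)
    # guarantee a positive observable window
    data_start = np.minimum(data_start, horizon - 60).astype(int)
    registration = np.minimum(registration, data_start)

    transfer = np.full(n, np.nan)
    has_transfer = rng.random(n) < config.transfer_out_prob
    k = int(has_transfer.sum())
    transfer[has_transfer] = np.floor(
        data_start[has_transfer]
        + 30.0
        + rng.random(k) * (horizon - data_start[has_transfer] - 31.0)
    )
    admin_end = np.where(np.isnan(transfer), np.floor(horizon), transfer).astype(int)

    smoking = rng.choice(["non", "ex", "current"], size=n, p=[0.49, 0.20, 0.31])
    bmi = np.round(rng.normal(26.0, 5.0, size=n), 1)
    covs = {
        name: (rng.random(n) < prev).astype(int)
        for name, prev in config.covariate_prevalence.items()
    }
    deprivation = rng.integers(1, 6, size=n)

    # psychiatric diagnoses: independent first-record dates per disease
    psych_parts = [np.array([""] * n, dtype=object)]
    first_psych = np.full(n, np.inf)
    diag_strings = np.full(n, "", dtype=object)
    for disease, prev in config.psych_prevalence.items():
        has = rng.random(n) < prev
        day = np.floor(
            data_start + rng.random(n) * np.maximum(admin_end - data_start, 1)
        ).astype(int)
        for i in np.flatnonzero(has):
            part = f"{disease}@{day[i]}"
            diag_strings[i] = part if diag_strings[i] == "" else diag_strings[i] + "|" + part
        first_psych = np.where(has, np.minimum(first_psych, day), first_psych)
    has_psych = np.isfinite(first_psych)

    # treatment assignment: base odds by psychiatric status, shifted by
    # configured confounder effects (binary covariates only)
    base_p = np.where(has_psych, config.treatment_given_psych, config.treatment_given_nonpsych)
    with np.errstate(divide="ignore"):
        odds = base_p / (1.0 - base_p)
    hazard_mult = np.ones(n)
    for cov, (odds_mult, haz_mult) in config.confounder_effects.items():
        if cov not in covs:
            raise ConfigError(
                f"confounder_effects key {cov!r} is not a binary patient covariate"
            )
        x = covs[cov]
        odds = odds * np.power(float(odds_mult), x)
        hazard_mult = hazard_mult * np.power(float(haz_mult), x)
    p_treat = np.where(np.isinf(odds), 1.0, odds / (1.0 + odds))
    treated = rng.random(n) < p_treat

    # inject covariate missingness
    miss = config.missing_rates
    if miss.get("smoking", 0) > 0:
        smoking = np.where(rng.random(n) < miss["smoking"], "missing", smoking)
    if miss.get("bmi", 0) > 0:
        bmi = np.where(rng.random(n) < miss["bmi"], np.nan, bmi)

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "practice_id": practice_id,
            "sex": sex,
            "birth_year": birth_year,
            "registration_date": registration,
            "data_start": data_start,
            "transfer_out": transfer,
            "death_date": np.full(n, np.nan),
            "smoking": smoking,
            "bmi": bmi,
            **covs,
            "deprivation": deprivation,
            "psych_diagnoses": diag_strings,
            "_treated": treated,
            "_conf_hazard_mult": hazard_mult,
        }
    )
    return patients


def explode_psych_diagnoses(patients: pd.DataFrame) -> pd.DataFrame:
    """Long table (patient_id, disease, day) from the serialised column."""
    rows: list[tuple[int, str, int]] = []
    col = patients["psych_diagnoses"].fillna("")
    for pid, s in zip(patients["patient_id"].to_numpy(), col.to_numpy()):
        if not s:
            continue
        for part in s.split("|"):
            disease, day = part.split("@")
            rows.append((pid, disease, int(day)))
    return pd.DataFrame(rows, columns=["patient_id", "disease", "day"])


def first_psych_day(patients: pd.DataFrame) -> pd.Series:
    """First psychiatric first-record day per patient (NaN if none)."""
    long = explode_psych_diagnoses(patients)
    if long.empty:
        return pd.Series(np.nan, index=patients["patient_id"], name="first_psych")
    first = long.groupby("patient_id")["day"].min()
    return first.reindex(patients["patient_id"]).rename("first_psych")


# ---------------------------------------------------------------------------
# Prescribing
# ---------------------------------------------------------------------------

def generate_prescribing(patients: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Simulate repeat antipsychotic prescriptions for treated patients.

    Chains of scripts with stochastic inter-script gaps (mostly shorter
    than the 30.4-day grace period, some longer, to exercise episode
    stitching downstream).  Daily dose targets are drawn from a
    chlorpromazine-equivalent menu spanning the low/medium/high bands and
    realised as (quantity, tablets/day, mg/tablet) triples; some of those
    fields are then nulled per ``missing_rates`` to exercise imputation.
    """
    rng = _rng(config, 2)
    drug_table = load_drug_table()
    typicals = sorted(d for d, r in drug_table.items() if r["class"] == "typical")
    atypicals = sorted(d for d, r in drug_table.items() if r["class"] == "atypical")

    treated = patients[patients["_treated"].astype(bool)]
    if treated.empty:
        return _empty_rx()

    pid = treated["patient_id"].to_numpy()
    data_start = treated["data_start"].to_numpy(dtype=float)
    registration = treated["registration_date"].to_numpy(dtype=float)
    horizon = config.horizon_days
    transfer = treated["transfer_out"].to_numpy(dtype=float)
    admin_end = np.where(np.isnan(transfer), np.floor(horizon), transfer)

    first_dx = first_psych_day(patients).to_numpy()[treated.index.to_numpy()] \
        if len(patients) else np.full(len(treated), np.nan)
    lower = np.where(np.isnan(first_dx), data_start, np.maximum(first_dx, data_start))
    start0 = np.floor(lower + rng.random(len(treated)) * np.maximum(admin_end - lower, 1) * 0.7)

    n_rx = np.minimum(rng.geometric(max(config.rx_stop_prob, 1e-6), size=len(treated)), 400)
    m = int(n_rx.sum())
    rx_pid = np.repeat(pid, n_rx)
    rx_gid = np.repeat(np.arange(len(treated)), n_rx)

    quantity = rng.choice(np.asarray(config.quantity_choices, dtype=float), size=m)
    pdd = rng.choice(np.asarray(config.pdd_choices, dtype=float), size=m)
    duration = quantity / pdd

    short = rng.random(m) < config.gap_short_prob
    gap = np.where(
        short,
        rng.uniform(*config.gap_short_range, size=m),
        rng.uniform(*config.gap_long_range, size=m),
    )
    step = duration + gap
    offset = _group_exclusive_cumsum(step, rx_gid)
    start = np.floor(np.repeat(start0, n_rx) + offset)

    # drug per patient with occasional switches
    pat_is_typical = rng.random(len(treated)) < config.typical_fraction
    pat_drug = np.where(
        pat_is_typical,
        rng.choice(typicals, size=len(treated)),
        rng.choice(atypicals, size=len(treated)),
    ).astype(object)
    drug = np.repeat(pat_drug, n_rx)
    switch = rng.random(m) < 0.05
    k_switch = int(switch.sum())
    sw_typical = rng.random(k_switch) < config.typical_fraction
    drug[switch] = np.where(
        sw_typical,
        rng.choice(typicals, size=k_switch),
        rng.choice(atypicals, size=k_switch),
    )

    levels = np.asarray(config.dose_menu["levels_mg"], dtype=float)
    weights = np.asarray(config.dose_menu["weights"], dtype=float)
    target = rng.choice(levels, size=m, p=weights / weights.sum())
    factor = np.array([drug_table[d]["cpz_factor"] for d in drug])
    strength = target / (pdd * factor)

    rx = pd.DataFrame(
        {
            "patient_id": rx_pid,
            "date": start,
            "drug_name": drug,
            "drug_class": [drug_table[d]["class"] for d in drug],
            "quantity": quantity,
            "prescribed_daily_dose": pdd,
            "strength": strength,
            "_duration": duration,
            "_ddd_mg": target,
        }
    )
    end_per_rx = np.repeat(admin_end, n_rx)
    rx = rx[rx["date"] < end_per_rx].reset_index(drop=True)

    # pre-study scripts for a fraction of treated patients registered
    # before the study window: these make them *prevalent* users
    can_prev = registration < -30
    is_prev = can_prev & (rng.random(len(treated)) < config.prevalent_fraction)
    if is_prev.any():
        k = int(is_prev.sum())
        pre_date = np.floor(registration[is_prev] + rng.random(k) * (-registration[is_prev] - 1))
        pre = pd.DataFrame(
            {
                "patient_id": pid[is_prev],
                "date": pre_date,
                "drug_name": pat_drug[is_prev],
                "drug_class": [drug_table[d]["class"] for d in pat_drug[is_prev]],
                "quantity": rng.choice(np.asarray(config.quantity_choices, float), size=k),
                "prescribed_daily_dose": rng.choice(np.asarray(config.pdd_choices, float), size=k),
                "strength": np.full(k, np.nan),
                "_duration": np.full(k, 28.0),
                "_ddd_mg": np.full(k, np.nan),
            }
        )
        rx = pd.concat([rx, pre], ignore_index=True)

    # field-level missingness
    miss = config.missing_rates
    for colname in ("quantity", "prescribed_daily_dose", "strength"):
        rate = miss.get(colname, 0.0)
        if rate > 0:
            nulled = rng.random(len(rx)) < rate
            rx.loc[nulled, colname] = np.nan

    rx = rx.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)
    return rx


def _empty_rx() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype=int),
            "date": pd.Series(dtype=float),
            "drug_name": pd.Series(dtype=object),
            "drug_class": pd.Series(dtype=object),
            "quantity": pd.Series(dtype=float),
            "prescribed_daily_dose": pd.Series(dtype=float),
            "strength": pd.Series(dtype=float),
            "_duration": pd.Series(dtype=float),
            "_ddd_mg": pd.Series(dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# Truth exposure windows (generator-internal; downstream recomputes its own)
# ---------------------------------------------------------------------------

def truth_current_windows(rx: pd.DataFrame) -> pd.DataFrame:
    """Stitched current-exposure windows from the generator's true durations.

    A script starting within 30.4 days of the running expected end of
    treatment extends the chain; the window is [chain start,
    last expected end + 30.4).  Columns: patient_id, start, end.
    """
    if rx.empty:
        return pd.DataFrame(columns=["patient_id", "start", "end"])
    df = rx.sort_values(["patient_id", "date"], kind="mergesort")
    start = df["date"].to_numpy(dtype=float)
    expected_end = start + df["_duration"].to_numpy(dtype=float)
    pid = df["patient_id"].to_numpy()
    run_end = pd.Series(expected_end).groupby(pid).cummax().to_numpy()
    prev_run = np.empty_like(run_end)
    prev_run[0] = -np.inf
    prev_run[1:] = run_end[:-1]
    same = np.empty(len(df), dtype=bool)
    same[0] = False
    same[1:] = pid[1:] == pid[:-1]
    new_chain = ~same | (start > prev_run + DAYS_PER_MONTH)
    chain_id = np.cumsum(new_chain)
    chains = pd.DataFrame(
        {"patient_id": pid, "chain": chain_id, "start": start, "E": expected_end}
    ).groupby("chain").agg(
        patient_id=("patient_id", "first"), start=("start", "min"), E=("E", "max")
    )
    chains["end"] = chains["E"] + DAYS_PER_MONTH
    return chains[["patient_id", "start", "end"]].reset_index(drop=True)


def _dose_band(ddd: np.ndarray) -> np.ndarray:
    lo, hi = DOSE_BAND_EDGES_MG
    return np.where(ddd < lo, "low", np.where(ddd < hi, "medium", "high")).astype(object)


def _hazard_pieces(
    patients: pd.DataFrame,
    rx: pd.DataFrame,
    config: SimConfig,
    dose_dependent: bool,
) -> pd.DataFrame:
    """Piecewise exposure structure per patient over [data_start, admin_end).

    Returns rows (patient_id, t0, t1, in_current, band) sorted by patient
    then time.  ``band`` is the active dose band where in_current (from the
    generator's true chlorpromazine-equivalent dose of the governing
    script), else "".
    """
    pats = patients
    pid = pats["patient_id"].to_numpy()
    t_start = pats["data_start"].to_numpy(dtype=float)
    transfer = pats["transfer_out"].to_numpy(dtype=float)
    t_end = np.where(np.isnan(transfer), np.floor(config.horizon_days), transfer)

    frames = [
        pd.DataFrame({"patient_id": pid, "t": t_start, "kind": 0, "delta": 0, "band": ""}),
    ]
    chains = truth_current_windows(rx)
    if not chains.empty:
        bounds = pd.DataFrame(
            {
                "patient_id": pats["patient_id"],
                "lo": t_start,
                "hi": t_end,
            }
        )
        ch = chains.merge(bounds, on="patient_id", how="left")
        ch["start"] = ch["start"].clip(lower=ch["lo"])
        ch["end"] = ch["end"].clip(upper=ch["hi"])
        ch = ch[ch["start"] < ch["end"]]
        frames.append(
            pd.DataFrame(
                {"patient_id": ch["patient_id"], "t": ch["start"], "kind": 1,
                 "delta": 1, "band": ""}
            )
        )
        frames.append(
            pd.DataFrame(
                {"patient_id": ch["patient_id"], "t": ch["end"], "kind": 2,
                 "delta": -1, "band": ""}
            )
        )
        if dose_dependent and not rx.empty:
            dd = rx.dropna(subset=["_ddd_mg"])
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": dd["patient_id"],
                        "t": dd["date"].astype(float),
                        "kind": 3,
                        "delta": 0,
                        "band": _dose_band(dd["_ddd_mg"].to_numpy()),
                    }
                )
            )
    pts = pd.concat(frames, ignore_index=True)
    pts = pts.sort_values(["patient_id", "t", "kind"], kind="mergesort")
    pts["cur"] = pts.groupby("patient_id")["delta"].cumsum() > 0
    if dose_dependent:
        band = pts["band"].replace("", np.nan)
        pts["band"] = band.groupby(pts["patient_id"]).ffill().fillna("low")
    else:
        pts["band"] = ""

    end_map = pd.Series(t_end, index=pid)
    pts["t1"] = pts.groupby("patient_id")["t"].shift(-1)
    last = pts["t1"].isna()
    pts.loc[last, "t1"] = pts.loc[last, "patient_id"].map(end_map).to_numpy()
    pieces = pts.rename(columns={"t": "t0"})[
        ["patient_id", "t0", "t1", "cur", "band"]
    ]
    pieces = pieces[pieces["t1"] > pieces["t0"]].reset_index(drop=True)
    return pieces


def _sample_event_times(
    pieces: pd.DataFrame,
    rate_per_day: np.ndarray,
    targets: pd.Series,
    rng: np.random.Generator,
) -> pd.Series:
    """First event time per patient from piecewise-constant hazards.

    ``targets`` is an Exp(1) draw indexed by patient_id; inverse-CDF walk
    over the cumulative piece hazards.  Returns event day (float) indexed
    by patient_id, only for patients whose event falls inside follow-up.
    """
    lens = pieces["t1"].to_numpy() - pieces["t0"].to_numpy()
    contrib = lens * rate_per_day
    cum = pd.Series(contrib).groupby(pieces["patient_id"].to_numpy()).cumsum().to_numpy()
    tgt = targets.reindex(pieces["patient_id"]).to_numpy()
    hit = cum >= tgt
    if not hit.any():
        return pd.Series(dtype=float)
    sel = pieces[hit].copy()
    sel["cum"] = cum[hit]
    sel["rate"] = rate_per_day[hit]
    first = sel.groupby("patient_id").head(1).set_index("patient_id")
    prev_cum = first["cum"] - (first["t1"] - first["t0"]) * first["rate"]
    t = first["t0"] + (targets.reindex(first.index) - prev_cum) / first["rate"]
    return t


def generate_outcomes(
    patients: pd.DataFrame, rx: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate outcome events and emit coded events plus free-text notes.

    Fills ``patients["death_date"]`` in place (death terminates
    follow-up).  Returns ``(events, freetext)``:

    * ``events`` — rows (patient_id, date, source, code, admission_date,
      discharge_date) covering death certificates, primary-care Read-like
      codes, hospital episodes (incidental and outcome-linked, including a
      configurable fraction of deaths with a discharge shortly before
      death, to exercise the out-of-hospital rule of the narrow
      sudden-death definition), psychiatric first records and the cohort
      exclusion conditions;
    * ``freetext`` — notes within (mostly) three weeks of a death, with a
      held-out ``truth_label`` used only for test scoring.
    """
    rng = _rng(config, 3)
    n = len(patients)
    pid = patients["patient_id"].to_numpy()
    conf_mult = patients["_conf_hazard_mult"].to_numpy(dtype=float)
    conf_by_pid = pd.Series(conf_mult, index=pid)
    transfer = patients["transfer_out"].to_numpy(dtype=float)
    admin_end = np.where(np.isnan(transfer), np.floor(config.horizon_days), transfer)
    end_by_pid = pd.Series(admin_end, index=pid)

    event_times: dict[str, pd.Series] = {}
    for outcome in SIM_OUTCOMES:
        base = config.baseline_hazards.get(outcome, 0.0)
        if base <= 0:
            event_times[outcome] = pd.Series(dtype=float)
            continue
        dose_rr = config.true_rr_by_dose.get(outcome, {})
        pieces = _hazard_pieces(patients, rx, config, dose_dependent=bool(dose_rr))
        rr = config.true_rr.get(outcome, 1.0)
        mult = np.where(pieces["cur"].to_numpy(), rr, 1.0)
        if dose_rr:
            band_mult = pieces["band"].map(lambda b: dose_rr.get(b, 1.0)).to_numpy()
            mult = mult * np.where(pieces["cur"].to_numpy(), band_mult, 1.0)
        rate_day = (
            base / DAYS_PER_YEAR
            * mult
            * conf_by_pid.reindex(pieces["patient_id"]).to_numpy()
        )
        targets = pd.Series(rng.exponential(size=n), index=pid)
        event_times[outcome] = _sample_event_times(pieces, rate_day, targets, rng)

    # death = earliest death-type event; truncates everything else
    death = pd.Series(np.inf, index=pid)
    cause = pd.Series("", index=pid, dtype=object)
    for outcome in SIM_DEATH_OUTCOMES:
        t = event_times[outcome]
        if t.empty:
            continue
        t = t.reindex(pid)
        better = t.notna() & (t < death)
        death[better] = t[better]
        cause[better] = outcome
    death = death.where(death < end_by_pid, np.inf)
    cause = cause.where(np.isfinite(death), "")
    death_day = np.floor(death)

    patients["death_date"] = np.where(np.isfinite(death), death_day, np.nan)
    # a transfer after death is meaningless; drop it
    tr = patients["transfer_out"].to_numpy(dtype=float)
    patients["transfer_out"] = np.where(
        np.isfinite(death) & (tr >= death_day), np.nan, tr
    )

    follow_end = pd.Series(np.where(np.isfinite(death), death_day, admin_end), index=pid)

    ev_frames: list[pd.DataFrame] = []
    notes: list[dict] = []

    dead_pid = pid[np.isfinite(death)]
    dead_day = death_day[np.isfinite(death)]
    dead_cause = cause[np.isfinite(death)].to_numpy()

    # --- death certificates -------------------------------------------------
    code_menu = {
        "scd": load_code_sets()["outcomes"]["scd_primary"]["icd"],
        "cardiac_other_death": _CARDIAC_NONSUDDEN_CODES,
        "other_death": _OTHER_DEATH_CODES,
        "suicide": _SUICIDE_DEATH_CODES,
    }
    dc_codes = np.array(
        [rng.choice(code_menu[c]) for c in dead_cause], dtype=object
    ) if len(dead_cause) else np.array([], dtype=object)
    ev_frames.append(
        pd.DataFrame(
            {
                "patient_id": dead_pid,
                "date": dead_day,
                "source": "death_certificate",
                "code": dc_codes,
                "admission_date": np.nan,
                "discharge_date": np.nan,
            }
        )
    )

    # --- GP also codes some deaths (enables the registry-only definition) ---
    gp_codes = rng.random(len(dead_pid)) < config.read_death_code_prob
    if gp_codes.any():
        k = int(gp_codes.sum())
        ev_frames.append(
            pd.DataFrame(
                {
                    "patient_id": dead_pid[gp_codes],
                    "date": dead_day[gp_codes] + rng.integers(0, 6, size=k),
                    "source": "primary_care",
                    "code": [read_code_for(c) for c in dc_codes[gp_codes]],
                    "admission_date": np.nan,
                    "discharge_date": np.nan,
                }
            )
        )

    # --- hospital episode ending shortly before death -----------------------
    near_hosp = rng.random(len(dead_pid)) < config.hosp_before_death_frac
    if near_hosp.any():
        k = int(near_hosp.sum())
        discharge = dead_day[near_hosp] - rng.integers(1, 46, size=k)
        admission = discharge - rng.integers(1, 15, size=k)
        reg_by_pid = pd.Series(
            patients["registration_date"].to_numpy(dtype=float), index=pid
        )
        reg_near = reg_by_pid.reindex(dead_pid[near_hosp]).to_numpy()
        admission = np.maximum(admission, reg_near)
        keep = (discharge >= 0) & (admission <= discharge)
        ev_frames.append(
            pd.DataFrame(
                {
                    "patient_id": dead_pid[near_hosp][keep],
                    "date": admission[keep],
                    "source": "hospital",
                    "code": rng.choice(_GENERAL_HOSP_CODES, size=int(keep.sum())),
                    "admission_date": admission[keep],
                    "discharge_date": discharge[keep],
                }
            )
        )

    # --- background hospitalisations ---------------------------------------
    fu_years = np.maximum(
        (follow_end.to_numpy() - patients["data_start"].to_numpy()) / DAYS_PER_YEAR, 0
    )
    n_hosp = rng.poisson(config.background_hosp_rate * fu_years)
    if n_hosp.sum() > 0:
        h_pid = np.repeat(pid, n_hosp)
        h_start = np.repeat(patients["data_start"].to_numpy(dtype=float), n_hosp)
        h_end = np.repeat(follow_end.to_numpy(), n_hosp)
        adm = np.floor(h_start + rng.random(int(n_hosp.sum())) * np.maximum(h_end - h_start, 1))
        dis = adm + rng.integers(1, 11, size=len(adm))
        ev_frames.append(
            pd.DataFrame(
                {
                    "patient_id": h_pid,
                    "date": adm,
                    "source": "hospital",
                    "code": rng.choice(_GENERAL_HOSP_CODES, size=len(adm)),
                    "admission_date": adm,
                    "discharge_date": np.minimum(dis, np.repeat(np.floor(config.horizon_days), len(adm))),
                }
            )
        )

    # --- nonfatal outcomes: CHD and ventricular arrhythmia ------------------
    for outcome, icds in (("chd", ["I21", "I22"]), ("ventricular_arrhythmia", ["I49.0"])):
        t = event_times[outcome]
        if t.empty:
            continue
        t = t[t < follow_end.reindex(t.index)]
        if t.empty:
            continue
        day = np.floor(t.to_numpy())
        icd = rng.choice(icds, size=len(t))
        route = rng.random(len(t))
        hosp_mask = route < 0.7
        if hosp_mask.any():
            dis = day[hosp_mask] + rng.integers(1, 11, size=int(hosp_mask.sum()))
            ev_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": t.index.to_numpy()[hosp_mask],
                        "date": day[hosp_mask],
                        "source": "hospital",
                        "code": icd[hosp_mask],
                        "admission_date": day[hosp_mask],
                        "discharge_date": dis,
                    }
                )
            )
        gp_mask = ~hosp_mask | (rng.random(len(t)) < 0.3)
        if gp_mask.any():
            ev_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": t.index.to_numpy()[gp_mask],
                        "date": day[gp_mask],
                        "source": "primary_care",
                        "code": [read_code_for(c) for c in icd[gp_mask]],
                        "admission_date": np.nan,
                        "discharge_date": np.nan,
                    }
                )
            )

    # --- psychiatric first records as primary-care codes --------------------
    psych_long = explode_psych_diagnoses(patients)
    if not psych_long.empty:
        ev_frames.append(
            pd.DataFrame(
                {
                    "patient_id": psych_long["patient_id"],
                    "date": psych_long["day"].astype(float),
                    "source": "primary_care",
                    "code": "PSY." + psych_long["disease"],
                    "admission_date": np.nan,
                    "discharge_date": np.nan,
                }
            )
        )

    # --- cohort exclusion conditions ----------------------------------------
    code_sets = load_code_sets()
    reg = patients["registration_date"].to_numpy(dtype=float)
    for prev, codes, lo in (
        (config.exclusion_anytime_prev, code_sets["exclusions"]["any_time"]["read"], reg),
        (
            config.exclusion_vt_prev,
            code_sets["exclusions"]["pre_registration_and_pre_index"]["read"],
            reg,
        ),
    ):
        has = rng.random(n) < prev
        if has.any():
            k = int(has.sum())
            day = np.floor(lo[has] + rng.random(k) * np.maximum(admin_end[has] - lo[has], 1))
            ev_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[has],
                        "date": day,
                        "source": "primary_care",
                        "code": rng.choice(codes, size=k),
                        "admission_date": np.nan,
                        "discharge_date": np.nan,
                    }
                )
            )

    # --- free-text notes near deaths ----------------------------------------
    terms = load_freetext_terms()
    triggers = terms["triggers"]
    exclusions = terms["exclusion_phrases"]
    verbose_cutoff = (config.n_practices + 1) // 2
    practice_by_pid = pd.Series(patients["practice_id"].to_numpy(), index=pid)
    filler = (
        " Long consultation note with detailed history, medication review,"
        " examination findings and follow-up plan recorded by the practice."
    )
    for p, day, cs in zip(dead_pid, dead_day, dead_cause):
        if rng.random() >= config.note_prob_death:
            continue
        # mostly inside the +-21-day search window, occasionally outside
        if rng.random() < 0.1:
            note_day = day + rng.integers(25, 41)
        else:
            note_day = day + rng.integers(-10, 11)
        if cs == "scd":
            if rng.random() < config.trigger_prob_scd:
                trig = triggers[int(rng.integers(len(triggers)))]
                text = f"Relative reports patient {trig} at home. GP informed."
            else:
                text = "Found deceased at home; certification arranged."
            label = "true_scd"
        else:
            label = "other_cause"
            if rng.random() < config.trigger_prob_other:
                trig = triggers[int(rng.integers(len(triggers)))]
                if rng.random() < config.exclusion_phrase_prob:
                    phrase = exclusions[int(rng.integers(len(exclusions)))]
                    text = f"Reported {trig} - {phrase} confirmed by coroner."
                else:
                    text = f"Family state patient {trig}; no further details."
            else:
                text = "Death notification received; records updated."
        if int(practice_by_pid.loc[p]) <= verbose_cutoff:
            text = text + filler
        notes.append(
            {"patient_id": p, "date": float(note_day), "text": text, "truth_label": label}
        )

    events = pd.concat(ev_frames, ignore_index=True)
    events["date"] = events["date"].astype(float)
    events = events.sort_values(["patient_id", "date", "source"], kind="mergesort")
    events = events.reset_index(drop=True)
    freetext = pd.DataFrame(
        notes, columns=["patient_id", "date", "text", "truth_label"]
    )
    return events, freetext


def simulate(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Run the full generator; returns the four linked tables."""
    patients = generate_population(config)
    rx = generate_prescribing(patients, config)
    events, freetext = generate_outcomes(patients, rx, config)
    # scripts dated after a simulated death never make it into the record
    death = patients.set_index("patient_id")["death_date"]
    rx_death = death.reindex(rx["patient_id"]).to_numpy(dtype=float)
    rx = rx[~(rx["date"].to_numpy() >= rx_death)].reset_index(drop=True)
    return {
        "patients": patients,
        "prescriptions": rx,
        "events": events,
        "freetext": freetext,
    }
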