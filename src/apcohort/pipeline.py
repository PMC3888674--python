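"""End-to-end orchestration: simulate -> cohorts -> exposure -> outcomes ->
rates -> smoothed hazards, with delimited-file I/O, input validation and a
run manifest.

Tables are flat CSV (comma, UTF-8) with ISO calendar dates; internally all
dates are day offsets from the run's origin date.  A run writes every
stage's output plus ``manifest.json`` (config hash, seed, per-stage row
counts, exclusion flow), and re-running with the same configuration
reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohorts as cohorts_mod
from . import exposure as exposure_mod
from . import hazard as hazard_mod
from . import outcomes as outcomes_mod
from . import rates as rates_mod
from .config import (
    ANALYSIS_OUTCOMES,
    DAYS_PER_YEAR,
    ConfigError,
    SimConfig,
    day_to_date,
    date_to_day,
    sim_config_from_mapping,
)
from .synth import simulate

logger = logging.getLogger(__name__)

_DATE_COLUMNS = {
    "patients": ["registration_date", "data_start", "transfer_out", "death_date"],
    "prescriptions": ["date"],
    "events": ["date", "admission_date", "discharge_date"],
    "freetext": ["date"],
}

_REQUIRED_COLUMNS = {
    "patients": ["patient_id", "practice_id", "sex", "birth_year",
                 "registration_date", "data_start", "transfer_out", "death_date"],
    "prescriptions": ["patient_id", "date", "drug_name", "drug_class",
                      "quantity", "prescribed_daily_dose", "strength"],
    "events": ["patient_id", "date", "source", "code",
               "admission_date", "discharge_date"],
    "freetext": ["patient_id", "date", "text"],
}


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either ``input_dir`` points at existing tables or ``sim`` describes a
    simulation to generate them.  All protocol thresholds keep their
    package defaults unless overridden here.
    """

    out_dir: str = "apcohort_run"
    seed: int = 0
    input_dir: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    match_ratio: int = 3
    match_age_tolerance: float = 2.0
    secondary_hospital_mode: str = "window_30d"
    users_current_only: bool = True
    n_hazard_periods: int = 100
    smoother_bandwidth_periods: float = 5.0
    smoother_kernel: str = "epanechnikov"

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**{k: v for k, v in raw.items()}, sim=sim_config_from_mapping(sim_raw))
        if seed is not None:
            cfg.seed = int(seed)
            cfg.sim.seed = int(seed)
        return cfg

    def config_hash(self) -> str:
        def _default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=_default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Delimited-file I/O
# ---------------------------------------------------------------------------

def write_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path, origin) -> None:
    """Write the four linked tables as CSV with ISO dates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df = df[[c for c in df.columns if not c.startswith("_")]].copy()
        for col in _DATE_COLUMNS.get(name, []):
            if col in df.columns:
                vals = df[col].astype(float)
                df[col] = [
                    day_to_date(v, origin).isoformat() if np.isfinite(v) else ""
                    for v in vals
                ]
        df.to_csv(out / f"{name}.csv", index=False)


def read_tables(in_dir: str | Path, origin) -> dict[str, pd.DataFrame]:
    """Read the four tables back, converting ISO dates to day offsets."""
    out: dict[str, pd.DataFrame] = {}
    for name in ("patients", "prescriptions", "events", "freetext"):
        path = Path(in_dir) / f"{name}.csv"
        if not path.exists():
            if name == "freetext":
                out[name] = pd.DataFrame(
                    columns=["patient_id", "date", "text", "truth_label"]
                )
                continue
            raise ConfigError(f"missing input table: {path}")
        df = pd.read_csv(path)
        missing = set(_REQUIRED_COLUMNS[name]) - set(df.columns)
        if missing:
            raise ConfigError(f"{path}: missing columns {sorted(missing)}")
        for col in _DATE_COLUMNS.get(name, []):
            if col in df.columns:
                df[col] = [
                    float(date_to_day(v, origin)) if isinstance(v, str) and v else np.nan
                    for v in df[col].fillna("")
                ]
        out[name] = df
    return out


def validate_inputs(tables: dict[str, pd.DataFrame]) -> dict[str, int]:
    """Schema, date-ordering and referential-integrity checks.

    Returns per-violation counts; an empty report means well-formed data.
    """
    report: dict[str, int] = {}
    patients = tables["patients"]
    pids = set(patients["patient_id"])

    for name in ("prescriptions", "events", "freetext"):
        df = tables.get(name)
        if df is None or df.empty:
            continue
        n = int((~df["patient_id"].isin(pids)).sum())
        if n:
            report[f"{name}_unknown_patient"] = n

    reg = patients.set_index("patient_id")["registration_date"]
    death = patients.set_index("patient_id")["death_date"].astype(float)

    ev = tables["events"]
    if len(ev):
        ev_reg = reg.reindex(ev["patient_id"]).to_numpy(dtype=float)
        n = int((ev["date"].to_numpy(dtype=float) < ev_reg).sum())
        if n:
            report["event_before_registration"] = n
        hosp = ev[ev["source"] == "hospital"]
        bad = (
            hosp["admission_date"].astype(float) > hosp["discharge_date"].astype(float)
        ).sum()
        if bad:
            report["hospital_admission_after_discharge"] = int(bad)
        dc = ev[ev["source"] == "death_certificate"]
        dc_death = death.reindex(dc["patient_id"]).to_numpy()
        n = int((dc["date"].to_numpy(dtype=float) != dc_death).sum())
        if n:
            report["death_certificate_date_mismatch"] = n

    dead = patients[np.isfinite(death.to_numpy())]
    n = int(
        (dead["death_date"].astype(float) < dead["data_start"].astype(float)).sum()
    )
    if n:
        report["death_before_data_start"] = n
    return report


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def build_subjects(tables: dict[str, pd.DataFrame], cfg: RunConfig):
    """Cohorts with exclusions; subjects get a stable subject_id."""
    criteria = cohorts_mod.MatchCriteria(
        age_tolerance=cfg.match_age_tolerance, ratio=cfg.match_ratio
    )
    subjects, flow = cohorts_mod.build_cohorts(
        tables["patients"], tables["prescriptions"], tables["events"],
        criteria=criteria, seed=cfg.seed,
        study_start=0.0, study_end=cfg.sim.horizon_days,
    )
    subjects = subjects.reset_index(drop=True)
    subjects.insert(0, "subject_id", np.arange(len(subjects)))
    return subjects, flow


def build_exposure(tables: dict[str, pd.DataFrame], subjects: pd.DataFrame):
    """Episodes (with imputation) and per-user exposure timelines."""
    episodes = exposure_mod.episodes_frame(tables["prescriptions"])
    users = subjects[subjects["cohort"] == "user"]
    censor = users.set_index("patient_id")["censor_date"].astype(float)
    timelines = exposure_mod.build_timelines(episodes, censor)
    summary = exposure_mod.imputation_summary(episodes)
    return episodes, timelines, summary


def build_outcomes(tables, subjects, cfg: RunConfig):
    matches = outcomes_mod.search_free_text(
        tables["freetext"], tables["patients"],
        start_day=cfg.sim.freetext_start_day,
    )
    adjudicated = outcomes_mod.adjudicate(
        subjects, tables["events"], matches, tables["patients"],
        secondary_hospital_mode=cfg.secondary_hospital_mode,
    )
    return matches, adjudicated


def analyse(
    tables, subjects, timelines, adjudicated, cfg: RunConfig
) -> dict[str, pd.DataFrame]:
    """Rate tables and adjusted rate-ratio estimates for the main comparisons."""
    origin_year = cfg.sim.origin_date.year
    estimates: list[dict] = []
    cell_frames: list[pd.DataFrame] = []

    for outcome in ANALYSIS_OUTCOMES:
        seg = rates_mod.subject_segments(
            subjects, tables["patients"], timelines, adjudicated, outcome,
            origin_year=origin_year, users_current_only=cfg.users_current_only,
        )
        if seg.empty:
            continue
        seg = rates_mod.attach_covariates(seg, tables["patients"])
        seg["exposure"] = np.where(seg["cohort"] == "user", "current", "unexposed")

        cells = rates_mod.accumulate_person_time(
            seg, ["cohort", "exposure", "age_band", "sex"]
        )
        cells.insert(0, "outcome", outcome)
        cell_frames.append(cells)

        for ref_cohort in ("psych_nonuser", "general_control"):
            sub = seg[seg["cohort"].isin(["user", ref_cohort])]
            if sub.empty or sub["cohort"].nunique() < 2:
                continue
            for adjustment in ("age_sex", "full"):
                try:
                    ests = rates_mod.fit_rate_ratio(
                        sub, outcome=outcome, adjustment=adjustment
                    )
                except Exception:
                    logger.warning("fit failed: %s vs %s", outcome, ref_cohort)
                    continue
                for e in ests:
                    estimates.append(_estimate_row(e, f"current_vs_{ref_cohort}"))

        # typical vs atypical by first antipsychotic class
        users = subjects[subjects["cohort"] == "user"][["subject_id", "first_class"]]
        useg = seg.merge(users, on="subject_id", how="inner")
        useg = useg[useg["first_class"].isin(["typical", "atypical"])]
        if len(useg) and useg["first_class"].nunique() == 2:
            useg = useg.copy()
            for adjustment in ("age_sex", "full"):
                try:
                    ests = rates_mod.fit_rate_ratio(
                        useg, outcome=outcome, exposure_col="first_class",
                        reference="typical", adjustment=adjustment,
                    )
                except Exception:
                    continue
                for e in ests:
                    estimates.append(_estimate_row(e, "atypical_vs_typical"))

        # dose-band comparison against the psychiatric nonuser reference
        sub = seg[seg["cohort"].isin(["user", "psych_nonuser"])]
        if len(sub):
            for ests in rates_mod.stratified_rr(
                sub, by="dose_band", outcome=outcome
            ).values():
                for e in ests:
                    estimates.append(_estimate_row(e, "dose_band_vs_psych_nonuser"))

    out = {
        "cells": pd.concat(cell_frames, ignore_index=True) if cell_frames else pd.DataFrame(),
        "estimates": pd.DataFrame(estimates),
    }
    out["cause_of_death"] = cause_of_death_table(tables, subjects, adjudicated)
    return out


def _estimate_row(e: rates_mod.RateRatioEstimate, comparison: str) -> dict:
    return {
        "outcome": e.outcome,
        "comparison": comparison,
        "exposed": e.exposed,
        "reference": e.reference,
        "adjustment": e.adjustment,
        "events_exposed": e.n_events_exposed,
        "events_reference": e.n_events_reference,
        "py_exposed": round(e.person_years_exposed, 2),
        "py_reference": round(e.person_years_reference, 2),
        "rate_exposed_per_1000py": round(e.rate_exposed, 2) if e.person_years_exposed else np.nan,
        "rr": round(e.rr, 4) if np.isfinite(e.rr) else "NC",
        "ci_low": round(e.ci_low, 4) if np.isfinite(e.ci_low) else "NC",
        "ci_high": round(e.ci_high, 4) if np.isfinite(e.ci_high) else "NC",
        "covariates_retained": "|".join(e.covariates_retained),
    }


_ICD_CHAPTERS = [
    ("A", "B", "A00-B99 infectious"),
    ("C", "D", "C00-D89 neoplasms/blood"),
    ("E", "E", "E00-E90 endocrine/metabolic"),
    ("F", "F", "F00-F99 mental/behavioural"),
    ("G", "G", "G00-G99 nervous system"),
    ("I", "I", "I00-I99 circulatory"),
    ("J", "J", "J00-J99 respiratory"),
    ("K", "K", "K00-K93 digestive"),
    ("L", "L", "L00-L99 skin"),
    ("M", "M", "M00-M99 musculoskeletal"),
    ("N", "N", "N00-N99 genitourinary"),
    ("Q", "Q", "Q00-Q99 congenital"),
    ("R", "R", "R00-R99 symptoms/signs"),
    ("V", "Y", "V01-Y98 external causes"),
]


def icd_chapter(code: str) -> str:
    letter = str(code)[:1].upper()
    for lo, hi, label in _ICD_CHAPTERS:
        if lo <= letter <= hi:
            return label
    return "other"


def cause_of_death_table(tables, subjects, adjudicated) -> pd.DataFrame:
    """Primary causes of death by ICD-10 chapter in typical vs atypical users."""
    users = subjects[subjects["cohort"] == "user"]
    ev = tables["events"]
    certs = ev[ev["source"] == "death_certificate"][["patient_id", "code"]]
    deaths = adjudicated[
        (adjudicated["outcome"] == "all_cause_mortality")
        & (adjudicated["cohort"] == "user")
    ].merge(certs, on="patient_id", how="left")
    deaths = deaths.merge(
        users[["subject_id", "first_class"]], on="subject_id", how="left"
    )
    if deaths.empty:
        return pd.DataFrame(columns=["first_class", "chapter", "events"])
    deaths["chapter"] = deaths["code"].fillna("").map(icd_chapter)
    out = (
        deaths.groupby(["first_class", "chapter"])
        .size()
        .rename("events")
        .reset_index()
    )
    return out.sort_values(["first_class", "chapter"]).reset_index(drop=True)


def smooth_treatment_time(
    subjects, patients, adjudicated, cfg: RunConfig
) -> pd.DataFrame:
    """Smoothed all-cause hazard over treatment time, by first drug class.

    Follow-up runs from the start of medication (the user index date) to
    the end of data collection; the ratio curve compares atypical to
    typical initiators.
    """
    users = subjects[subjects["cohort"] == "user"]
    deaths = adjudicated[
        (adjudicated["outcome"] == "all_cause_mortality")
        & (adjudicated["cohort"] == "user")
    ].groupby("subject_id")["event_date"].min()

    rows = []
    curves = {}
    span = None
    grids = {}
    for cls in ("typical", "atypical"):
        grp = users[users["first_class"] == cls]
        if grp.empty:
            continue
        start = grp["index_date"].to_numpy(dtype=float)
        end = grp["censor_date"].to_numpy(dtype=float)
        ev = deaths.reindex(grp["subject_id"]).to_numpy(dtype=float)
        fu = (np.fmin(end, ev) - start) / DAYS_PER_YEAR
        et = np.where(np.isfinite(ev), (ev - start) / DAYS_PER_YEAR, np.nan)
        grids[cls] = (fu, et)
        span = max(span or 0.0, float(fu.max()) if len(fu) else 0.0)
    for cls, (fu, et) in grids.items():
        grid = hazard_mod.build_grid(fu, et, n_periods=cfg.n_hazard_periods, span=span)
        bw = cfg.smoother_bandwidth_periods * (grid.period_edges[1] - grid.period_edges[0])
        curves[cls] = hazard_mod.smooth(grid, bandwidth=bw, kernel=cfg.smoother_kernel)

    frames = []
    for cls, c in curves.items():
        frames.append(
            pd.DataFrame(
                {
                    "series": f"hazard_{cls}",
                    "time_years": c.eval_points,
                    "value": c.hazard,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "boundary": c.boundary,
                }
            )
        )
    if "typical" in curves and "atypical" in curves:
        r = hazard_mod.hazard_ratio_curve(curves["atypical"], curves["typical"])
        frames.append(
            pd.DataFrame(
                {
                    "series": "rr_atypical_vs_typical",
                    "time_years": r.eval_points,
                    "value": r.hazard,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "boundary": r.boundary,
                }
            )
        )
    _ = rows
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------

def run(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    origin = cfg.sim.origin_date
    manifest: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash(), "stages": {}}

    if cfg.input_dir:
        tables = read_tables(cfg.input_dir, origin)
        logger.info("loaded input tables from %s", cfg.input_dir)
    else:
        tables = simulate(cfg.sim)
        write_tables(tables, out, origin)
    manifest["stages"]["tables"] = {k: int(len(v)) for k, v in tables.items()}

    report = validate_inputs(tables)
    manifest["validation"] = report
    if report:
        logger.warning("input validation violations: %s", report)

    subjects, flow = build_subjects(tables, cfg)
    manifest["stages"]["cohorts"] = {
        "subjects": int(len(subjects)),
        **{f"n_{c}": int((subjects["cohort"] == c).sum())
           for c in ("user", "general_control", "psych_nonuser")},
    }
    manifest["exclusion_flow"] = flow
    subjects.to_csv(out / "cohorts.csv", index=False)

    episodes, timelines, imput = build_exposure(tables, subjects)
    manifest["stages"]["exposure"] = {
        "episodes": int(len(episodes)), "intervals": int(len(timelines)),
        **{k: (round(v, 4) if isinstance(v, float) else v) for k, v in imput.items()},
    }
    timelines.to_csv(out / "exposure.csv", index=False)

    matches, adjudicated = build_outcomes(tables, subjects, cfg)
    manifest["stages"]["outcomes"] = {
        "freetext_matches": int(len(matches)),
        "adjudicated": int(len(adjudicated)),
    }
    adjudicated.to_csv(out / "outcomes.csv", index=False)

    results = analyse(tables, subjects, timelines, adjudicated, cfg)
    results["cells"].to_csv(out / "rate_cells.csv", index=False)
    results["estimates"].to_csv(out / "estimates.csv", index=False)
    results["cause_of_death"].to_csv(out / "cause_of_death.csv", index=False)
    manifest["stages"]["analysis"] = {
        "cells": int(len(results["cells"])),
        "estimates": int(len(results["estimates"])),
    }

    curve = smooth_treatment_time(subjects, tables["patients"], adjudicated, cfg)
    curve.to_csv(out / "hazard_curves.csv", index=False)
    manifest["stages"]["hazard"] = {"points": int(len(curve))}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
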