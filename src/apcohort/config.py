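"""Shared constants, packaged reference tables, and run configuration.

All dates are handled internally as integer (or fractional, for derived
window boundaries) day offsets from a configurable origin calendar date;
intervals are half-open ``[start, end)``.  Calendar conventions follow the
study protocol: one month = 30.4 days, six months = 182.4 days, three weeks
= 21 days, one year = 365.25 days.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

# ---------------------------------------------------------------------------
# Protocol constants (surfaced by name so a run config can override them)
# ---------------------------------------------------------------------------

DAYS_PER_MONTH: float = 30.4          # grace period after expected end of rx
DAYS_RECENT_WINDOW: float = 182.4     # "recent exposure" extends to 6 months
DAYS_PER_YEAR: float = 365.25
FREETEXT_WINDOW_DAYS: int = 21        # +-3 weeks around the death date
FREETEXT_CONTEXT_CHARS: int = 500     # context kept either side of a hit

DDD_VALID_RANGE_MG: tuple[float, float] = (25.0, 1000.0)   # BNF plausibility
DURATION_VALID_RANGE_DAYS: tuple[float, float] = (1.0, 91.4)

DOSE_BAND_EDGES_MG: tuple[float, float] = (200.0, 400.0)   # low / medium / high
CUM_DURATION_EDGES_DAYS: tuple[float, float] = (365.25, 3 * 365.25)

HOSPITAL_DISCHARGE_RULE_DAYS: int = 30   # narrow-SCD out-of-hospital rule

EVENTS_PER_PARAMETER: int = 5
P_ENTER: float = 0.05
P_REMOVE: float = 0.10

N_HAZARD_PERIODS: int = 100

AGE_BAND_EDGES: tuple[int, ...] = (30, 65, 80)   # 18-29 / 30-64 / 65-79 / 80+

PSYCH_DISEASES: tuple[str, ...] = (
    "schizophrenia", "bipolar_disorder", "major_depression", "dementia",
)

# cause-level outcome names used by the simulator; analysis-level outcomes
# (all_cause_mortality etc.) are derived downstream
SIM_OUTCOMES: tuple[str, ...] = (
    "scd", "cardiac_other_death", "other_death", "suicide",
    "chd", "ventricular_arrhythmia",
)
SIM_DEATH_OUTCOMES: tuple[str, ...] = (
    "scd", "cardiac_other_death", "other_death", "suicide",
)

ANALYSIS_OUTCOMES: tuple[str, ...] = (
    "all_cause_mortality", "cardiac_mortality",
    "scd_primary", "scd_secondary", "scd_tertiary",
    "chd", "ventricular_arrhythmia",
)


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

def _load_yaml(name: str) -> dict:
    with resources.files("apcohort.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_drug_table() -> dict:
    """Return {drug_name: {"class": ..., "cpz_factor": ...}}."""
    raw = _load_yaml("drugs.yaml")
    table: dict[str, dict] = {}
    for cls in ("typical", "atypical"):
        for drug, row in raw[cls].items():
            table[drug] = {"class": cls, "cpz_factor": float(row["cpz_factor"])}
    return table


def load_code_sets() -> dict:
    """Outcome / suicide / exclusion code sets (ICD-10 prefixes)."""
    return _load_yaml("code_sets.yaml")


def load_freetext_terms() -> dict:
    """Trigger strings, conjunctive pairs, and exclusion phrases."""
    return _load_yaml("freetext_terms.yaml")


def read_code_for(icd: str) -> str:
    """Internal 1:1 mapping from an ICD-10 code to a Read-like code."""
    return "Ry" + icd.replace(".", "")


def icd_for_read_code(read: str) -> str | None:
    if not read.startswith("Ry"):
        return None
    body = read[2:]
    # re-insert the dot of an ICD-10 subcode (letter + 2 digits [+ decimal])
    if len(body) > 3:
        return body[:3] + "." + body[3:]
    return body


def code_matches(code: str, entries: list[str] | tuple[str, ...]) -> bool:
    """ICD-10 hierarchy prefix matching: entry I46 matches I46.1 etc."""
    for entry in entries:
        if code == entry or code.startswith(entry + "."):
            return True
        # undotted Read-like payloads ("I461" from RyI461)
        if "." not in code and "." in entry and code == entry.replace(".", ""):
            return True
    return False


def day_to_date(day: float, origin: _dt.date) -> _dt.date:
    return origin + _dt.timedelta(days=int(day))


def date_to_day(date: _dt.date | str, origin: _dt.date) -> int:
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    return (date - origin).days


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

def _default_psych_prevalence() -> dict[str, float]:
    return {
        "schizophrenia": 0.012,
        "bipolar_disorder": 0.010,
        "major_depression": 0.10,
        "dementia": 0.030,
    }


def _default_baseline_hazards() -> dict[str, float]:
    # events per person-year in the unexposed psychiatric reference,
    # on the scale of the published nonuser incidence rates
    return {
        "scd": 0.0005,
        "cardiac_other_death": 0.006,
        "other_death": 0.019,
        "suicide": 0.0004,
        "chd": 0.0035,
        "ventricular_arrhythmia": 0.0018,
    }


def _default_true_rr() -> dict[str, float]:
    return {name: 1.0 for name in SIM_OUTCOMES}


def _default_missing_rates() -> dict[str, float]:
    return {
        "strength": 0.05,
        "prescribed_daily_dose": 0.05,
        "quantity": 0.03,
        "bmi": 0.20,
        "smoking": 0.15,
    }


def _default_covariate_prevalence() -> dict[str, float]:
    return {
        "alcohol_drug_abuse": 0.05,
        "diabetes": 0.07,
        "suicide_attempt_history": 0.03,
        "prior_psych_admission": 0.04,
        "antidepressant": 0.20,
        "anxiolytic": 0.06,
        "statin": 0.09,
        "antihypertensive": 0.15,
    }


def _default_dose_menu() -> dict:
    # chlorpromazine-equivalent daily targets and their sampling weights;
    # spans the low / medium / high bands
    return {
        "levels_mg": [100.0, 150.0, 250.0, 300.0, 450.0, 600.0],
        "weights": [0.25, 0.25, 0.15, 0.15, 0.10, 0.10],
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic linked-records generator.

    The defaults define the package's reference study conditions: a
    ten-year observation window, psychiatric disease prevalences and
    unexposed event rates on the scale of a UK primary-care population,
    and null treatment effects (``true_rr`` all 1).  Tests and analyses
    plant non-null effects by overriding ``true_rr`` /
    ``confounder_effects``.
    """

    n_patients: int = 20_000
    n_practices: int = 20
    origin_date: _dt.date = _dt.date(2001, 1, 1)
    horizon_years: float = 10.0
    seed: int = 0

    # multiplicative rate ratios applied during current exposure
    true_rr: dict[str, float] = field(default_factory=_default_true_rr)
    # optional extra multiplier per current dose band {low, medium, high}
    true_rr_by_dose: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline_hazards: dict[str, float] = field(default_factory=_default_baseline_hazards)
    # covariate -> (odds multiplier on treatment, hazard multiplier on outcomes)
    confounder_effects: dict[str, tuple[float, float]] = field(default_factory=dict)

    psych_prevalence: dict[str, float] = field(default_factory=_default_psych_prevalence)
    covariate_prevalence: dict[str, float] = field(
        default_factory=_default_covariate_prevalence
    )
    treatment_given_psych: float = 0.55
    treatment_given_nonpsych: float = 0.02
    typical_fraction: float = 0.63
    prevalent_fraction: float = 0.30      # treated patients with pre-study use
    missing_rates: dict[str, float] = field(default_factory=_default_missing_rates)

    # prescribing process
    rx_stop_prob: float = 0.08            # chance the chain ends after each rx
    gap_short_prob: float = 0.85          # short gap => continuous treatment
    gap_short_range: tuple[float, float] = (0.0, 25.0)
    gap_long_range: tuple[float, float] = (45.0, 400.0)
    quantity_choices: tuple[int, ...] = (28, 56, 84)
    pdd_choices: tuple[float, ...] = (1.0, 2.0)
    dose_menu: dict = field(default_factory=_default_dose_menu)

    # record-stream realism
    transfer_out_prob: float = 0.15
    exclusion_anytime_prev: float = 0.002
    exclusion_vt_prev: float = 0.003
    read_death_code_prob: float = 0.5     # GP also codes the death
    hosp_before_death_frac: float = 0.25  # discharge in the weeks before death
    background_hosp_rate: float = 0.05    # admissions per person-year
    note_prob_death: float = 0.8          # a free-text note near the death
    trigger_prob_scd: float = 0.85        # SCD note embeds a trigger string
    trigger_prob_other: float = 0.10      # non-SCD note embeds a trigger
    exclusion_phrase_prob: float = 0.60   # ... with a clarifying other cause
    freetext_start_year: int = 2006

    def __post_init__(self) -> None:
        if isinstance(self.origin_date, str):
            self.origin_date = _dt.date.fromisoformat(self.origin_date)
        probs = {
            "treatment_given_psych": self.treatment_given_psych,
            "treatment_given_nonpsych": self.treatment_given_nonpsych,
            "typical_fraction": self.typical_fraction,
            "prevalent_fraction": self.prevalent_fraction,
            "rx_stop_prob": self.rx_stop_prob,
            "gap_short_prob": self.gap_short_prob,
            **{f"psych_prevalence[{k}]": v for k, v in self.psych_prevalence.items()},
            **{f"missing_rates[{k}]": v for k, v in self.missing_rates.items()},
        }
        for name, value in probs.items():
            if not 0.0 <= float(value) <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {value}")
        for name, value in self.baseline_hazards.items():
            if value < 0:
                raise ConfigError(f"baseline_hazards[{name}] must be >= 0, got {value}")
        for name, value in self.true_rr.items():
            if value <= 0:
                raise ConfigError(f"true_rr[{name}] must be > 0, got {value}")
        if self.n_patients <= 0 or self.n_practices <= 0:
            raise ConfigError("n_patients and n_practices must be positive")

    @property
    def horizon_days(self) -> float:
        return self.horizon_years * DAYS_PER_YEAR

    @property
    def freetext_start_day(self) -> int:
        return date_to_day(_dt.date(self.freetext_start_year, 1, 1), self.origin_date)


class ConfigError(ValueError):
    """Invalid configuration value (named field in the message)."""


def sim_config_from_mapping(raw: Mapping) -> SimConfig:
    """Build a SimConfig from a parsed YAML/JSON mapping (unknown keys fail)."""
    known = {f.name for f in SimConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
    kwargs = dict(raw)
    for key in ("gap_short_range", "gap_long_range", "quantity_choices", "pdd_choices"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if "confounder_effects" in kwargs:
        kwargs["confounder_effects"] = {
            k: tuple(v) for k, v in kwargs["confounder_effects"].items()
        }
    return SimConfig(**kwargs)
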