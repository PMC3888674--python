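"""Person-time accumulation and Poisson rate-ratio estimation.

Each subject's follow-up runs from the index date to the first of: the
outcome event, death, transfer out, or end of data collection.  Follow-up
is split at every stratum boundary — exposure-state changes, dose-band
changes, age-band birthdays — and accumulated as person-years with event
counts per cell; incidence rates are reported per 1000 person-years.

Rate ratios come from a log-linear Poisson model for event counts with a
log person-time offset (fitted by iteratively reweighted least squares via
statsmodels GLM), with Wald 95% confidence intervals on the log scale.
The age-and-sex-adjusted model contains only the forced terms (exposure,
age band, sex); the fully adjusted model first runs automated backward
elimination over candidate covariates, with the candidate pool truncated
so the parameter budget respects five outcome events per parameter, each
candidate tested as a block (joint Wald test for categorical covariates),
removed at P >= 0.10 and retained only below P < 0.05.  Cells compared
with zero events yield a "not calculable" (NC) result rather than an
estimate.  Missing BMI and smoking enter as indicator levels of their
categorical codings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .config import AGE_BAND_EDGES, DAYS_PER_YEAR, EVENTS_PER_PARAMETER, P_ENTER, P_REMOVE

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATES = [
    "alcohol_drug_abuse",
    "antidepressant",
    "antihypertensive",
    "anxiolytic",
    "bmi_band",
    "deprivation",
    "diabetes",
    "prior_psych_admission",
    "smoking",
    "statin",
    "suicide_attempt_history",
]

_CATEGORICAL = {"bmi_band", "smoking", "deprivation"}


@dataclass
class ModelSpec:
    """Covariate-selection settings for the fully adjusted model."""

    outcome: str = ""
    candidate_covariates: list[str] = field(
        default_factory=lambda: list(DEFAULT_CANDIDATES)
    )
    events_per_parameter: int = EVENTS_PER_PARAMETER
    p_enter: float = P_ENTER
    p_remove: float = P_REMOVE


@dataclass
class RateRatioEstimate:
    """One exposed-vs-reference comparison from the Poisson model."""

    outcome: str
    exposed: str
    reference: str
    rr: float
    ci_low: float
    ci_high: float
    adjustment: str
    covariates_retained: list[str]
    n_events_exposed: int
    n_events_reference: int
    person_years_exposed: float
    person_years_reference: float
    nc: bool = False

    @property
    def rate_exposed(self) -> float:
        """Incidence rate per 1000 person-years in the exposed level."""
        return 1000.0 * self.n_events_exposed / self.person_years_exposed

    @property
    def rate_reference(self) -> float:
        return 1000.0 * self.n_events_reference / self.person_years_reference


# ---------------------------------------------------------------------------
# Subject-level segments
# ---------------------------------------------------------------------------

def _age_band_label(age: np.ndarray) -> np.ndarray:
    edges = AGE_BAND_EDGES
    labels = ["18-29", "30-64", "65-79", "80+"]
    idx = np.searchsorted(np.asarray(edges, dtype=float), age, side="right")
    return np.asarray(labels, dtype=object)[idx]


def _split_at(df: pd.DataFrame, cut: np.ndarray) -> pd.DataFrame:
    """Split rows at a per-row cut point where it falls strictly inside."""
    inside = (cut > df["start"].to_numpy()) & (cut < df["end"].to_numpy())
    if not inside.any():
        return df
    left = df[inside].copy()
    right = df[inside].copy()
    left["end"] = cut[inside]
    right["start"] = cut[inside]
    return pd.concat([df[~inside], left, right], ignore_index=True)


def subject_segments(
    subjects: pd.DataFrame,
    patients: pd.DataFrame,
    timelines: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome_name: str,
    origin_year: int = 2001,
    users_current_only: bool = True,
) -> pd.DataFrame:
    """Stratified person-time segments with event assignment.

    ``subjects`` must carry a unique ``subject_id``.  Users contribute the
    segments of their exposure timeline (restricted to current exposure by
    default, carrying dose and cumulative-duration bands); controls and
    psychiatric nonusers contribute a single unexposed span.  All segments
    are clipped to ``[index, min(censor, event))`` and split at age-band
    birthdays; the event is assigned to the segment it falls in.
    """
    subj = subjects.copy()
    if "subject_id" not in subj.columns:
        subj["subject_id"] = np.arange(len(subj))

    ev = outcomes[outcomes["outcome"] == outcome_name]
    first_event = ev.groupby("subject_id")["event_date"].min() if "subject_id" in ev.columns else pd.Series(dtype=float)
    subj["event_date"] = first_event.reindex(subj["subject_id"]).to_numpy()
    subj["endpoint"] = np.fmin(
        subj["censor_date"].to_numpy(dtype=float),
        subj["event_date"].to_numpy(dtype=float),
    )
    subj = subj[subj["endpoint"] > subj["index_date"]]

    pats = patients.set_index("patient_id")
    birth_day = (
        (pats["birth_year"].astype(float) - float(origin_year)) * DAYS_PER_YEAR
    )

    pieces = []
    is_user = subj["cohort"] == "user"

    nonusers = subj[~is_user]
    if len(nonusers):
        base = pd.DataFrame(
            {
                "subject_id": nonusers["subject_id"].to_numpy(),
                "patient_id": nonusers["patient_id"].to_numpy(),
                "cohort": nonusers["cohort"].to_numpy(),
                "start": nonusers["index_date"].to_numpy(dtype=float),
                "end": nonusers["endpoint"].to_numpy(dtype=float),
                "exposure": "unexposed",
                "dose_band": None,
                "cum_duration_band": None,
                "drug_class": None,
            }
        )
        pieces.append(base)

    users = subj[is_user]
    if len(users) and not timelines.empty:
        tl = timelines.merge(
            users[["subject_id", "patient_id", "cohort", "index_date", "endpoint"]],
            on="patient_id",
            how="inner",
        )
        tl["start"] = np.maximum(tl["start"], tl["index_date"])
        tl["end"] = np.minimum(tl["end"], tl["endpoint"])
        tl = tl[tl["end"] > tl["start"]]
        if users_current_only:
            tl = tl[tl["state"] == "current"]
        tl = tl.rename(columns={"state": "exposure"})
        pieces.append(
            tl[
                ["subject_id", "patient_id", "cohort", "start", "end",
                 "exposure", "dose_band", "cum_duration_band", "drug_class"]
            ]
        )

    if not pieces:
        return pd.DataFrame(
            columns=["subject_id", "patient_id", "cohort", "start", "end",
                     "exposure", "dose_band", "cum_duration_band",
                     "drug_class", "age_band", "sex", "py", "events"]
        )
    seg = pd.concat(pieces, ignore_index=True)

    # split at age-band birthdays
    for edge in AGE_BAND_EDGES:
        cut = birth_day.reindex(seg["patient_id"]).to_numpy() + edge * DAYS_PER_YEAR
        seg = _split_at(seg, cut)
    bd = birth_day.reindex(seg["patient_id"]).to_numpy()
    age_at_start = (seg["start"].to_numpy() - bd) / DAYS_PER_YEAR
    seg["age_band"] = _age_band_label(age_at_start)
    seg["sex"] = pats["sex"].reindex(seg["patient_id"]).to_numpy()

    seg["py"] = (seg["end"] - seg["start"]) / DAYS_PER_YEAR

    # event lands in the segment containing (event - 0.5)
    ev_day = first_event.reindex(subj["subject_id"])
    ev_map = dict(zip(subj["subject_id"], subj["event_date"]))
    t_star = seg["subject_id"].map(ev_map).astype(float) - 0.5
    seg["events"] = (
        (t_star >= seg["start"]) & (t_star < seg["end"])
    ).astype(int)
    _ = ev_day
    return seg.reset_index(drop=True)


def accumulate_person_time(
    segments: pd.DataFrame, strata: list[str]
) -> pd.DataFrame:
    """Aggregate segments into cells: events, person-years, rate/1000 py."""
    g = segments.groupby(strata, dropna=False, observed=True)
    cells = g.agg(events=("events", "sum"), person_years=("py", "sum")).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        cells["rate_per_1000py"] = 1000.0 * cells["events"] / cells["person_years"]
    return cells


def attach_covariates(segments: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Join baseline covariates (with missing-indicator codings) to segments."""
    pats = patients.set_index("patient_id")
    seg = segments.copy()
    for col in (
        "alcohol_drug_abuse", "diabetes", "suicide_attempt_history",
        "prior_psych_admission", "antidepressant", "anxiolytic", "statin",
        "antihypertensive", "deprivation", "smoking",
    ):
        if col in pats.columns:
            seg[col] = pats[col].reindex(seg["patient_id"]).to_numpy()
    if "bmi" in pats.columns:
        bmi = pats["bmi"].reindex(seg["patient_id"]).to_numpy(dtype=float)
        band = np.where(
            np.isnan(bmi), "missing",
            np.where(bmi < 25, "<25", np.where(bmi < 30, "25-30", ">=30")),
        )
        seg["bmi_band"] = band
    return seg


# ---------------------------------------------------------------------------
# Poisson fitting
# ---------------------------------------------------------------------------

def _term_for(cov: str) -> str:
    return f"C({cov})" if cov in _CATEGORICAL else cov

def _aggregate_for_fit(
    segments: pd.DataFrame, exposure_col: str, covariates: list[str]
) -> pd.DataFrame:
    keys = [exposure_col, "age_band", "sex"] + [c for c in covariates]
    keys = [k for k in dict.fromkeys(keys)]  # unique, order kept
    agg = (
        segments.groupby(keys, dropna=False, observed=True)
        .agg(events=("events", "sum"), py=("py", "sum"))
        .reset_index()
    )
    return agg[agg["py"] > 0]


def _fit_glm(agg: pd.DataFrame, exposure_col: str, reference: str, covariates: list[str]):
    terms = [f"C({exposure_col}, Treatment(reference={reference!r}))"]
    # single-level factors carry no information and break the design matrix
    if agg["age_band"].nunique() > 1:
        terms.append("C(age_band)")
    if agg["sex"].nunique() > 1:
        terms.append("C(sex)")
    terms += [_term_for(c) for c in covariates if agg[c].nunique(dropna=False) > 1]
    formula = "events ~ " + " + ".join(terms)
    model = smf.glm(
        formula, data=agg, family=sm.families.Poisson(),
        offset=np.log(agg["py"].to_numpy()),
    )
    with warnings.catch_warnings():
        # saturated designs (2-cell crude tables) fit perfectly by design
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore")
        return model.fit(tol=1e-8, maxiter=100)


def select_covariates(
    segments: pd.DataFrame,
    exposure_col: str,
    reference: str,
    spec: ModelSpec | None = None,
) -> list[str]:
    """Backward elimination under the five-events-per-parameter budget.

    Candidates are considered in the ModelSpec's (alphabetical) order, the pool
    truncated so that total non-intercept parameters stay within
    ``events // events_per_parameter`` (forced terms always kept), then
    covariates are dropped one at a time — worst block Wald P first —
    while any candidate has P >= p_remove, and finally while any has
    P >= p_enter, so the returned set is significant at p_enter.
    """
    spec = spec or ModelSpec()
    total_events = int(segments["events"].sum())
    budget = total_events // spec.events_per_parameter

    # parameter cost of forced terms (levels present in the data)
    def _df_of(col: str) -> int:
        return max(segments[col].nunique(dropna=False) - 1, 1)

    forced_df = _df_of(exposure_col) + _df_of("age_band") + _df_of("sex")
    remaining = budget - forced_df

    pool: list[str] = []
    for cov in spec.candidate_covariates:
        if cov not in segments.columns:
            continue
        cost = _df_of(cov) if cov in _CATEGORICAL else 1
        if cost <= remaining:
            pool.append(cov)
            remaining -= cost

    if not pool:
        return []

    for threshold in (spec.p_remove, spec.p_enter):
        while pool:
            agg = _aggregate_for_fit(segments, exposure_col, pool)
            try:
                res = _fit_glm(agg, exposure_col, reference, pool)
                table = res.wald_test_terms(skip_single=False, scalar=True)
                pvals = table.table["pvalue"]
            except Exception:  # singular fit: drop the last-added candidate
                logger.warning("selection fit failed; dropping %s", pool[-1])
                pool = pool[:-1]
                continue
            worst, worst_p = None, -1.0
            for cov in pool:
                term = _term_for(cov)
                p = float(pvals.get(term, np.nan))
                if np.isnan(p):
                    p = 1.0
                if p > worst_p:
                    worst, worst_p = cov, p
            if worst is not None and worst_p >= threshold:
                pool = [c for c in pool if c != worst]
            else:
                break
    return pool


def fit_rate_ratio(
    segments: pd.DataFrame,
    outcome: str = "",
    exposure_col: str = "exposure",
    reference: str = "unexposed",
    adjustment: str = "age_sex",
    spec: ModelSpec | None = None,
) -> list[RateRatioEstimate]:
    """Adjusted rate ratios for every exposure level against the reference.

    ``adjustment='age_sex'`` fits only the forced terms; ``'full'`` runs
    covariate selection first.  Levels with zero events (or a zero-event
    reference) are reported as NC instead of raising.
    """
    levels = segments[exposure_col].dropna().unique().tolist()
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from data")
    exposed_levels = sorted(str(l) for l in levels if l != reference)

    by_level = segments.groupby(exposure_col, observed=True).agg(
        events=("events", "sum"), py=("py", "sum")
    )
    ref_events = int(by_level.loc[reference, "events"])
    ref_py = float(by_level.loc[reference, "py"])

    covariates: list[str] = []
    if adjustment == "full":
        covariates = select_covariates(segments, exposure_col, reference, spec)

    estimable = [
        lvl for lvl in exposed_levels if by_level.loc[lvl, "events"] > 0
    ] if ref_events > 0 else []

    results: dict[str, RateRatioEstimate] = {}
    if estimable:
        keep = segments[exposure_col].isin(estimable + [reference])
        agg = _aggregate_for_fit(segments[keep], exposure_col, covariates)
        res = _fit_glm(agg, exposure_col, reference, covariates)
        prefix = f"C({exposure_col}, Treatment(reference={reference!r}))[T."
        for lvl in estimable:
            name = f"{prefix}{lvl}]"
            beta = float(res.params[name])
            se = float(res.bse[name])
            results[lvl] = RateRatioEstimate(
                outcome=outcome,
                exposed=lvl,
                reference=reference,
                rr=float(np.exp(beta)),
                ci_low=float(np.exp(beta - 1.959963984540054 * se)),
                ci_high=float(np.exp(beta + 1.959963984540054 * se)),
                adjustment=adjustment,
                covariates_retained=list(covariates),
                n_events_exposed=int(by_level.loc[lvl, "events"]),
                n_events_reference=ref_events,
                person_years_exposed=float(by_level.loc[lvl, "py"]),
                person_years_reference=ref_py,
            )
    out = []
    for lvl in exposed_levels:
        if lvl in results:
            out.append(results[lvl])
        else:
            out.append(
                RateRatioEstimate(
                    outcome=outcome, exposed=lvl, reference=reference,
                    rr=np.nan, ci_low=np.nan, ci_high=np.nan,
                    adjustment=adjustment, covariates_retained=list(covariates),
                    n_events_exposed=int(by_level.loc[lvl, "events"]) if lvl in by_level.index else 0,
                    n_events_reference=ref_events,
                    person_years_exposed=float(by_level.loc[lvl, "py"]) if lvl in by_level.index else 0.0,
                    person_years_reference=ref_py,
                    nc=True,
                )
            )
    return out


def crude_rate_ratio(
    events_exposed: float, py_exposed: float,
    events_reference: float, py_reference: float,
) -> tuple[float, float, float]:
    """Closed-form two-cell rate ratio with a Wald CI on the log scale."""
    rr = (events_exposed / py_exposed) / (events_reference / py_reference)
    se = np.sqrt(1.0 / events_exposed + 1.0 / events_reference)
    z = 1.959963984540054
    return rr, rr * np.exp(-z * se), rr * np.exp(z * se)


def stratified_rr(
    segments: pd.DataFrame,
    by: str,
    outcome: str = "",
    exposure_col: str = "exposure",
    reference: str = "unexposed",
    adjustment: str = "age_sex",
    spec: ModelSpec | None = None,
) -> dict[str, list[RateRatioEstimate]]:
    """One set of estimates per stratum of ``by``.

    For ``by='dose_band'`` or ``by='cum_duration_band'`` the band replaces
    the exposure label on user segments (reference kept), giving one
    estimate per band from a single model; otherwise the data are subset
    per stratum and fitted separately (NC where events are too few).
    """
    if by in ("dose_band", "cum_duration_band"):
        seg = segments.copy()
        user = seg["cohort"] == "user"
        seg = seg[~user | seg[by].notna()]
        seg[exposure_col] = np.where(
            seg["cohort"] == "user", seg[by], seg[exposure_col]
        )
        return {"all": fit_rate_ratio(seg, outcome, exposure_col, reference,
                                      adjustment, spec)}
    out: dict[str, list[RateRatioEstimate]] = {}
    for value, sub in segments.groupby(by, observed=True):
        levels = sub[exposure_col].unique()
        if reference not in levels or len(levels) < 2:
            out[str(value)] = []
            continue
        try:
            out[str(value)] = fit_rate_ratio(
                sub, outcome, exposure_col, reference, adjustment, spec
            )
        except Exception:
            logger.warning("stratum %s=%s not estimable", by, value)
            out[str(value)] = []
    return out
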