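"""Person-time accounting and Poisson rate-ratio machinery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import apcohort as ap
from apcohort.config import DAYS_PER_YEAR
from apcohort.rates import (
    ModelSpec,
    _split_at,
    accumulate_person_time,
    crude_rate_ratio,
    fit_rate_ratio,
    select_covariates,
    subject_segments,
)

from conftest import mk_patients


def seg_frame(rows):
    """Minimal segment frame for fitting (constant age/sex by default)."""
    defaults = {"age_band": "65-79", "sex": "F", "cohort": "user"}
    return pd.DataFrame([{**defaults, **r} for r in rows])


# ---------------------------------------------------------------------------
# Person-time accumulation
# ---------------------------------------------------------------------------

class TestPersonTime:
    def _segments(self, patients, subjects, outcomes=None):
        if outcomes is None:
            outcomes = pd.DataFrame(
                columns=["subject_id", "patient_id", "cohort", "outcome",
                         "event_date", "winning_source"]
            )
        timelines = pd.DataFrame(columns=[
            "patient_id", "start", "end", "state", "dose_band",
            "cum_duration_band", "drug_class"])
        return subject_segments(
            subjects, patients, timelines, outcomes, "all_cause_mortality"
        )

    def test_two_year_follow_up_is_two_person_years(self):
        patients = mk_patients([{}])
        subjects = pd.DataFrame([{
            "subject_id": 0, "patient_id": 1, "cohort": "psych_nonuser",
            "index_date": 0.0, "censor_date": 2 * DAYS_PER_YEAR}])
        seg = self._segments(patients, subjects)
        cells = accumulate_person_time(seg, ["cohort"])
        assert np.isclose(cells["person_years"].iloc[0], 2.0)
        assert cells["events"].iloc[0] == 0

    def test_age_band_crossing_splits_but_conserves(self):
        # born 1950, origin 2001 -> crosses the 65-year edge mid-follow-up
        patients = mk_patients([{"birth_year": 1950}])
        start = (2013 - 2001) * DAYS_PER_YEAR
        subjects = pd.DataFrame([{
            "subject_id": 0, "patient_id": 1, "cohort": "psych_nonuser",
            "index_date": start, "censor_date": start + 4 * DAYS_PER_YEAR}])
        seg = self._segments(patients, subjects)
        assert set(seg["age_band"]) == {"30-64", "65-79"}
        assert np.isclose(seg["py"].sum(), 4.0)

    def test_event_assigned_to_active_cell(self):
        patients = mk_patients([{"birth_year": 1950, "death_date": 500.0}])
        subjects = pd.DataFrame([{
            "subject_id": 0, "patient_id": 1, "cohort": "psych_nonuser",
            "index_date": 0.0, "censor_date": 500.0}])
        outcomes = pd.DataFrame([{
            "subject_id": 0, "patient_id": 1, "cohort": "psych_nonuser",
            "outcome": "all_cause_mortality", "event_date": 500.0,
            "winning_source": "death_certificate"}])
        seg = self._segments(patients, subjects, outcomes)
        assert seg["events"].sum() == 1
        assert np.isclose(seg["py"].sum(), 500.0 / DAYS_PER_YEAR)

    def test_day_count_oracle_on_random_subjects(self):
        rng = np.random.default_rng(0)
        rows, srows = [], []
        for i in range(100):
            idx = float(rng.integers(0, 1000))
            censor = idx + float(rng.integers(1, 2000))
            rows.append({"birth_year": int(rng.integers(1925, 1985))})
            srows.append({"subject_id": i, "patient_id": i + 1,
                          "cohort": "psych_nonuser", "index_date": idx,
                          "censor_date": censor})
        patients = mk_patients(rows)
        subjects = pd.DataFrame(srows)
        seg = self._segments(patients, subjects)
        total = seg.groupby("subject_id")["py"].sum()
        for i, s in enumerate(srows):
            days = s["censor_date"] - s["index_date"]
            assert abs(total.loc[i] - days / DAYS_PER_YEAR) < 1.0 / DAYS_PER_YEAR

    def test_user_time_restricted_to_current_exposure(self, sim_tables):
        cfg, tables = sim_tables
        subjects, _ = ap.build_cohorts(
            tables["patients"], tables["prescriptions"], tables["events"],
            seed=1, study_end=cfg.horizon_days)
        subjects.insert(0, "subject_id", np.arange(len(subjects)))
        eps = ap.episodes_frame(tables["prescriptions"])
        users = subjects[subjects["cohort"] == "user"]
        tl = ap.build_timelines(
            eps, users.set_index("patient_id")["censor_date"].astype(float))
        empty = pd.DataFrame(columns=["subject_id", "patient_id", "cohort",
                                      "outcome", "event_date", "winning_source"])
        seg = subject_segments(
            subjects, tables["patients"], tl, empty, "all_cause_mortality",
            users_current_only=True)
        user_seg = seg[seg["cohort"] == "user"]
        assert (user_seg["exposure"] == "current").all()
        current_py = tl[tl["state"] == "current"]
        # clipped person-time cannot exceed the unclipped current time
        assert user_seg["py"].sum() <= (
            (current_py["end"] - current_py["start"]).sum() / DAYS_PER_YEAR
        ) + 1e-9

    def test_full_partition_conserves_followup(self, sim_tables):
        cfg, tables = sim_tables
        subjects, _ = ap.build_cohorts(
            tables["patients"], tables["prescriptions"], tables["events"],
            seed=1, study_end=cfg.horizon_days)
        subjects.insert(0, "subject_id", np.arange(len(subjects)))
        eps = ap.episodes_frame(tables["prescriptions"])
        users = subjects[subjects["cohort"] == "user"]
        tl = ap.build_timelines(
            eps, users.set_index("patient_id")["censor_date"].astype(float))
        empty = pd.DataFrame(columns=["subject_id", "patient_id", "cohort",
                                      "outcome", "event_date", "winning_source"])
        seg = subject_segments(
            subjects, tables["patients"], tl, empty, "all_cause_mortality",
            users_current_only=False)
        got = seg.groupby("subject_id")["py"].sum()
        want = (subjects.set_index("subject_id")["censor_date"]
                - subjects.set_index("subject_id")["index_date"]) / DAYS_PER_YEAR
        # users start contributing at their index (= first in-window script)
        rel = (got - want.reindex(got.index)).abs() / want.reindex(got.index)
        assert rel.max() < 1e-9


def test_split_at_is_exact():
    df = pd.DataFrame({"start": [0.0, 10.0], "end": [10.0, 20.0]})
    out = _split_at(df, np.array([5.0, 25.0]))
    assert len(out) == 3 and np.isclose(out["end"].sum() - out["start"].sum(), 20.0)


# ---------------------------------------------------------------------------
# Poisson fitting
# ---------------------------------------------------------------------------

class TestFitRateRatio:
    def test_matches_closed_form_on_two_cells(self):
        seg = seg_frame(
            [{"exposure": "current", "events": 40, "py": 2000.0},
             {"exposure": "unexposed", "events": 20, "py": 2000.0,
              "cohort": "psych_nonuser"}]
        )
        est = fit_rate_ratio(seg)[0]
        rr, lo, hi = crude_rate_ratio(40, 2000.0, 20, 2000.0)
        assert np.isclose(est.rr, rr, rtol=1e-7)
        assert np.isclose(est.ci_low, lo, rtol=1e-4)
        assert np.isclose(est.ci_high, hi, rtol=1e-4)

    def test_identical_groups_give_rr_one(self):
        seg = seg_frame(
            [{"exposure": "current", "events": 33, "py": 1234.0},
             {"exposure": "unexposed", "events": 33, "py": 1234.0,
              "cohort": "psych_nonuser"}]
        )
        est = fit_rate_ratio(seg)[0]
        assert np.isclose(est.rr, 1.0, atol=1e-10)

    def test_zero_events_yield_nc_not_exception(self):
        seg = seg_frame(
            [{"exposure": "current", "events": 0, "py": 100.0},
             {"exposure": "unexposed", "events": 5, "py": 100.0,
              "cohort": "psych_nonuser"}]
        )
        est = fit_rate_ratio(seg)[0]
        assert est.nc and np.isnan(est.rr)

    def test_multi_level_exposure_one_estimate_per_level(self):
        seg = seg_frame(
            [{"exposure": "low", "events": 15, "py": 1000.0},
             {"exposure": "medium", "events": 20, "py": 1000.0},
             {"exposure": "high", "events": 25, "py": 1000.0},
             {"exposure": "unexposed", "events": 10, "py": 1000.0,
              "cohort": "psych_nonuser"}]
        )
        ests = {e.exposed: e for e in fit_rate_ratio(seg)}
        assert set(ests) == {"low", "medium", "high"}
        assert ests["low"].rr < ests["medium"].rr < ests["high"].rr

    def test_missing_reference_raises(self):
        seg = seg_frame([{"exposure": "current", "events": 5, "py": 10.0}])
        with pytest.raises(ValueError):
            fit_rate_ratio(seg)


class TestCovariateSelection:
    def _data(self, rng, n=4000, beta_z=1.0, confounded=True, events_scale=1.0):
        z = rng.integers(0, 2, n)
        noise = rng.integers(0, 2, n)
        p_exp = np.where(z == 1, 0.6, 0.3) if confounded else np.full(n, 0.45)
        exposed = rng.random(n) < p_exp
        py = rng.uniform(0.5, 3.0, n)
        rate = 0.05 * events_scale * np.exp(beta_z * z + np.log(2.0) * exposed)
        events = rng.poisson(rate * py)
        return pd.DataFrame({
            "exposure": np.where(exposed, "current", "unexposed"),
            "cohort": np.where(exposed, "user", "psych_nonuser"),
            "age_band": rng.choice(["30-64", "65-79"], n),
            "sex": rng.choice(["F", "M"], n),
            "zconf": z, "znoise": noise, "events": events, "py": py,
        })

    def test_parameter_budget_truncates_candidates(self):
        """Ten events allow two parameters; forced terms exhaust the budget."""
        rng = np.random.default_rng(1)
        df = self._data(rng, n=300, events_scale=0.05)
        df = df.iloc[: np.searchsorted(df["events"].cumsum(), 10) + 1]
        spec = ModelSpec(candidate_covariates=[
            "znoise", "zconf", "a", "b", "c", "d"])
        kept = select_covariates(df, "exposure", "unexposed", spec)
        assert kept == []

    def test_strong_confounder_retained_and_debiases(self):
        rng = np.random.default_rng(2)
        df = self._data(rng, n=6000, beta_z=1.2)
        spec = ModelSpec(candidate_covariates=["zconf", "znoise"])
        kept = select_covariates(df, "exposure", "unexposed", spec)
        assert "zconf" in kept
        crude = fit_rate_ratio(df, adjustment="age_sex")[0]
        full = fit_rate_ratio(df, adjustment="full", spec=spec)[0]
        assert abs(np.log(full.rr) - np.log(2.0)) < abs(np.log(crude.rr) - np.log(2.0))
        assert np.log(crude.rr) > np.log(2.0) + 0.05  # planted upward bias

    def test_pure_noise_covariate_mostly_removed(self):
        rng = np.random.default_rng(3)
        removed = 0
        for _ in range(20):
            df = self._data(rng, n=1500, beta_z=0.0, confounded=False)
            kept = select_covariates(
                df, "exposure", "unexposed",
                ModelSpec(candidate_covariates=["znoise"]))
            removed += "znoise" not in kept
        assert removed >= 16  # ~5% type-I retention


def test_stratified_rr_dose_bands():
    seg = seg_frame(
        [{"exposure": "current", "dose_band": "low", "events": 12, "py": 900.0},
         {"exposure": "current", "dose_band": "medium", "events": 18, "py": 900.0},
         {"exposure": "current", "dose_band": "high", "events": 26, "py": 900.0},
         {"exposure": "unexposed", "dose_band": None, "events": 10, "py": 1000.0,
          "cohort": "psych_nonuser"}]
    )
    out = ap.stratified_rr(seg, by="dose_band")["all"]
    ests = {e.exposed: e.rr for e in out}
    assert ests["low"] < ests["medium"] < ests["high"]


def test_empty_stratum_is_nc():
    seg = seg_frame(
        [{"exposure": "current", "dose_band": "low", "events": 5, "py": 100.0},
         {"exposure": "current", "dose_band": "high", "events": 0, "py": 50.0},
         {"exposure": "unexposed", "dose_band": None, "events": 5, "py": 100.0,
          "cohort": "psych_nonuser"}]
    )
    out = {e.exposed: e for e in ap.stratified_rr(seg, by="dose_band")["all"]}
    assert out["high"].nc and not out["low"].nc
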