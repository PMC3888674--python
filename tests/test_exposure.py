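"""Dose standardisation, duration estimation, and timeline algebra."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import apcohort as ap
from apcohort.exposure import (
    DEFAULT_DURATION_DAYS,
    build_imputation_tables,
    episodes_frame,
)

from conftest import mk_episodes, mk_rx
from oracles import interval_lookup, scan_states, day_dose


# ---------------------------------------------------------------------------
# DDD computation and imputation
# ---------------------------------------------------------------------------

class TestComputeDDD:
    def test_chlorpromazine_identity_conversion(self):
        tables = ap.ImputationTables()
        ddd, imputed = ap.compute_ddd(
            {"drug_name": "chlorpromazine", "prescribed_daily_dose": 2.0,
             "strength": 100.0},
            tables,
        )
        assert ddd == 200.0 and not imputed

    def test_out_of_range_uses_therapy_median(self):
        tables = ap.ImputationTables(ddd_by_drug={"chlorpromazine": 250.0})
        ddd, imputed = ap.compute_ddd(
            {"drug_name": "chlorpromazine", "prescribed_daily_dose": 4.0,
             "strength": 300.0},  # 1200 mg, above the plausible range
            tables,
        )
        assert imputed and ddd == 250.0

    def test_no_therapy_median_falls_back_to_class(self):
        tables = ap.ImputationTables(ddd_by_class={"typical": 320.0})
        ddd, imputed = ap.compute_ddd(
            {"drug_name": "haloperidol", "prescribed_daily_dose": np.nan,
             "strength": np.nan},
            tables,
        )
        assert imputed and ddd == 320.0

    def test_below_range_treated_as_unknown(self):
        tables = ap.ImputationTables(ddd_by_drug={"haloperidol": 300.0})
        # 0.1 tab/day x 2 mg x 50 = 10 mg, below 25
        ddd, imputed = ap.compute_ddd(
            {"drug_name": "haloperidol", "prescribed_daily_dose": 0.1,
             "strength": 2.0},
            tables,
        )
        assert imputed and ddd == 300.0

    def test_unknown_drug_is_a_configuration_error(self):
        with pytest.raises(ap.ConfigError):
            ap.compute_ddd(
                {"drug_name": "aspirin", "prescribed_daily_dose": 1.0,
                 "strength": 100.0},
                ap.ImputationTables(),
            )


class TestEstimateDuration:
    def test_quantity_over_daily_dose(self):
        dur, imputed = ap.estimate_duration(
            {"drug_name": "chlorpromazine", "quantity": 56.0,
             "prescribed_daily_dose": 2.0},
            ap.ImputationTables(),
        )
        assert dur == 28.0 and not imputed

    def test_implausibly_long_duration_imputed(self):
        tables = ap.ImputationTables(duration_by_drug={"chlorpromazine": 28.0})
        dur, imputed = ap.estimate_duration(
            {"drug_name": "chlorpromazine", "quantity": 1000.0,
             "prescribed_daily_dose": 1.0},
            tables,
        )
        assert imputed and dur == 28.0

    def test_missing_quantity_uses_product_median(self):
        tables = ap.ImputationTables(duration_by_drug={"olanzapine": 30.0})
        dur, imputed = ap.estimate_duration(
            {"drug_name": "olanzapine", "quantity": np.nan,
             "prescribed_daily_dose": 1.0},
            tables,
        )
        assert imputed and dur == 30.0

    def test_boundaries_are_inclusive(self):
        # 1 and 91.4 days are plausible, just inside the bounds
        for qty, pdd, expect in [(1.0, 1.0, 1.0), (91.4, 1.0, 91.4)]:
            dur, imputed = ap.estimate_duration(
                {"drug_name": "chlorpromazine", "quantity": qty,
                 "prescribed_daily_dose": pdd},
                ap.ImputationTables(),
            )
            assert dur == expect and not imputed


def test_imputation_tables_built_from_calculable_values():
    rx = mk_rx(
        [
            {"date": 0, "prescribed_daily_dose": 2.0, "strength": 100.0},   # 200
            {"date": 30, "prescribed_daily_dose": 3.0, "strength": 100.0},  # 300
            {"date": 60, "prescribed_daily_dose": 20.0, "strength": 100.0}, # 2000: invalid
            {"date": 90, "strength": np.nan},                               # missing
        ]
    )
    tables = build_imputation_tables(rx)
    assert tables.ddd_by_drug["chlorpromazine"] == 250.0
    assert tables.ddd_by_class["typical"] == 250.0


def test_imputation_is_idempotent():
    """Imputed outputs are in-range, so a second pass changes nothing."""
    rng = np.random.default_rng(5)
    rows = []
    for i in range(200):
        rows.append(
            {
                "date": float(i),
                "patient_id": i % 20,
                "prescribed_daily_dose": rng.choice([1.0, 2.0, 40.0, np.nan]),
                "strength": rng.choice([50.0, 100.0, 400.0, np.nan]),
                "quantity": rng.choice([28.0, 56.0, 5000.0, np.nan]),
            }
        )
    eps = episodes_frame(mk_rx(rows))
    lo, hi = 25.0, 1000.0
    assert ((eps["ddd_mg"] >= lo) & (eps["ddd_mg"] <= hi)).all()
    assert ((eps["duration_days"] >= 1.0) & (eps["duration_days"] <= 91.4)).all()
    # feed the standardised values back through: nothing is re-imputed
    tables = build_imputation_tables(mk_rx(rows))
    for ddd in eps["ddd_mg"].unique():
        val, imputed = ap.compute_ddd(
            {"drug_name": "chlorpromazine", "prescribed_daily_dose": 1.0,
             "strength": float(ddd)},
            tables,
        )
        assert val == ddd and not imputed


def test_duplicate_prescriptions_merged():
    rx = mk_rx([{"date": 10.0}, {"date": 10.0}, {"date": 50.0}])
    eps = episodes_frame(rx)
    assert len(eps) == 2


# ---------------------------------------------------------------------------
# Dose bands
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ddd,band",
    [(150.0, "low"), (199.9, "low"), (200.0, "medium"), (399.9, "medium"),
     (400.0, "high"), (1000.0, "high")],
)
def test_dose_band_edges(ddd, band):
    assert ap.dose_band(ddd) == band


def test_dose_band_rejects_nonpositive():
    with pytest.raises(ValueError):
        ap.dose_band(0.0)


@pytest.mark.parametrize(
    "days,band", [(100, "<1y"), (365.25, "1-3y"), (1000, "1-3y"), (1096, ">3y")]
)
def test_cumulative_duration_band(days, band):
    assert ap.cum_duration_band(days) == band


# ---------------------------------------------------------------------------
# Timeline construction
# ---------------------------------------------------------------------------

class TestTimeline:
    def test_single_script_windows(self):
        eps = mk_episodes([{"start": 0.0, "duration_days": 28.0}])
        tl = ap.build_timeline(eps, censor_date=400.0)
        current = tl[tl["state"] == "current"]
        assert current["start"].min() == 0.0
        assert np.isclose(current["end"].max(), 58.4)
        recent = tl[tl["state"] == "recent"].iloc[0]
        assert np.isclose(recent["start"], 58.4) and np.isclose(recent["end"], 210.4)
        past = tl[tl["state"] == "past"].iloc[0]
        assert np.isclose(past["start"], 210.4) and past["end"] == 400.0

    def test_gap_within_grace_is_stitched(self):
        eps = mk_episodes(
            [{"start": 0.0, "duration_days": 28.0},
             {"start": 40.0, "duration_days": 28.0}]
        )
        tl = ap.build_timeline(eps, censor_date=300.0)
        current = tl[tl["state"] == "current"]
        assert current["start"].min() == 0.0
        assert np.isclose(current["end"].max(), 98.4)  # 40 + 28 + 30.4
        # one continuous current block: segments tile [0, 98.4)
        assert (current["start"].to_numpy()[1:] == current["end"].to_numpy()[:-1]).all()

    def test_boundary_gap_exactly_one_month_is_continuous(self):
        # expected end 28, grace to 58.4; a script at day 58.4 still stitches
        eps = mk_episodes(
            [{"start": 0.0, "duration_days": 28.0},
             {"start": 58.4, "duration_days": 28.0}]
        )
        tl = ap.build_timeline(eps, censor_date=200.0)
        current = tl[tl["state"] == "current"]
        assert np.isclose(current["end"].max(), 58.4 + 28.0 + 30.4)
        assert (current["start"].min(), len(tl[tl["state"] == "recent"])) == (0.0, 1)

    def test_new_script_during_past_reopens_current(self):
        eps = mk_episodes(
            [{"start": 0.0, "duration_days": 28.0},
             {"start": 250.0, "duration_days": 28.0}]
        )
        tl = ap.build_timeline(eps, censor_date=500.0)
        past = tl[tl["state"] == "past"]
        assert past.iloc[0]["end"] == 250.0  # truncated by the new script
        assert interval_lookup(tl, 250.0).state == "current"

    def test_person_time_is_conserved_exactly(self):
        eps = mk_episodes(
            [{"start": 3.0, "duration_days": 14.0},
             {"start": 100.0, "duration_days": 56.0},
             {"start": 400.0, "duration_days": 28.0}]
        )
        censor = 730.0
        tl = ap.build_timeline(eps, censor)
        assert np.isclose((tl["end"] - tl["start"]).sum(), censor - 3.0, atol=1e-9)
        # intervals are disjoint, ordered, contiguous
        assert (tl["start"].to_numpy()[1:] == tl["end"].to_numpy()[:-1]).all()

    def test_overlapping_scripts_sum_doses(self):
        eps = mk_episodes(
            [{"start": 0.0, "duration_days": 28.0, "ddd_mg": 150.0},
             {"start": 10.0, "duration_days": 28.0, "ddd_mg": 150.0}]
        )
        tl = ap.build_timeline(eps, censor_date=100.0)
        assert interval_lookup(tl, 5.0).dose_band == "low"       # 150
        assert interval_lookup(tl, 15.0).dose_band == "medium"   # 300
        assert interval_lookup(tl, 30.0).dose_band == "low"      # back to 150
        # grace tail after both expire carries the latest script's dose
        assert interval_lookup(tl, 40.0).dose_band == "low"

    def test_cumulative_duration_band_progression(self):
        # 400-day continuous current exposure crosses the 1-year edge
        eps = mk_episodes([{"start": 0.0, "duration_days": 91.0},
                           {"start": 91.0, "duration_days": 91.0},
                           {"start": 182.0, "duration_days": 91.0},
                           {"start": 273.0, "duration_days": 91.0},
                           {"start": 364.0, "duration_days": 91.0}])
        tl = ap.build_timeline(eps, censor_date=500.0)
        current = tl[tl["state"] == "current"]
        bands = current["cum_duration_band"].tolist()
        assert bands[0] == "<1y" and bands[-1] == "1-3y"
        edge_rows = current[current["cum_duration_band"] == "1-3y"]
        assert np.isclose(edge_rows["start"].min(), 365.25)

    def test_mixed_class_interval(self):
        eps = mk_episodes(
            [{"start": 0.0, "duration_days": 28.0, "drug_class": "typical"},
             {"start": 5.0, "duration_days": 28.0, "drug_class": "atypical"}]
        )
        tl = ap.build_timeline(eps, censor_date=60.0)
        assert interval_lookup(tl, 10.0).drug_class == "mixed"
        assert interval_lookup(tl, 2.0).drug_class == "typical"


# ---------------------------------------------------------------------------
# Property: equivalence with the day-by-day scanner
# ---------------------------------------------------------------------------

episode_lists = st.lists(
    st.tuples(
        st.integers(min_value=0, max_value=600),          # start day
        st.sampled_from([1.0, 14.0, 28.0, 42.0, 56.0, 91.4]),  # duration
        st.sampled_from([100.0, 150.0, 250.0, 450.0]),    # ddd
    ),
    min_size=1,
    max_size=20,
)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(eps=episode_lists, censor=st.integers(min_value=1, max_value=900))
def test_timeline_matches_day_scanner(eps, censor):
    starts = np.array([e[0] for e in eps], dtype=float)
    if censor <= starts.min():
        censor = int(starts.min()) + 1
    durs = np.array([e[1] for e in eps])
    ddds = np.array([e[2] for e in eps])
    frame = mk_episodes(
        [{"start": s, "duration_days": d, "ddd_mg": m}
         for s, d, m in zip(starts, durs, ddds)]
    )
    tl = ap.build_timeline(frame, float(censor))

    expected = scan_states(starts, starts + durs, censor)
    for day, want in expected.items():
        row = interval_lookup(tl, float(day))
        assert row is not None, f"day {day} uncovered"
        assert row.state == want, f"day {day}: {row.state} != {want}"
        if want == "current":
            dose = day_dose(float(day), starts, starts + durs, ddds)
            assert row.dose_band == ap.dose_band(dose)
    # conservation and ordering hold on every example
    assert np.isclose((tl["end"] - tl["start"]).sum(), censor - starts.min())
    cur = tl[tl["state"] == "current"]
    cums = cur["cum_duration_band"].map({"<1y": 0, "1-3y": 1, ">3y": 2})
    assert (np.diff(cums.to_numpy()) >= 0).all()
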