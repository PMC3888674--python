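"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's interval algebra: exposure states
are derived day by day from the raw prescription set, person-time by
counting days, hazard grids by per-subject accumulation.
"""

from __future__ import annotations

import numpy as np

GRACE = 30.4
RECENT = 182.4


def day_state(day: float, starts: np.ndarray, expected_ends: np.ndarray) -> str | None:
    """Exposure state on one day by scanning every prescription.

    The latest expected end among scripts already started governs: within
    the one-month grace after it the day is current (gaps shorter than the
    grace never leave current, which reproduces the stitching rule);
    within six months, recent; later, past.  None before the first script.
    """
    seen = starts <= day
    if not seen.any():
        return None
    horizon = float(np.max(expected_ends[seen]))
    if day < horizon + GRACE:
        return "current"
    if day < horizon + RECENT:
        return "recent"
    return "past"


def day_dose(day: float, starts, expected_ends, ddds) -> float:
    """Active chlorpromazine-equivalent dose on one day.

    Sum of doses of scripts covering the day; in a grace tail (no active
    script) the most recent script's dose governs (latest start, then
    latest position breaking ties).
    """
    active = (starts <= day) & (day < expected_ends)
    if active.any():
        return float(np.sum(ddds[active]))
    seen = np.flatnonzero(starts <= day)
    if len(seen) == 0:
        return np.nan
    best = seen[np.lexsort((seen, starts[seen]))[-1]]
    return float(ddds[best])


def scan_states(
    starts: np.ndarray, expected_ends: np.ndarray, censor: int
) -> dict[int, str]:
    """State per integer day over [first start, censor)."""
    first = int(np.min(starts))
    out = {}
    for d in range(first, int(censor)):
        s = day_state(d, starts, expected_ends)
        if s is not None:
            out[d] = s
    return out


def interval_lookup(timeline, t: float):
    """Row of the timeline containing time t, or None."""
    for row in timeline.itertuples(index=False):
        if row.start <= t < row.end:
            return row
    return None


def count_person_days(index: float, end: float) -> float:
    """Follow-up in days by explicit day counting (integer boundaries)."""
    return max(0.0, float(end) - float(index))


def grid_tally(followup, event_time, edges):
    """Per-period events and at-risk time by per-subject accumulation."""
    n = len(edges) - 1
    events = np.zeros(n)
    at_risk = np.zeros(n)
    for T, ev in zip(followup, event_time):
        for j in range(n):
            lo, hi = edges[j], edges[j + 1]
            at_risk[j] += max(0.0, min(T, hi) - lo) if T > lo else 0.0
        if np.isfinite(ev):
            j = min(int(np.searchsorted(edges, ev, side="right")) - 1, n - 1)
            if 0 <= j < n:
                events[j] += 1
    return events, at_risk
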