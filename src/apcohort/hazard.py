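"""Kernel-smoothed hazard curves over time since treatment start.

Follow-up from the start of medication is subdivided into a fixed number
of equal-length periods (100 by default); per-period event counts and
at-risk person-time give occurrence/exposure rate estimates — the
discrete hazard increments of a Nelson-Aalen-type estimator on a
person-time grid.  A kernel-weighted sum of those increments
(Ramlau-Hansen smoothing; Epanechnikov kernel by default) yields a
continuous hazard-rate curve with a log-scale normal pointwise confidence
band, and the pointwise ratio of two curves compares the hazard between
groups over treatment time.  Estimates within one bandwidth of either end
of the grid are flagged as boundary points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import N_HAZARD_PERIODS

_Z95 = 1.959963984540054


@dataclass
class HazardGrid:
    """Events and at-risk time per period of time-since-treatment-start."""

    period_edges: np.ndarray        # n_periods + 1, strictly increasing
    events: np.ndarray              # count per period
    at_risk_time: np.ndarray        # person-time per period (same units)

    @property
    def n_periods(self) -> int:
        return len(self.events)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.period_edges[:-1] + self.period_edges[1:])

    @property
    def raw_rates(self) -> np.ndarray:
        """Per-period hazard estimates: events / at-risk time (0 where empty)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.events / self.at_risk_time
        return np.where(self.at_risk_time > 0, r, 0.0)


@dataclass
class SmoothedCurve:
    """Pointwise hazard (or hazard-ratio) estimate with confidence band."""

    eval_points: np.ndarray
    hazard: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    variance: np.ndarray
    bandwidth: float
    kernel: str
    boundary: np.ndarray            # True where within one bandwidth of an end


def build_grid(
    followup: np.ndarray,
    event_time: np.ndarray,
    n_periods: int = N_HAZARD_PERIODS,
    span: float | None = None,
) -> HazardGrid:
    """Per-period events and at-risk time from per-subject follow-up.

    ``followup`` is each subject's time from treatment start to the end of
    follow-up; ``event_time`` the event's time on the same scale (NaN when
    no event).  A subject contributes at-risk time to every period it
    survives through.
    """
    if n_periods < 2:
        raise ValueError(f"n_periods must be >= 2, got {n_periods}")
    followup = np.asarray(followup, dtype=float)
    event_time = np.asarray(event_time, dtype=float)
    if span is None:
        span = float(followup.max()) if len(followup) else 1.0
    edges = np.linspace(0.0, span, n_periods + 1)

    # overlap of [0, T_i) with each period, summed over subjects
    lo = edges[:-1][None, :]
    hi = edges[1:][None, :]
    at_risk = np.clip(followup[:, None], lo, hi) - lo
    at_risk = at_risk.sum(axis=0)

    has_event = np.isfinite(event_time)
    ev = np.histogram(event_time[has_event], bins=edges)[0].astype(float)
    # events exactly at the span end belong to the last period (half-open
    # elsewhere; numpy's histogram closes the final bin, which matches)
    return HazardGrid(period_edges=edges, events=ev, at_risk_time=at_risk)


def _kernel(name: str, u: np.ndarray) -> np.ndarray:
    a = np.abs(u)
    if name == "epanechnikov":
        return np.where(a <= 1, 0.75 * (1 - u * u), 0.0)
    if name == "uniform":
        return np.where(a <= 1, 0.5, 0.0)
    if name == "biweight":
        return np.where(a <= 1, 0.9375 * (1 - u * u) ** 2, 0.0)
    raise ValueError(f"unknown kernel {name!r}")


def smooth(
    grid: HazardGrid,
    bandwidth: float | None = None,
    kernel: str = "epanechnikov",
    eval_points: np.ndarray | None = None,
) -> SmoothedCurve:
    """Ramlau-Hansen smoothing of the per-period hazard increments.

    The estimate at t is a kernel-weighted average of the per-period
    occurrence/exposure rates (weights normalised to unit mass), with
    pointwise variance from the weighted event counts over squared at-risk
    time and a normal-theory interval on the log scale.  ``bandwidth``
    defaults to five grid periods.
    """
    if bandwidth is None:
        bandwidth = 5.0 * (grid.period_edges[1] - grid.period_edges[0])
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    if eval_points is None:
        eval_points = grid.midpoints
    eval_points = np.asarray(eval_points, dtype=float)

    mids = grid.midpoints
    rates = grid.raw_rates
    with np.errstate(divide="ignore", invalid="ignore"):
        var_inc = np.where(
            grid.at_risk_time > 0, grid.events / grid.at_risk_time**2, 0.0
        )

    u = (eval_points[:, None] - mids[None, :]) / bandwidth
    w = _kernel(kernel, u)
    mass = w.sum(axis=1)
    ok = mass > 0
    w[ok] = w[ok] / mass[ok, None]

    hazard = w @ rates
    variance = (w * w) @ var_inc
    with np.errstate(divide="ignore", invalid="ignore"):
        se_log = np.sqrt(variance) / hazard
    ci_low = np.where(hazard > 0, hazard * np.exp(-_Z95 * se_log), 0.0)
    ci_high = np.where(hazard > 0, hazard * np.exp(_Z95 * se_log), 0.0)

    t0, t1 = grid.period_edges[0], grid.period_edges[-1]
    boundary = (eval_points < t0 + bandwidth) | (eval_points > t1 - bandwidth)
    return SmoothedCurve(
        eval_points=eval_points, hazard=hazard, ci_low=ci_low, ci_high=ci_high,
        variance=variance, bandwidth=float(bandwidth), kernel=kernel,
        boundary=boundary,
    )


def hazard_ratio_curve(curve_a: SmoothedCurve, curve_b: SmoothedCurve) -> SmoothedCurve:
    """Pointwise ratio a/b with a combined log-scale confidence band.

    Points where either curve is zero are masked (NaN): the ratio or its
    variance is undefined there.
    """
    if not np.array_equal(curve_a.eval_points, curve_b.eval_points):
        raise ValueError("curves must share eval_points")
    ha, hb = curve_a.hazard, curve_b.hazard
    ok = (ha > 0) & (hb > 0)
    ratio = np.where(ok, ha / np.where(hb > 0, hb, 1.0), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log = np.where(
            ok,
            curve_a.variance / np.where(ha > 0, ha, 1.0) ** 2
            + curve_b.variance / np.where(hb > 0, hb, 1.0) ** 2,
            np.nan,
        )
    se = np.sqrt(var_log)
    return SmoothedCurve(
        eval_points=curve_a.eval_points,
        hazard=ratio,
        ci_low=ratio * np.exp(-_Z95 * se),
        ci_high=ratio * np.exp(_Z95 * se),
        variance=var_log,
        bandwidth=curve_a.bandwidth,
        kernel=curve_a.kernel,
        boundary=curve_a.boundary | curve_b.boundary,
    )
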