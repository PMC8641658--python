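"""Horizon endpoints, Kaplan-Meier product-limit curves and log-rank tests.

Graft loss is retransplantation or death, whichever comes first; the patient
endpoint ignores retransplantation.  For the binary horizon endpoints,
patients censored before the horizon without an event are excluded by
default (``censored_as_survivor=True`` gives the alternative reading).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .cohort import OutcomeRecord

HORIZONS = (90, 180, 365)
ENDPOINTS = ("graft", "patient")


@dataclass(frozen=True)
class HorizonLabel:
    patient_id: str
    horizon: int
    endpoint: str
    label: str  # "event" | "survivor" | "excluded"


def _event_time(outcome: OutcomeRecord, endpoint: str) -> float | None:
    if endpoint == "graft":
        return outcome.graft_loss_day
    if endpoint == "patient":
        return outcome.death_day if outcome.death else None
    raise ValueError(f"unknown endpoint {endpoint!r}")


def derive_labels(
    outcomes: Iterable[OutcomeRecord],
    horizon: int,
    endpoint: str,
    censored_as_survivor: bool = False,
) -> list[HorizonLabel]:
    """Binary labels at a horizon: event if the endpoint event occurred on or
    before the horizon; survivor if followed (event-free) to the horizon;
    otherwise excluded (or survivor under ``censored_as_survivor``)."""
    labels = []
    for outcome in outcomes:
        t = _event_time(outcome, endpoint)
        if t is not None and t <= horizon:
            label = "event"
        elif outcome.follow_up_days >= horizon or (t is not None and t > horizon):
            label = "survivor"
        else:
            label = "survivor" if censored_as_survivor else "excluded"
        labels.append(HorizonLabel(outcome.patient_id, horizon, endpoint, label))
    return labels


def time_and_event(outcome: OutcomeRecord, endpoint: str) -> tuple[float, bool]:
    """(time, event flag) pair for the product-limit estimator."""
    t = _event_time(outcome, endpoint)
    if t is not None:
        return t, True
    return outcome.follow_up_days, False


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival just after each distinct event time."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) at those times
    at_risk: np.ndarray    # number at risk just before each time
    n_events: np.ndarray   # events at each time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate with simultaneous decrement of
    tied event times.  ``events`` is 1 for an observed event, 0 censored."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one subject")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    event_times = np.unique(times[events == 1])
    surv, risk, evts = [], [], []
    s = 1.0
    for t in event_times:
        n_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        risk.append(n_risk)
        evts.append(d)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(risk, dtype=int),
        n_events=np.asarray(evts, dtype=int),
    )


def logrank_test(groups: list[tuple]) -> tuple[float, int, float]:
    """k-sample log-rank test.

    ``groups`` is a list of (times, events) pairs; returns
    (chi-square, df, p) with df = k - 1.  The statistic is the quadratic form
    of observed-minus-expected events in the first k-1 groups against the
    hypergeometric covariance accumulated over distinct event times.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    times_list, events_list = [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {g} has zero subjects")
        times_list.append(t)
        events_list.append(e)

    all_times = np.concatenate(times_list)
    all_events = np.concatenate(events_list)
    group_idx = np.concatenate(
        [np.full(t.size, g) for g, t in enumerate(times_list)]
    )
    event_times = np.unique(all_times[all_events == 1])

    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk_mask = all_times >= t
        n = at_risk_mask.sum()
        d = int(np.sum((all_times == t) & (all_events == 1)))
        n_g = np.array([(at_risk_mask & (group_idx == g)).sum() for g in range(k)], dtype=float)
        d_g = np.array(
            [np.sum((all_times == t) & (all_events == 1) & (group_idx == g)) for g in range(k)],
            dtype=float,
        )
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            frac = n_g / n
            v = d * (n - d) / (n - 1)
            cov += v * (np.diag(frac) - np.outer(frac, frac))

    diff = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    if not np.any(diff) or not np.any(v):
        chi2 = 0.0
    else:
        try:
            chi2 = float(diff @ np.linalg.solve(v, diff))
        except np.linalg.LinAlgError:
            chi2 = float(diff @ np.linalg.pinv(v) @ diff)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p


def km_table(curve: KMCurve):
    """CSV-friendly table of the product-limit estimate."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time": curve.times,
            "at_risk": curve.at_risk,
            "events": curve.n_events,
            "survival": curve.survival,
        }
    )
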