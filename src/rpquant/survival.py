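"""Survival endpoints and comparisons.

Endpoints are measured in days from radiotherapy completion: locoregional
progression-free survival (LRPFS), progression-free survival (PFS) and
overall survival (OS). Comparisons follow the study design: Kaplan-Meier
curves, the two-group log-rank test, and univariate Cox regression (Efron
tie handling, Wald confidence intervals). Estimation is delegated to
lifelines; this module fixes the interfaces and the degenerate-input
behaviour (no events -> missing result rather than an exception or an
infinite hazard ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test

__all__ = [
    "ENDPOINTS",
    "SurvivalRecord",
    "KMEstimate",
    "CoxResult",
    "km_estimate",
    "logrank",
    "cox_univariate",
]

ENDPOINTS = ("LRPFS", "PFS", "OS")


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient-endpoint observation."""

    time: float
    event: bool
    endpoint: str = "OS"
    group: str | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be positive, got {self.time}")


def _times_events(records) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=bool)
    if times.size == 0:
        raise ValueError("no survival records")
    if np.any(times <= 0):
        raise ValueError("all times must be positive")
    return times, events


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival step function with a risk table.

    ``survival[i]`` is S(t) just after ``times[i]``; S(0) = 1 is implicit.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return 1.0 if i < 0 else float(self.survival[i])


def km_estimate(records) -> KMEstimate:
    """Kaplan-Meier estimate from (time, event) records; censoring allowed."""
    times, events = _times_events(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    t = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy(dtype=float)
    return KMEstimate(
        times=t,
        survival=surv,
        at_risk=tbl["at_risk"].to_numpy(dtype=float),
        n_events=tbl["observed"].to_numpy(dtype=float),
    )


def logrank(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p.

    Returns (nan, nan) when no events are observed in either group, where
    the statistic is undefined.
    """
    ta, ea = _times_events(group_a)
    tb, eb = _times_events(group_b)
    if ea.sum() + eb.sum() == 0:
        return float("nan"), float("nan")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit: hazard ratio, Wald 95% CI and p.

    ``converged`` is False when the partial likelihood was flat or monotone
    (e.g. complete separation); estimates are then unreliable and callers
    should report them as missing.
    """

    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p: float
    log_hr: float
    se_log_hr: float
    n_events: int
    converged: bool


def cox_univariate(times, events, covariate) -> CoxResult:
    """Cox proportional-hazards fit for a single covariate (Efron ties)."""
    df = pd.DataFrame(
        {
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=bool).astype(int),
            "x": np.asarray(covariate, dtype=float),
        }
    )
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise ValueError("need at least 2 events for Cox regression")
    if df["x"].nunique() < 2:
        raise ValueError("covariate is constant")

    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, ConvergenceWarning):
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cph.fit(df, duration_col="time", event_col="event")
                except ConvergenceError as err:
                    raise ValueError(f"Cox fit failed outright: {err}") from err

    row = cph.summary.loc["x"]
    return CoxResult(
        hazard_ratio=float(np.exp(row["coef"])),
        ci_lower=float(np.exp(row["coef lower 95%"])),
        ci_upper=float(np.exp(row["coef upper 95%"])),
        p=float(row["p"]),
        log_hr=float(row["coef"]),
        se_log_hr=float(row["se(coef)"]),
        n_events=n_events,
        converged=converged,
    )
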