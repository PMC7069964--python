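"""Five-year outcome labels, Kaplan-Meier curves, log-rank tests and
univariate Cox proportional-hazards analysis of predicted risk groups.

Time is measured in months throughout; the classification horizon is 60
months (five years). Patients censored before the horizon cannot be
labeled alive or dead for classification, but their partial follow-up
still contributes to KM/log-rank/Cox analyses.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "FiveYearLabels", "KMCurve", "LogRankResult", "CoxResult",
    "RiskGroupResult", "five_year_label", "km_estimate", "logrank",
    "cox_univariate", "risk_group_survival", "HORIZON_MONTHS",
]

log = logging.getLogger(__name__)

HORIZON_MONTHS = 60.0


@dataclass
class FiveYearLabels:
    """Binary five-year outcome per sample.

    ``dead`` is True for an observed death within the horizon; samples
    alive past the horizon (event or not) are labeled alive. ``usable``
    is False for patients censored before the horizon, whose five-year
    status is unknown.
    """

    sample_ids: tuple[str, ...]
    dead: np.ndarray
    usable: np.ndarray


def five_year_label(survival_table: pd.DataFrame,
                    horizon: float = HORIZON_MONTHS) -> FiveYearLabels:
    """Label each patient alive/dead at five years.

    time > horizon -> alive regardless of a later event; an observed death
    at or before the horizon -> dead; censored at or before the horizon ->
    masked out (``usable`` False).
    """
    t = survival_table["time_months"].to_numpy(dtype=float)
    e = survival_table["event"].to_numpy(dtype=int)
    if np.any(t < 0):
        raise ValueError("negative survival times")
    dead = (e == 1) & (t <= horizon)
    usable = (t > horizon) | dead
    return FiveYearLabels(tuple(survival_table.index), dead, usable)


@dataclass
class KMCurve:
    """Product-limit estimate evaluated after each event time (months)."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


def km_estimate(times, events, truncate_months: float = HORIZON_MONTHS) -> KMCurve:
    """Kaplan-Meier estimate truncated at ``truncate_months``.

    At tied times events are processed before censorings (the standard
    product-limit convention). Returns survival probability, at-risk and
    event counts after each distinct event time up to the truncation.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    ev = ev[ev.index <= truncate_months]
    t = ev.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    s = np.array([float(sf.loc[ti]) for ti in t])
    return KMCurve(t, s, ev["at_risk"].to_numpy(dtype=int),
                   ev["observed"].to_numpy(dtype=int))


@dataclass
class LogRankResult:
    statistic: float
    p_value: float


def logrank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test (chi-square, 1 df)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    res = logrank_test(ta, tb, event_observed_A=np.asarray(events_a, int),
                       event_observed_B=np.asarray(events_b, int))
    return LogRankResult(float(res.test_statistic), float(res.p_value))


@dataclass
class CoxResult:
    """Univariate Cox PH fit for a binary high-risk indicator."""

    log_hr: float
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_high: int
    n_low: int
    monotone: bool = False  # all events in one group; unbounded estimate


def _breslow_score_terms(x, times, events):
    """Per-event-time (d_j, s_j, n1_j, n0_j) for the Breslow likelihood."""
    order = np.argsort(times, kind="stable")
    t, e, xx = times[order], events[order], x[order]
    out = []
    for tj in np.unique(t[e == 1]):
        at = t >= tj
        ev = (t == tj) & (e == 1)
        out.append((int(ev.sum()), int(xx[ev].sum()),
                    int((xx == 1)[at].sum()), int((xx == 0)[at].sum())))
    return out


def cox_univariate(group_indicator, times, events) -> CoxResult:
    """Newton maximization of the Breslow partial likelihood for a single
    binary covariate (1 = high risk), with Wald 95% CI and p-value.

    If every event falls in one group the likelihood is monotone in the
    coefficient; the result is returned with ``monotone=True`` and
    infinite confidence bounds.
    """
    x = np.asarray(group_indicator, dtype=int)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if set(np.unique(x)) - {0, 1}:
        raise ValueError("group indicator must be binary 0/1")
    n_high, n_low = int((x == 1).sum()), int((x == 0).sum())
    terms = _breslow_score_terms(x, times, events)
    if not terms:
        raise ValueError("no events observed")
    s_total = sum(s for _, s, _, _ in terms)
    d_high = s_total
    d_low = sum(d for d, _, _, _ in terms) - s_total
    if d_high == 0 or d_low == 0:
        beta = -np.inf if d_high == 0 else np.inf
        return CoxResult(beta, float(np.exp(beta)), 0.0, np.inf, 1.0,
                         n_high, n_low, monotone=True)
    beta = 0.0
    for _ in range(100):
        u = np.exp(beta)
        score = float(s_total)
        info = 0.0
        for d, _s, n1, n0 in terms:
            denom = n1 * u + n0
            score -= d * n1 * u / denom
            info += d * n1 * n0 * u / denom**2
        step = score / info
        beta += step
        if abs(step) < 1e-12:
            break
    se = 1.0 / np.sqrt(info)
    z = stats.norm.ppf(0.975)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return CoxResult(float(beta), float(np.exp(beta)),
                     float(np.exp(beta - z * se)), float(np.exp(beta + z * se)),
                     float(p), n_high, n_low)


@dataclass
class RiskGroupResult:
    km_high: KMCurve | None
    km_low: KMCurve | None
    logrank: LogRankResult | None
    cox: CoxResult | None
    n_high: int
    n_low: int
    degenerate: bool = False


def risk_group_survival(risk_scores, cutoff: float,
                        survival_table: pd.DataFrame) -> RiskGroupResult:
    """Stratify patients at ``cutoff`` and compare the risk groups.

    High risk = predicted death probability >= cutoff. KM curves, the
    log-rank test and a univariate Cox fit use the full survival records
    (censored patients included). If one group is empty a degenerate
    result is returned with a warning.
    """
    scores = np.asarray(risk_scores, dtype=float)
    if scores.size != len(survival_table):
        raise ValueError("predictions not aligned to survival records")
    high = scores >= cutoff
    t = survival_table["time_months"].to_numpy(dtype=float)
    e = survival_table["event"].to_numpy(dtype=int)
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        warnings.warn("all samples fell into one risk group; "
                      "survival comparison is degenerate", stacklevel=2)
        return RiskGroupResult(None, None, None, None, n_high, n_low,
                               degenerate=True)
    km_h = km_estimate(t[high], e[high])
    km_l = km_estimate(t[~high], e[~high])
    lr = logrank(t[high], e[high], t[~high], e[~high])
    cox = cox_univariate(high.astype(int), t, e)
    return RiskGroupResult(km_h, km_l, lr, cox, n_high, n_low)
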