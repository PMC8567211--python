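"""Survival estimation for trial endpoints.

Endpoints follow the usual leukaemia-trial conventions:

* relapse rate - time to relapse for patients reaching remission,
  censored at death in remission or last contact, presented as 1 - KM;
* event-free survival (EFS) - time to relapse, second tumour or death,
  censored at last contact;
* overall survival (OS) - time to death, censored at last contact.

Kaplan-Meier estimation, log-rank tests, Cox proportional-hazards models
(Efron tie handling) and Harrell's concordance index are provided as
thin wrappers around lifelines, returning plain dataclasses.  Pointwise
95% confidence bands use the log(-log) (exponential Greenwood)
transform, which keeps the bounds inside [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index

ENDPOINTS = ("relapse", "efs", "os")


@dataclass
class SurvivalCurve:
    """Product-limit estimate with pointwise 95% bounds and risk counts."""

    event_times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray


@dataclass
class CoxResult:
    """Per-covariate hazard ratio with Wald interval and p-value."""

    covariate: str
    hr: float
    ci95: tuple[float, float]
    p: float
    log_partial_likelihood: float
    n_events: int

    @property
    def coef(self) -> float:
        return float(np.log(self.hr))


def km_fit(times, indicators) -> SurvivalCurve:
    """Kaplan-Meier fit with Greenwood variance and log(-log) 95% CI."""
    times = np.asarray(times, dtype=float)
    indicators = np.asarray(indicators)
    if times.shape != indicators.shape:
        raise ValueError("times and indicators must have the same length")
    if times.size == 0:
        raise ValueError("at least one subject is required")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=indicators)
    ci = kmf.confidence_interval_survival_function_
    idx = kmf.survival_function_.index.to_numpy(dtype=float)
    return SurvivalCurve(
        event_times=idx,
        survival=kmf.survival_function_["KM_estimate"].to_numpy(),
        ci_low=ci.iloc[:, 0].to_numpy(),
        ci_high=ci.iloc[:, 1].to_numpy(),
        n_at_risk=kmf.event_table["at_risk"].reindex(idx).to_numpy(),
    )


def rate_at(curve: SurvivalCurve, horizon: float, as_failure: bool = False):
    """Survival (or failure) rate at a horizon with its 95% CI.

    Uses the last step at or before the horizon.  When the horizon lies
    before the first observed time, returns the degenerate estimate with
    a warning; beyond last follow-up, the final estimate is carried
    forward with a warning.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    positive_times = curve.event_times[curve.event_times > 0]
    if positive_times.size and horizon < positive_times[0]:
        warnings.warn("horizon precedes first observed time; returning S=1")
    pos = np.searchsorted(curve.event_times, horizon, side="right") - 1
    if pos < 0:
        s, lo, hi = 1.0, 1.0, 1.0
    else:
        if horizon > curve.event_times[-1]:
            warnings.warn("horizon beyond last follow-up; carrying last estimate forward")
        s = float(curve.survival[pos])
        lo = float(curve.ci_low[pos])
        hi = float(curve.ci_high[pos])
    if as_failure:
        return 1.0 - s, (1.0 - hi, 1.0 - lo)
    return s, (lo, hi)


def logrank(groups: Sequence[tuple]) -> tuple[float, float]:
    """Log-rank test across >=2 groups of ``(times, indicators)``."""
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e)
        if t.size == 0:
            raise ValueError(f"group {i} has zero subjects")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    times,
    indicators,
    covariates: pd.DataFrame,
    mode: str = "multivariate",
) -> dict[str, CoxResult]:
    """Cox proportional-hazards fit (Efron ties, Wald CI/p per covariate).

    ``mode="univariate"`` fits each covariate in its own model;
    ``mode="multivariate"`` fits them jointly.  Raises ``ValueError`` for
    constant covariates and ``RuntimeError`` on non-convergence (the
    message advises exact methods when separation is the likely cause).
    """
    covariates = pd.DataFrame(covariates)
    for col in covariates.columns:
        if covariates[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant")
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode: {mode!r}")

    def _one(cols: list) -> dict[str, CoxResult]:
        df = covariates[cols].copy()
        df["_time"] = np.asarray(times, dtype=float)
        df["_event"] = np.asarray(indicators).astype(int)
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError as err:
            raise RuntimeError(
                "Cox model failed to converge (possible complete separation; "
                f"consider exact methods): {err}"
            ) from err
        out = {}
        for col in cols:
            s = cph.summary.loc[col]
            out[col] = CoxResult(
                covariate=str(col),
                hr=float(s["exp(coef)"]),
                ci95=(float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"])),
                p=float(s["p"]),
                log_partial_likelihood=float(cph.log_likelihood_),
                n_events=int(df["_event"].sum()),
            )
        return out

    if mode == "univariate":
        results: dict[str, CoxResult] = {}
        for col in covariates.columns:
            results.update(_one([col]))
        return results
    return _one(list(covariates.columns))


def concordance(predicted_risk, times, indicators) -> float:
    """Harrell's C over usable pairs; prediction ties credited 0.5."""
    predicted_risk = np.asarray(predicted_risk, dtype=float)
    times = np.asarray(times, dtype=float)
    indicators = np.asarray(indicators)
    if not (predicted_risk.size == times.size == indicators.size):
        raise ValueError("inputs must have the same length")
    if indicators.sum() == 0:
        raise ValueError("no usable pairs: no events observed")
    # lifelines' concordance_index scores *higher predicted value = longer
    # survival*, so pass the negated risk.
    return float(concordance_index(times, -predicted_risk, indicators))


def endpoint_columns(endpoint: str) -> tuple[str, str]:
    """Map an endpoint name to its cohort-table column pair."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
    return f"time_{endpoint}", f"ind_{endpoint}"
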