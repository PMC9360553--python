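"""Kaplan-Meier estimation, log-rank testing, and univariate Cox regression.

Thin, typed wrappers over lifelines: the product-limit estimator, the
observed-vs-expected log-rank chi-square, and Cox partial-likelihood fits
with Efron tie handling. A median-split helper supports the common practice
of dichotomizing a continuous score at its median before Kaplan-Meier
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test

__all__ = ["KmCurve", "CoxResult", "km_estimate", "logrank_test", "cox_univariate", "median_split"]


@dataclass
class KmCurve:
    """Product-limit survival estimate."""

    times: np.ndarray  # event/censor times in ascending order (unique)
    at_risk: np.ndarray
    survival: np.ndarray  # S(t) just after each time
    censor_times: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.size and (s[0] > 1 + 1e-12 or (np.diff(s) > 1e-12).any() or (s < -1e-12).any()):
            raise ValueError("survival curve must start <= 1, be non-increasing, and stay in [0,1]")

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first observed time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald inference)."""

    beta: float
    hazard_ratio: float
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int
    converged: bool = True
    separation_flag: bool = False


def _validate_survival(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    return t, e.astype(int)


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimate with ties handled at common times."""
    t, e = _validate_survival(times, events)
    kmf = KaplanMeierFitter().fit(t, e)
    # lifelines inserts a t=0 anchor row; keep observed times only
    table = kmf.event_table
    observed_times = np.asarray(table.index, dtype=float)
    mask = np.isin(observed_times, np.unique(t))
    sf = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy()
    return KmCurve(
        times=observed_times[mask],
        at_risk=table["at_risk"].to_numpy()[mask],
        survival=sf[mask],
        censor_times=np.sort(t[e == 0]),
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value across >= 2 groups
    (1 degree of freedom for two groups)."""
    t, e = _validate_survival(times, events)
    g = np.asarray(groups)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if (counts == 0).any():
        raise ValueError("each group needs >= 1 subject")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(covariate, times, events, max_iter: int = 100) -> CoxResult:
    """Univariate Cox PH regression of survival on one covariate.

    Efron correction for tied event times; Wald z and p; perfect separation
    (monotone partial likelihood) is flagged rather than silently reported.
    """
    t, e = _validate_survival(times, events)
    x = np.asarray(covariate, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariate must be finite")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if e.sum() == 0:
        raise ValueError("no events")
    df = pd.DataFrame({"x": x, "time": t, "event": e})
    cph = CoxPHFitter()
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            cph.fit(df, duration_col="time", event_col="event",
                    fit_options={"max_steps": max_iter, "precision": 1e-9})
        except ConvergenceError as err:
            raise ValueError(f"Cox fit did not converge: {err}") from err
        except ConvergenceWarning:
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event",
                        fit_options={"max_steps": max_iter})
    s = cph.summary.loc["x"]
    return CoxResult(
        beta=float(s["coef"]),
        hazard_ratio=float(s["exp(coef)"]),
        se=float(s["se(coef)"]),
        z=float(s["z"]),
        p=float(s["p"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        n=len(df),
        n_events=int(e.sum()),
        converged=True,
        separation_flag=separation,
    )


def median_split(values) -> np.ndarray:
    """Dichotomize a continuous covariate at its median: 'high' where value
    is strictly above the median, else 'low'."""
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    return np.where(v > med, "high", "low")
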