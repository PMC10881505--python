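"""Nonparametric survival stages: Kaplan-Meier, log-rank, univariate screening.

These estimators operate on one outcome at a time.  For the semi-competing
cohort the cause-specific convention applies: the recurrence outcome uses
(y1, d1), so a death without recurrence censors the recurrence process at
y1; the death outcome uses (y2, d2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Dataset

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "median_survival",
    "survival_at",
    "logrank_test",
    "cause_specific_logrank",
    "univariate_screen",
    "SCREENING_COVARIATES",
]


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variances and log(-log) bands.

    ``times`` are the distinct event times in ascending order; censoring
    between event times only depletes the risk sets.  ``median`` is the
    smallest time at which the curve drops to 0.5 or below; the median CI
    inverts the pointwise bands (NaN encodes "not reached").
    """

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float
    median_ci: tuple[float, float]
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
                "lower": self.ci_lower,
                "upper": self.ci_upper,
            }
        )


@dataclass
class LogRankResult:
    """Multi-group log-rank comparison on (#groups - 1) degrees of freedom."""

    statistic: float
    df: int
    p_value: float
    groups: list
    observed: np.ndarray
    expected: np.ndarray


def _step_eval(times: np.ndarray, values: np.ndarray, t: float, start: float = 1.0) -> float:
    """Right-continuous step-function evaluation with value ``start`` before
    the first jump."""
    idx = np.searchsorted(times, t, side="right") - 1
    return float(values[idx]) if idx >= 0 else start


def km_estimate(times, events, alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Ties of events at one time are grouped into a single factor; a
    censored observation tied with an event time is still counted at risk
    there (events first).  Pointwise (1-alpha) bands use the Greenwood
    variance on the log(-log) scale.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("events must be 0 or 1")

    n = times.size
    event_times = np.unique(times[events == 1])
    n_risk = np.empty(event_times.size)
    n_event = np.empty(event_times.size)
    for j, t in enumerate(event_times):
        n_risk[j] = np.sum(times >= t)
        n_event[j] = np.sum((times == t) & (events == 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - n_event / n_risk
        survival = np.cumprod(factors)
        # Greenwood: Var S(t) = S(t)^2 * cumsum d / (r (r - d))
        gw_terms = np.where(n_risk > n_event, n_event / (n_risk * (n_risk - n_event)), np.inf)
        cum_gw = np.cumsum(gw_terms)
        variance = survival**2 * cum_gw
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        # log(-log) transformed bands: S^(exp(+/- z * se(log(-log S))))
        loglog_se = np.sqrt(cum_gw) / np.abs(np.log(survival))
        lower = survival ** np.exp(z * loglog_se)
        upper = survival ** np.exp(-z * loglog_se)
    zero = survival <= 0
    variance[zero] = 0.0
    lower[zero] = 0.0
    upper[zero] = 0.0
    lower = np.nan_to_num(lower, nan=0.0)
    upper = np.where(np.isnan(upper), 1.0, upper)

    median = _first_crossing(event_times, survival)
    med_lo = _first_crossing(event_times, lower)
    med_hi = _first_crossing(event_times, upper)
    return KMCurve(
        times=event_times,
        n_risk=n_risk,
        n_event=n_event,
        survival=survival,
        variance=variance,
        ci_lower=lower,
        ci_upper=upper,
        median=median,
        median_ci=(med_lo, med_hi),
        n=n,
    )


def _first_crossing(times: np.ndarray, curve: np.ndarray, level: float = 0.5) -> float:
    """Smallest time where the step curve is <= level; NaN if never."""
    hit = np.flatnonzero(curve <= level)
    return float(times[hit[0]]) if hit.size else float("nan")


def median_survival(curve: KMCurve) -> tuple[float, tuple[float, float]]:
    """Median survival time and its 95% CI from the pointwise bands.

    The lower bound is where the lower band crosses 0.5 (the earliest the
    true curve could reach it), the upper bound where the upper band does.
    NaN bounds mean the band never crosses 0.5 ("not reached").
    """
    return curve.median, curve.median_ci


def survival_at(curve: KMCurve, t_list) -> pd.DataFrame:
    """Survival probabilities (with Greenwood bands) at the requested times.

    The step function is evaluated right-continuously.  Times beyond the
    last observed event are flagged ``extrapolated`` and carry the value of
    the last step.
    """
    t_list = np.atleast_1d(np.asarray(t_list, dtype=float))
    if np.any(t_list <= 0):
        raise ValueError("evaluation times must be positive")
    last = curve.times[-1] if curve.times.size else 0.0
    rows = []
    for t in t_list:
        rows.append(
            {
                "time": float(t),
                "survival": _step_eval(curve.times, curve.survival, t),
                "lower": _step_eval(curve.times, curve.ci_lower, t),
                "upper": _step_eval(curve.times, curve.ci_upper, t),
                "extrapolated": bool(t > last),
            }
        )
    return pd.DataFrame(rows)


def logrank_test(times, events, groups) -> LogRankResult:
    """K-sample log-rank test via hypergeometric observed-minus-expected.

    At each distinct pooled event time the per-group event counts are
    compared with their hypergeometric expectations; the quadratic form of
    the first K-1 components against the estimated covariance gives a
    chi-square statistic on K-1 degrees of freedom.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = labels.size
    if k < 2:
        raise ValueError("need at least two nonempty groups")
    gidx = np.searchsorted(labels, groups)

    event_times = np.unique(times[events == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n_j = at_risk.sum()
        d_j = int(((times == t) & (events == 1)).sum())
        if n_j == 0 or d_j == 0:
            continue
        n_ij = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_ij = np.bincount(gidx[(times == t) & (events == 1)], minlength=k).astype(float)
        frac = n_ij / n_j
        observed += d_ij
        expected += d_j * frac
        if n_j > 1:
            mult = d_j * (n_j - d_j) / (n_j - 1)
            V += mult * (np.diag(frac) - np.outer(frac, frac))
    diff = (observed - expected)[:-1]
    Vsub = V[:-1, :-1]
    if diff.size and np.any(np.diag(Vsub) > 0):
        statistic = float(diff @ np.linalg.pinv(Vsub) @ diff)
    else:
        statistic = 0.0
    statistic = max(statistic, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(statistic, df))
    return LogRankResult(
        statistic=statistic,
        df=df,
        p_value=p,
        groups=list(labels),
        observed=observed,
        expected=expected,
    )


def _outcome_arrays(ds: Dataset, outcome: str) -> tuple[np.ndarray, np.ndarray]:
    y1, d1, y2, d2 = ds.arrays()
    if outcome == "recurrence":
        return y1, d1
    if outcome == "death":
        return y2, d2
    raise ValueError("outcome must be 'recurrence' or 'death'")


def cause_specific_logrank(ds: Dataset, outcome: str, group_covariate: str) -> LogRankResult:
    """Log-rank comparison of one outcome across the levels of a covariate.

    For the recurrence outcome a death without recurrence censors the
    recurrence process at y1; for the death outcome (y2, d2) is used.
    """
    times, events = _outcome_arrays(ds, outcome)
    groups = ds.covariate(group_covariate)
    return logrank_test(times, events, groups)


#: candidate covariates for the default univariate screening pass
SCREENING_COVARIATES = [
    "age_group",
    "gender",
    "bmi_group",
    "grade",
    "tumor_size_group",
    "chemo_group",
    "stage",
    "site",
    "stage_site",
    "radiotherapy",
    "chemotherapy",
    "morphology",
]


def univariate_screen(
    ds: Dataset,
    alpha: float = 0.1,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Screen candidate covariates by cause-specific log-rank per outcome.

    A covariate passes when its log-rank p-value is below ``alpha`` for at
    least one of the two outcomes.  Covariates with fewer than two observed
    levels are reported with NaN p-values and do not pass.
    """
    if covariates is None:
        covariates = [c for c in SCREENING_COVARIATES if ds.records and c in ds.records[0].covariates]
    rows = []
    for name in covariates:
        ps = {}
        for outcome in ("recurrence", "death"):
            levels = np.unique(ds.covariate(name))
            if levels.size < 2:
                ps[outcome] = float("nan")
                continue
            ps[outcome] = cause_specific_logrank(ds, outcome, name).p_value
        passes = any(p < alpha for p in ps.values() if not np.isnan(p))
        rows.append(
            {
                "covariate": name,
                "p_recurrence": ps["recurrence"],
                "p_death": ps["death"],
                "passes": passes,
            }
        )
    return pd.DataFrame(rows)
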