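"""Survival statistics used throughout the pipeline.

Kaplan–Meier product-limit estimation, median survival (with a
``NOT_REACHED`` sentinel for curves that never drop to 0.5), survival at a
fixed time, the multi-group log-rank test, Benjamini–Hochberg adjustment,
and Cox proportional-hazards fitting.

KM and log-rank are implemented directly on numpy arrays because the
quantile screen runs thousands of log-rank tests per cohort; both are
cross-checked against lifelines in the test suite.  Cox fitting wraps
lifelines' ``CoxPHFitter``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Sentinel for a median that the KM curve never reaches.
NOT_REACHED = float("inf")


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class CoxFit:
    names: list[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    converged: bool


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("survival times must be nonnegative")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event flags must be 0/1")
    return times, events


def km_fit(times, events) -> SurvivalCurve:
    """Kaplan–Meier estimator: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    event_times = np.unique(t[e == 1])
    # at risk just before each event time; deaths at each event time
    n_at_risk = t.size - np.searchsorted(t, event_times, side="left")
    deaths = np.array([(t[e == 1] == et).sum() for et in event_times])
    surv = np.cumprod(1.0 - deaths / n_at_risk) if event_times.size else np.array([])
    return SurvivalCurve(event_times, surv, n_at_risk, times.size)


def median_survival(curve: SurvivalCurve) -> float:
    """Smallest event time with S(t) <= 0.5, or ``NOT_REACHED``."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return NOT_REACHED
    return float(curve.event_times[below[0]])


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Right-continuous step value S(t)."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    idx = np.searchsorted(curve.event_times, t, side="right")
    return 1.0 if idx == 0 else float(curve.survival[idx - 1])


def logrank_test(times, events, group_labels) -> LogrankResult:
    """Multi-group log-rank test (chi-square with G-1 df).

    Observed-minus-expected event counts per group with the hypergeometric
    variance at each distinct event time.
    """
    times, events = _check_surv(times, events)
    groups = np.asarray(group_labels)
    if groups.shape != times.shape:
        raise ValueError("group labels must align with times")
    uniq, gidx = np.unique(groups, return_inverse=True)
    g = uniq.size
    if g < 2:
        raise ValueError("log-rank test needs at least two groups")

    order = np.argsort(times, kind="stable")
    t, e, gi = times[order], events[order], gidx[order]
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return LogrankResult(0.0, g - 1, 1.0)

    onehot = np.eye(g)[gi]
    # at-risk per group just before each event time: reverse cumulative sums
    cum = np.vstack([np.zeros(g), np.cumsum(onehot, axis=0)])
    totals = cum[-1]
    starts = np.searchsorted(t, event_times, side="left")
    n_g = totals - cum[starts]                      # (T, g) at risk per group
    n_tot = n_g.sum(axis=1)
    dcum = np.vstack([np.zeros(g), np.cumsum(onehot * e[:, None], axis=0)])
    ends = np.searchsorted(t, event_times, side="right")
    d_g = dcum[ends] - dcum[starts]                 # (T, g) deaths per group
    d_tot = d_g.sum(axis=1)

    expected = n_g * (d_tot / n_tot)[:, None]
    z = (d_g - expected).sum(axis=0)

    # hypergeometric covariance, summed over event times
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = d_tot * (n_tot - d_tot) / (n_tot - 1)
    factor = np.where(n_tot > 1, factor, 0.0)
    p = n_g / n_tot[:, None]
    cov = -np.einsum("t,ti,tj->ij", factor, p, p)
    cov[np.diag_indices(g)] += (factor[:, None] * p).sum(axis=0)

    zr, covr = z[:-1], cov[:-1, :-1]
    try:
        stat = float(zr @ np.linalg.solve(covr, zr))
    except np.linalg.LinAlgError:
        stat = float(zr @ np.linalg.pinv(covr) @ zr)
    stat = max(stat, 0.0)
    pval = float(stats.chi2.sf(stat, g - 1))
    return LogrankResult(stat, g - 1, pval)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def coxph_fit(times, events, covariates, names: list[str] | None = None) -> CoxFit:
    """Cox proportional-hazards fit (lifelines); never raises on separation.

    Returns per-covariate coefficients, hazard ratios, Wald 95% CIs and
    p-values, with ``converged=False`` (and a logged warning) instead of an
    exception when the partial-likelihood maximization fails.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    times, events = _check_surv(times, events)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != times.size:
        X = X.T
    k = X.shape[1]
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if times.size <= k:
        raise ValueError("need more observations than covariates")
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant covariate")

    df = pd.DataFrame(X, columns=names)
    df["time"] = times
    df["event"] = events
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        logger.warning("Cox fit did not converge: %s", err)
        nan = np.full(k, np.nan)
        return CoxFit(names, nan, nan, nan, nan, nan, converged=False)

    summ = cph.summary.loc[names]
    return CoxFit(
        names=names,
        coefficients=summ["coef"].to_numpy(),
        hazard_ratios=summ["exp(coef)"].to_numpy(),
        ci_lower=np.exp(summ["coef lower 95%"].to_numpy()),
        ci_upper=np.exp(summ["coef upper 95%"].to_numpy()),
        p_values=summ["p"].to_numpy(),
        converged=True,
    )
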