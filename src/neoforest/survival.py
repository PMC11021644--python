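"""Survival stratification by predicted neoepitope load.

Each patient's load is the number of peptides whose prediction score
clears the operating-point cutoff.  Patients are split into quartile
groups (high / medium-high / medium-low / low) and compared with
Kaplan-Meier curves, the log-rank test, and a high-vs-low hazard ratio
from a single-covariate Cox model.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

GROUPS = ("high", "medium_high", "medium_low", "low")


def neoepitope_load(
    scores,
    patient_ids,
    cutoff: float,
    higher_is_positive: bool = True,
) -> dict[str, int]:
    """Per-patient count of peptides scoring at or beyond the cutoff."""
    scores = np.asarray(scores, dtype=float)
    patient_ids = np.asarray(patient_ids)
    hit = scores >= cutoff if higher_is_positive else scores <= cutoff
    return {
        str(p): int(hit[patient_ids == p].sum()) for p in np.unique(patient_ids)
    }


def quantile_groups(
    loads: Mapping[str, float] | Sequence[float],
) -> dict[str, str]:
    """Quartile stratification of patients by neoepitope load.

    Boundaries (Q1/Q2/Q3 by linear-interpolation quantiles, the R
    type-7 default): high when load >= Q3, low when load <= Q1,
    medium-low on (Q1, Q2], medium-high on (Q2, Q3).  Where collapsed
    quartiles make boundaries coincide the precedence is
    high > low > medium-high > medium-low.
    """
    if isinstance(loads, Mapping):
        keys = list(loads.keys())
        values = np.asarray([loads[k] for k in keys], dtype=float)
    else:
        values = np.asarray(loads, dtype=float)
        keys = [str(i) for i in range(len(values))]
    if len(values) < 4:
        raise ValueError("quartile grouping needs at least 4 patients")
    if np.all(values == values[0]):
        warnings.warn("all loads identical; every patient falls in one group")
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear = R type 7

    out: dict[str, str] = {}
    for key, v in zip(keys, values):
        if v >= q3:
            group = "high"
        elif v <= q1:
            group = "low"
        elif v > q2:
            group = "medium_high"
        else:
            group = "medium_low"
        out[key] = group
    return out


def km_estimator(times, events) -> pd.DataFrame:
    """Product-limit survival curve as (time, survival) steps."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
    )


def logrank_test(groups: Mapping[str, tuple]) -> tuple[float, int, float]:
    """Multi-group log-rank test; returns (chi2, df, p)."""
    names = [g for g, (t, _) in groups.items() if len(t) > 0]
    if len(names) < 2:
        raise ValueError("log-rank test needs >= 2 non-empty groups")
    times, events, labels = [], [], []
    for g in names:
        t, e = groups[g]
        times.extend(np.asarray(t, float))
        events.extend(np.asarray(e, int))
        labels.extend([g] * len(t))
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), len(names) - 1, float(res.p_value)


def cox_hr_high_vs_low(
    times, events, is_high, max_iter: int = 50, tol: float = 1e-10
) -> tuple[float, float]:
    """Hazard ratio of the high vs low group from a one-covariate Cox fit.

    Newton iteration on the Breslow partial likelihood; the covariate
    is the high-group indicator.  Returns (HR, Wald p-value).  A group
    without events makes the likelihood monotone, which is an error.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(is_high, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("both groups must be represented")
    for grp in (0.0, 1.0):
        if events[x == grp].sum() == 0:
            raise ValueError("a group has no events; hazard ratio is unbounded")

    order = np.argsort(times, kind="mergesort")
    times, events, x = times[order], events[order], x[order]
    event_times = np.unique(times[events == 1])

    beta = 0.0
    for _ in range(max_iter):
        grad = 0.0
        hess = 0.0
        for t in event_times:
            at_risk = times >= t
            d_mask = (times == t) & (events == 1)
            d = d_mask.sum()
            w = np.exp(beta * x[at_risk])
            s0 = w.sum()
            s1 = (w * x[at_risk]).sum()
            grad += x[d_mask].sum() - d * s1 / s0
            hess += d * (s1 / s0) * (1 - s1 / s0)
        if hess <= 0:
            break
        step = grad / hess
        beta += step
        if abs(step) < tol:
            break
    se = 1.0 / np.sqrt(hess) if hess > 0 else np.inf
    p = float(2 * stats.norm.sf(abs(beta / se))) if np.isfinite(se) else 1.0
    return float(np.exp(beta)), p


def survival_analysis(
    survival: pd.DataFrame,
    loads: Mapping[str, int],
) -> dict:
    """Quartile-group KM/log-rank/HR summary for one prediction model.

    ``survival`` needs columns patient_id, time, event; patients absent
    from ``loads`` are dropped with a log message.
    """
    surv = survival[survival["patient_id"].astype(str).isin(loads)].copy()
    dropped = len(survival) - len(surv)
    if dropped:
        logger.info("dropping %d patients without predictions", dropped)
    surv["group"] = [quantile_groups(loads)[str(p)] for p in surv["patient_id"]]

    group_data = {
        g: (sub["time"].to_numpy(), sub["event"].to_numpy())
        for g, sub in surv.groupby("group")
    }
    chi2, df, p = logrank_test(group_data)
    result = {
        "groups": {g: int(len(t)) for g, (t, _) in group_data.items()},
        "logrank_chi2": chi2,
        "logrank_df": df,
        "logrank_p": p,
        "km": {g: km_estimator(t, e) for g, (t, e) in group_data.items()},
    }
    hl = surv[surv["group"].isin(["high", "low"])]
    try:
        hr, hr_p = cox_hr_high_vs_low(
            hl["time"], hl["event"], (hl["group"] == "high").astype(float)
        )
        result["hr_high_vs_low"] = hr
        result["hr_p"] = hr_p
    except ValueError as exc:
        logger.info("hazard ratio unavailable: %s", exc)
        result["hr_high_vs_low"] = None
        result["hr_p"] = None
    return result
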