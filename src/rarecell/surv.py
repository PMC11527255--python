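"""Kaplan-Meier estimation and two-group log-rank testing.

Used to ask whether the presence of at least one CTC-IGC in a sample, or
high expression of a candidate marker, is associated with shorter
progression-free survival.  Cohort tables carry one row per subject with
columns ``id``, ``group``, ``time`` (months) and ``event`` (1 = observed,
0 = censored).  When an event and a censoring share a time, the event is
taken to precede the censoring (the standard convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["KMCurve", "km_estimate", "logrank_test", "dichotomize_expression"]


@dataclass
class KMCurve:
    """Product-limit survival curve with Greenwood variance.

    ``times`` are the distinct event times; ``survival[i]`` is S(t) just
    after ``times[i]``.  ``median`` is the first time with S(t) <= 0.5,
    or NaN when the curve never falls that far.
    """

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before any event."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def _validate(ct: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in ct.columns:
            raise ValueError(f"cohort table missing column {col!r}")
    if (ct["time"] <= 0).any():
        raise ValueError("times must be positive")
    if not ct["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return ct


def km_estimate(ct: pd.DataFrame, group=None) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group.

    With no censoring this reduces exactly to the empirical survival
    function.  The variance is Greenwood's formula.
    """
    ct = _validate(ct)
    if group is not None:
        ct = ct[ct["group"] == group]
    if len(ct) == 0:
        raise ValueError("no subjects in group")
    t = ct["time"].to_numpy(dtype=float)
    e = ct["event"].to_numpy(dtype=int)

    event_times = np.unique(t[e == 1])
    surv = np.empty(len(event_times))
    var = np.empty(len(event_times))
    at_risk = np.empty(len(event_times), dtype=int)
    n_ev = np.empty(len(event_times), dtype=int)
    s = 1.0
    gw = 0.0  # Greenwood accumulator sum d/(n(n-d))
    for i, ti in enumerate(event_times):
        n_i = int((t >= ti).sum())  # censored at ti still at risk (event first)
        d_i = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            gw += d_i / (n_i * (n_i - d_i))
            var[i] = s**2 * gw
        else:
            var[i] = 0.0
        surv[i] = s
        at_risk[i] = n_i
        n_ev[i] = d_i
    below = np.flatnonzero(surv <= 0.5)
    median = float(event_times[below[0]]) if below.size else float("nan")
    return KMCurve(
        times=event_times,
        survival=surv,
        variance=var,
        at_risk=at_risk,
        n_events=n_ev,
        median=median,
    )


def logrank_test(ct: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    At each distinct event time the observed events in group 1 are
    compared with the hypergeometric expectation given the risk sets; the
    squared standardized sum is referred to chi-square with 1 df.
    """
    ct = _validate(ct)
    groups = sorted(pd.unique(ct["group"]))
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 non-empty groups, got {groups}")
    t = ct["time"].to_numpy(dtype=float)
    e = ct["event"].to_numpy(dtype=int)
    g = (ct["group"] == groups[1]).to_numpy()
    if e.sum() == 0:
        raise ValueError("no events in cohort")

    o_minus_e = 0.0
    v = 0.0
    for ti in np.unique(t[e == 1]):
        at = t >= ti
        n = int(at.sum())
        n1 = int((at & g).sum())
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & g).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def dichotomize_expression(
    values: pd.Series | np.ndarray, rule: str = "median"
) -> np.ndarray:
    """Split subjects into 'high'/'low' by an expression cut-point.

    ``median`` (default): high iff value > median (ties go low);
    ``mean``: high iff value > mean.  Constant values leave a single
    group, which is an error because no two-group test is possible.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 subjects")
    if rule == "median":
        cut = float(np.median(v))
    elif rule == "mean":
        cut = float(np.mean(v))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    labels = np.where(v > cut, "high", "low")
    if len(np.unique(labels)) < 2:
        raise ValueError("constant expression values: cannot form two groups")
    return labels
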