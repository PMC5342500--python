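"""Median-split survival analysis: Kaplan-Meier, log-rank, Cox.

Samples are stratified at the median of anchor-gene expression
(strictly above the median -> "high"; ties at the median -> "low", a
deterministic rule). Group prognosis is compared with the product-limit
estimator, the two-group log-rank test, and a univariate Cox
proportional-hazards fit on the high/low indicator (Efron tie
handling). Estimation is delegated to lifelines; this module owns the
stratification rule and the result contracts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "CoxFit",
    "stratify_by_median",
    "km_curve",
    "logrank_test",
    "cox_hazard_ratio",
]


@dataclass(frozen=True)
class CoxFit:
    beta: float
    hr: float
    se: float
    p: float
    ci_low: float
    ci_high: float
    converged: bool


def stratify_by_median(expr: pd.Series) -> pd.Series:
    """Label samples high/low at the median; ties at the median go low."""
    if len(expr) < 2:
        raise ValueError("need >= 2 samples to stratify")
    x = expr.astype(float)
    if x.nunique() == 1:
        raise ValueError("all values identical; no stratification possible")
    med = x.median()
    return pd.Series(
        np.where(x > med, "high", "low"), index=expr.index, name="group"
    )


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    if (t["time"] < 0).any():
        raise ValueError("negative survival times")
    if not t["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return t


def km_curve(table: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Product-limit survival estimate, optionally for one group.

    Returns a DataFrame indexed by time with column ``survival``;
    starts at S(0) = 1 and is a non-increasing step function. Censored
    times enter the risk set but do not drop the curve.
    """
    t = _validate(table)
    if group is not None:
        t = t[t["group"] == group]
        if t.empty:
            raise ValueError(f"group {group!r} is empty")
    kmf = KaplanMeierFitter()
    kmf.fit(t["time"], t["event"])
    out = kmf.survival_function_
    out.columns = ["survival"]
    out.index.name = "time"
    return out


def logrank_test(table: pd.DataFrame) -> dict:
    """Two-group log-rank test (1 df chi-square).

    Expects columns (time, event, group) with groups {high, low}.
    """
    t = _validate(table)
    groups = t["group"].unique()
    if len(groups) != 2:
        raise ValueError("exactly two non-empty groups required")
    if t["event"].sum() == 0:
        raise ValueError("no events observed")
    a = t[t["group"] == groups[0]]
    b = t[t["group"] == groups[1]]
    res = _ll_logrank(a["time"], b["time"], a["event"], b["event"])
    return {"statistic": float(res.test_statistic), "p": float(res.p_value)}


def cox_hazard_ratio(table: pd.DataFrame) -> CoxFit:
    """Univariate Cox PH fit on the high-vs-low group indicator.

    Maximizes the Efron partial likelihood (Newton-Raphson inside
    lifelines); reports the Wald p-value and 95% CI for the hazard
    ratio of high relative to low. Complete separation is reported as
    ``converged=False`` rather than raised.
    """
    t = _validate(table)
    t["z"] = (t["group"] == "high").astype(float)
    if t["z"].nunique() < 2:
        # degenerate single-level covariate: no contrast, hr = 1 exactly
        return CoxFit(0.0, 1.0, np.nan, 1.0, np.nan, np.nan, True)
    if t["event"].sum() == 0:
        raise ValueError("no events observed")
    cph = CoxPHFitter()
    try:
        cph.fit(t[["time", "event", "z"]], duration_col="time", event_col="event")
    except ConvergenceError:
        return CoxFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False)
    s = cph.summary.loc["z"]
    return CoxFit(
        beta=float(s["coef"]),
        hr=float(np.exp(s["coef"])),
        se=float(s["se(coef)"]),
        p=float(s["p"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        converged=True,
    )
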