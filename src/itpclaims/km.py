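"""Kaplan-Meier time-to-withdrawal estimation and log-rank comparison.

Product-limit estimation and the log-rank test are delegated to
``lifelines``; this module owns the summary conventions: the median is
the smallest time with S(t) <= 0.5, its 95% CI comes from inverting the
fitter's (log-log Greenwood) confidence band, and the per-era analysis
reports both the all-initiator censored Kaplan-Meier median and the
descriptive median/IQR among patients with an observed withdrawal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times

from itpclaims.config import AnalysisConfig


@dataclass
class SurvivalFit:
    """Product-limit fit of one group."""

    group: str
    n: int
    n_events: int
    times: np.ndarray           # event/censor times on the curve
    at_risk: np.ndarray
    survival: np.ndarray
    median: float               # inf when not reached
    median_ci: tuple[float, float]

    def survival_at(self, t: float) -> float:
        """S(t) by step-function lookup."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def km_fit(times, events, group: str = "all") -> SurvivalFit:
    """Kaplan-Meier product-limit estimate with median and 95% CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("km_fit requires at least one subject")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=group)
    sf = kmf.survival_function_[group]
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = (float(ci.iloc[0, 0]), float(ci.iloc[0, 1]))
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy()
    return SurvivalFit(
        group=group, n=len(times), n_events=int(events.sum()),
        times=sf.index.to_numpy(dtype=float),
        at_risk=at_risk.astype(float),
        survival=sf.to_numpy(dtype=float),
        median=median, median_ci=(lo, hi))


def logrank(times_a, events_a, times_b, events_b
            ) -> tuple[float, float]:
    """One-degree-of-freedom log-rank statistic and p-value."""
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = logrank_test(times_a, times_b,
                       event_observed_A=events_a,
                       event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def withdrawal_analysis(withdrawal: pd.DataFrame, config: AnalysisConfig
                        ) -> tuple[dict, pd.DataFrame]:
    """Per-era Kaplan-Meier fits plus the between-era log-rank test.

    Input is the per-patient table from
    :func:`itpclaims.exposure.withdrawal_table` (columns ``time_days``,
    ``event``, ``era``).  Returns ``(summary, curves)`` where curves is
    a long table of the per-era survival steps.
    """
    summary: dict = {"eras": {}, "logrank": None}
    curve_rows = []
    fits: dict[str, SurvivalFit] = {}
    for era in config.era_years:
        sub = withdrawal[withdrawal["era"] == era]
        if sub.empty:
            summary["eras"][era] = {"n": 0, "warning": "no CS initiators"}
            continue
        fit = km_fit(sub["time_days"], sub["event"], group=era)
        fits[era] = fit
        events_only = sub.loc[sub["event"], "time_days"]
        summary["eras"][era] = {
            "n": fit.n,
            "n_events": fit.n_events,
            "km_median": fit.median,
            "km_median_ci": list(fit.median_ci),
            "survival_1m": fit.survival_at(30),
            "survival_3m": fit.survival_at(90),
            "event_only_median": float(events_only.median())
            if len(events_only) else None,
            "event_only_iqr": [float(events_only.quantile(0.25)),
                               float(events_only.quantile(0.75))]
            if len(events_only) else None,
        }
        for t, r, s in zip(fit.times, fit.at_risk, fit.survival):
            curve_rows.append({"group": era, "time": t, "at_risk": r,
                               "survival": s})
    if len(fits) == 2:
        (ea, fa), (eb, fb) = fits.items()
        a = withdrawal[withdrawal["era"] == ea]
        b = withdrawal[withdrawal["era"] == eb]
        chi2, p = logrank(a["time_days"], a["event"],
                          b["time_days"], b["event"])
        summary["logrank"] = {"groups": [ea, eb], "chi_square": chi2,
                              "p": p}
    curves = pd.DataFrame(curve_rows, columns=["group", "time", "at_risk",
                                               "survival"])
    return summary, curves
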