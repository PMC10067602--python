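"""Survival-model evaluation: Kaplan-Meier, log-rank, time-dependent AUC.

The time-dependent ROC uses the cumulative-case / dynamic-control definition
with inverse-probability-of-censoring weights (IPCW): at horizon t, cases are
samples with an observed event by t, controls are samples still under
observation past t, and both are reweighted by the Kaplan-Meier estimate of
the censoring distribution so the estimator is consistent under independent
censoring.  Tied risk scores contribute 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = ["KmCurve", "km_estimate", "logrank_test", "td_auc", "DAYS_PER_YEAR"]

DAYS_PER_YEAR = 365.25


@dataclass
class KmCurve:
    """Product-limit survival curve.

    ``times`` are the distinct event times in ascending order;
    ``survival`` the estimate just after each time (non-increasing, starting
    below 1 only at the first event); ``at_risk`` the risk-set size at each
    time (samples censored exactly at an event time count as at risk there).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t): right-continuous step-function lookup."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_survival(survival: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if len(survival) == 0:
        raise ValueError("empty survival table")
    time = survival["time"].to_numpy(float)
    event = survival["event"].to_numpy(int)
    if (time < 0).any():
        raise ValueError("negative survival times")
    return time, event


def km_estimate(survival: pd.DataFrame) -> KmCurve:
    """Kaplan-Meier product-limit estimator of the survival function."""
    time, event = _check_survival(survival)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    event_times = np.unique(time[event == 1])
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times])
    at_risk = np.array([(time >= t).sum() for t in event_times])
    return KmCurve(times=event_times, survival=surv, at_risk=at_risk)


def logrank_test(groups: dict[str, pd.DataFrame]) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, p-value).

    Reduces to the classical two-group form for k = 2; the statistic is
    referred to a chi-square distribution with k-1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    frames = []
    for name, df in groups.items():
        if len(df) == 0:
            raise ValueError(f"group {name!r} is empty")
        frames.append(pd.DataFrame({"time": df["time"], "event": df["event"], "group": name}))
    data = pd.concat(frames, ignore_index=True)
    res = multivariate_logrank_test(data["time"], data["group"], data["event"])
    return float(res.test_statistic), float(res.p_value)


def censoring_km(survival: pd.DataFrame) -> KmCurve:
    """KM estimate of the censoring distribution G (event indicator flipped)."""
    flipped = survival.copy()
    flipped["event"] = 1 - flipped["event"].astype(int)
    return km_estimate(flipped)


def td_auc(
    scores: pd.Series,
    survival: pd.DataFrame,
    horizons: tuple[float, ...] = (1.0, 3.0, 5.0),
    time_unit: str = "days",
) -> pd.Series:
    """IPCW cumulative/dynamic AUC of a risk score at the given horizons.

    Horizons are given in years and converted with 365.25 days/year when the
    survival times are in days (``time_unit="days"``); pass
    ``time_unit="years"`` (or ``"native"``) to use them as is.  A horizon with
    no observed case, no control, or beyond the last follow-up is reported as
    NaN (undefined), never defaulted to 0.5.
    """
    common = scores.index.intersection(survival.index)
    if len(common) == 0:
        raise ValueError("no shared samples between scores and survival")
    s = scores.loc[common].to_numpy(float)
    surv = survival.loc[common]
    time, event = _check_survival(surv)
    g = censoring_km(surv)

    factor = DAYS_PER_YEAR if time_unit == "days" else 1.0
    out = {}
    for h in horizons:
        t = h * factor
        cases = (time <= t) & (event == 1)
        controls = time > t
        g_t = g.at(t)
        if not cases.any() or not controls.any() or t >= time.max() or g_t <= 0:
            out[f"{h:g}y"] = np.nan
            continue
        # case weight 1/G(T_i-), control weight 1/G(t)
        w_case = np.array([1.0 / max(g.at(np.nextafter(ti, -np.inf)), 1e-12) for ti in time[cases]])
        w_ctrl = np.full(controls.sum(), 1.0 / g_t)
        sc, st = s[cases], s[controls]
        gt = (sc[:, None] > st[None, :]).astype(float)
        gt += 0.5 * (sc[:, None] == st[None, :])
        w = w_case[:, None] * w_ctrl[None, :]
        out[f"{h:g}y"] = float((w * gt).sum() / w.sum())
    return pd.Series(out, name="auc")
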