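"""Kaplan-Meier estimation and two-group log-rank comparison.

Overall survival of patients whose tumor lies in the reference region is
compared with those outside it. Estimation and testing are delegated to
lifelines (product-limit estimator; standard two-group log-rank with ties
handled jointly in the hypergeometric term); this module adapts them to the
per-sample record tables used across the package.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = ["SurvivalCurve", "km_estimate", "logrank_test", "plot_km"]


@dataclass
class SurvivalCurve:
    """A Kaplan-Meier step function: S(t) just after each distinct time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("empty survival record set")
    if not {"time_days", "event"}.issubset(records.columns):
        raise ValueError("records need columns time_days, event")
    if (records["time_days"] <= 0).any():
        raise ValueError("survival times must be positive")
    return records


def km_estimate(records: pd.DataFrame, label: str = "") -> SurvivalCurve:
    """Product-limit survival estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    ``records`` needs columns ``time_days`` and ``event`` (1 = death
    observed, 0 = censored). Censored subjects leave the risk set after
    their censoring time.
    """
    records = _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_days"], records["event"], label=label or None)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(sf.index).ffill().to_numpy(dtype=float)
    )
    keep = times > 0  # drop the t=0 anchor row lifelines prepends
    return SurvivalCurve(times[keep], surv[keep], at_risk[keep].astype(int), label)


def logrank_test(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    At each distinct event time the observed minus expected events in group
    a are accumulated under the hypergeometric variance;
    chi2 = (sum O - E)^2 / sum V on one degree of freedom.
    """
    a = _check_records(group_a)
    b = _check_records(group_b)
    if a["event"].sum() + b["event"].sum() == 0:
        raise ValueError("log-rank undefined: no events in either group")
    res = _ll_logrank(
        a["time_days"], b["time_days"], a["event"], b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def plot_km(
    curves: list[SurvivalCurve], path: str | Path, title: str = ""
) -> Path:
    """Write a simple Kaplan-Meier step plot to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for curve in curves:
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=curve.label or None)
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    if any(c.label for c in curves):
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
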