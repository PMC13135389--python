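"""Kaplan-Meier estimation and group comparison for 3-year overall survival.

Overall survival runs from diagnosis to death from any cause, with right
censoring at last follow-up and administrative censoring at a 36-month
horizon.  Estimation and testing stand on lifelines (product-limit curves,
k-group log-rank, Cox proportional hazards with the Efron tie correction
and a likelihood-ratio test against the null model).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .exceptions import FitError


@dataclass
class SurvivalRecord:
    """One sample's follow-up: time in months, event flag, group label."""

    sample_id: str
    time_months: float
    event: bool
    group: str = ""

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ValueError(
                f"negative time_months for sample {self.sample_id!r}"
            )


@dataclass
class KmCurve:
    """Product-limit curve: event times, survival steps, at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def administrative_censor(
    records: Sequence[SurvivalRecord], horizon_months: float = 36.0
) -> list[SurvivalRecord]:
    """Truncate follow-up beyond the horizon; truncated records are censored."""
    if horizon_months <= 0:
        raise ValueError("horizon_months must be positive")
    out = []
    for r in records:
        if r.time_months > horizon_months:
            out.append(replace(r, time_months=horizon_months, event=False))
        else:
            out.append(replace(r))
    return out


def km_estimate(records: Sequence[SurvivalRecord]) -> KmCurve:
    """Kaplan-Meier product-limit estimate over all records.

    Samples censored exactly at an event time are counted at risk at that
    time (the standard convention).
    """
    if not records:
        raise ValueError("km_estimate needs at least one record")
    times = np.array([r.time_months for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    fitter = KaplanMeierFitter()
    fitter.fit(times, events)
    event_table = fitter.event_table
    # keep rows where deaths occurred, plus time 0
    observed = event_table[event_table["observed"] > 0]
    out_times = np.concatenate(([0.0], observed.index.to_numpy(dtype=float)))
    surv = fitter.survival_function_at_times(out_times).to_numpy(dtype=float)
    at_risk = np.concatenate(
        ([len(records)], observed["at_risk"].to_numpy(dtype=int))
    )
    return KmCurve(times=out_times, survival=surv, at_risk=at_risk)


def logrank_test(records: Sequence[SurvivalRecord]) -> tuple[float, float, int]:
    """k-group log-rank test; returns (chi-square, p, dof=k-1)."""
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise ValueError(f"log-rank needs >= 2 groups, got {groups}")
    if not any(r.event for r in records):
        raise ValueError("log-rank needs at least one event")
    frame = pd.DataFrame(
        {
            "time": [r.time_months for r in records],
            "event": [int(r.event) for r in records],
            "group": [r.group for r in records],
        }
    )
    result = multivariate_logrank_test(frame["time"], frame["group"], frame["event"])
    return float(result.test_statistic), float(result.p_value), len(groups) - 1


def cox_lrt(
    records: Sequence[SurvivalRecord], ties: str = "efron"
) -> dict:
    """Cox fit with a categorical group covariate, scored by the LRT.

    Returns the likelihood-ratio statistic against the intercept-free null,
    its p-value (df = k−1), and per-group hazard ratios relative to the
    first group in sorted order.
    """
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise ValueError(f"Cox model needs >= 2 groups, got {groups}")
    frame = pd.DataFrame(
        {
            "time": [r.time_months for r in records],
            "event": [int(r.event) for r in records],
        }
    )
    for g in groups[1:]:  # first group is the reference
        frame[f"group_{g}"] = [int(r.group == g) for r in records]
    fitter = CoxPHFitter()
    try:
        fitter.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:  # convergence and degenerate-design failures
        raise FitError(f"Cox fit failed: {exc}") from exc
    lrt = fitter.log_likelihood_ratio_test()
    hazard_ratios = {
        g: float(np.exp(fitter.params_[f"group_{g}"])) for g in groups[1:]
    }
    hazard_ratios[groups[0]] = 1.0
    return {
        "statistic": float(lrt.test_statistic),
        "p_value": float(lrt.p_value),
        "dof": len(groups) - 1,
        "hazard_ratios": hazard_ratios,
        "reference_group": groups[0],
    }


def km_plot(records: Sequence[SurvivalRecord], path: str) -> None:
    """Optional KM plot, one curve per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for group in sorted({r.group for r in records}):
        sub = [r for r in records if r.group == group]
        fitter = KaplanMeierFitter()
        fitter.fit(
            [r.time_months for r in sub], [r.event for r in sub], label=group
        )
        fitter.plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def records_from_annotation(annotations, group_by: str = "egfr") -> list[SurvivalRecord]:
    """Build survival records from cohort annotations.

    ``group_by='egfr'`` labels EGFR-mt vs EGFR-WT; callers wanting the
    3-group mSig stratification attach group labels themselves.
    """
    out = []
    for a in annotations:
        group = "EGFR-mt" if a.egfr_mutant else "EGFR-WT"
        out.append(
            SurvivalRecord(
                sample_id=a.sample_id,
                time_months=a.survival_months,
                event=a.event,
                group=group,
            )
        )
    return out
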