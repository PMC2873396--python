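"""Risk grouping, Kaplan-Meier curves and the k-sample log-rank test.

Tumors fall into three prognostic groups: MYCN-amplified (worst
prognosis, takes precedence when both alterations are present),
12q24.31-gained (intermediate), and neither (best). Curve estimation
and testing are delegated to lifelines; ties between deaths and
censorings at the same time follow the standard events-first
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .config import InvalidParameterError

MYCN_AMP = "MYCN_AMP"
GAIN_12Q24 = "GAIN_12Q24"
NEITHER = "NEITHER"


class InvalidDataError(ValueError):
    """Survival data unusable for the requested analysis."""


@dataclass
class SurvivalRecord:
    patient_id: str
    time: float
    event: bool
    risk_group: Optional[str] = None


@dataclass
class KmCurve:
    """Product-limit curve evaluated at the distinct event times."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray


def assign_risk_group(gain: Optional[bool], myc_amplified: Optional[bool],
                      myc_dominates: bool = True) -> Optional[str]:
    """Three-level risk group; MYCN amplification dominates by default.

    Returns None (caller excludes and reports) when either flag is
    missing.
    """
    if gain is None or myc_amplified is None:
        return None
    if myc_amplified and (myc_dominates or not gain):
        return MYCN_AMP
    if gain:
        return GAIN_12Q24
    if myc_amplified:
        return MYCN_AMP
    return NEITHER


def km_estimate(records: Sequence[SurvivalRecord]) -> KmCurve:
    """Kaplan-Meier product-limit estimate at the distinct event times."""
    if not records:
        raise InvalidParameterError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    if (times <= 0).any() or not np.isfinite(times).all():
        raise InvalidParameterError("follow-up times must be finite and positive")
    kmf = KaplanMeierFitter().fit(times, events)
    event_times = np.unique(times[events])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    # n at risk just before each event time
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    return KmCurve(event_times=event_times, survival_probs=surv,
                   at_risk=at_risk)


def logrank_test(records: Sequence[SurvivalRecord]
                 ) -> tuple[float, int, float]:
    """k-sample log-rank test across risk groups.

    Returns (chi-square statistic, df = k-1, p). Requires at least two
    non-empty groups and at least one event.
    """
    recs = [r for r in records if r.risk_group is not None]
    groups = sorted({r.risk_group for r in recs})
    if len(groups) < 2:
        raise InvalidDataError("log-rank needs at least two non-empty groups")
    if not any(r.event for r in recs):
        raise InvalidDataError("log-rank needs at least one event")
    df = pd.DataFrame({
        "time": [r.time for r in recs],
        "event": [int(r.event) for r in recs],
        "group": [r.risk_group for r in recs],
    })
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def km_by_group(records: Sequence[SurvivalRecord]) -> dict[str, KmCurve]:
    """One KM curve per risk group."""
    out: dict[str, KmCurve] = {}
    for grp in sorted({r.risk_group for r in records if r.risk_group}):
        out[grp] = km_estimate([r for r in records if r.risk_group == grp])
    return out


def records_from_frame(df: pd.DataFrame) -> list[SurvivalRecord]:
    """Build records from a (patient_id, time, event[, risk_group]) frame."""
    has_group = "risk_group" in df.columns
    return [SurvivalRecord(str(r.patient_id), float(r.time), bool(r.event),
                           str(r.risk_group) if has_group else None)
            for r in df.itertuples(index=False)]
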