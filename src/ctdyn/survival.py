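"""Molecular response classification and survival contrasts.

A *ctDNA response* is a >= 50% drop in ctDNA concentration (hGE/mL) between
baseline and follow-up in the same compartment. Patients whose baseline
sample is ctDNA-negative are non-evaluable and excluded from response-group
contrasts; a follow-up that turns negative while baseline was positive is a
100% reduction and hence a response.

Survival machinery (Kaplan-Meier product-limit estimate, two-group log-rank
test, univariate proportional-hazards ratio) is delegated to lifelines and
exposed through thin, validated wrappers returning plain containers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .concordance import ContingencyTable
from .variants import Compartment, SampleProfile, Timepoint, ctdna_concentration

__all__ = [
    "RESPONSE_REDUCTION",
    "DEFAULT_RECIST_MAP",
    "ResponseCall",
    "SurvivalRecord",
    "Endpoint",
    "KMEstimate",
    "call_response",
    "response_vs_radiology",
    "km_fit",
    "logrank_test",
    "univariate_hr",
]

#: A responder shows at least this fractional reduction in ctDNA concentration.
RESPONSE_REDUCTION = 0.5

#: Binarization of RECIST categories into radiographic responder status.
DEFAULT_RECIST_MAP: Mapping[str, bool] = {"CR": True, "PR": True, "SD": False, "PD": False}

_TIMEPOINT_ORDER = {Timepoint.BASELINE: 0, Timepoint.WEEK8: 1, Timepoint.PROGRESSION: 2}


class Endpoint(str, enum.Enum):
    INTRACRANIAL_PFS = "icPFS"
    EXTRACRANIAL_PFS = "ecPFS"
    OS = "OS"


@dataclass(frozen=True)
class ResponseCall:
    patient_id: str
    compartment: str
    baseline_conc: float  # hGE/mL
    followup_conc: float  # hGE/mL
    pct_change: float | None  # percent; negative = decrease; None if non-evaluable
    responder: bool
    evaluable: bool


def call_response(
    baseline: SampleProfile,
    followup: SampleProfile,
    reduction: float = RESPONSE_REDUCTION,
) -> ResponseCall:
    """Classify molecular response from a baseline/follow-up concentration pair.

    The reduction threshold is inclusive: exactly 50% down is a response.
    Baseline-negative patients come back ``evaluable=False, responder=False``.
    """
    if baseline.patient_id != followup.patient_id:
        raise ValueError("response pairing requires the same patient")
    if baseline.compartment != followup.compartment:
        raise ValueError("response pairing requires the same compartment")
    if _TIMEPOINT_ORDER[baseline.timepoint] >= _TIMEPOINT_ORDER[followup.timepoint]:
        raise ValueError("baseline timepoint must precede the follow-up timepoint")
    base_conc = ctdna_concentration(baseline)
    post_conc = ctdna_concentration(followup)
    evaluable = base_conc > 0
    if evaluable:
        pct_change = 100.0 * (post_conc - base_conc) / base_conc
        responder = post_conc <= (1.0 - reduction) * base_conc
    else:
        pct_change = None
        responder = False
    return ResponseCall(
        patient_id=baseline.patient_id,
        compartment=baseline.compartment.value,
        baseline_conc=base_conc,
        followup_conc=post_conc,
        pct_change=pct_change,
        responder=responder,
        evaluable=evaluable,
    )


def response_vs_radiology(
    calls: Sequence[ResponseCall],
    labels: Mapping[str, str],
    recist_map: Mapping[str, bool] = DEFAULT_RECIST_MAP,
) -> ContingencyTable:
    """2x2 agreement of molecular vs radiographic response over evaluable patients.

    ``labels`` maps patient to a RECIST category; an unmapped category is a
    configuration error. Rows (A) are molecular calls, columns (B) radiographic.
    """
    counts = {"both_pos": 0, "a_only": 0, "b_only": 0, "both_neg": 0}
    for call in calls:
        if not call.evaluable:
            continue
        label = labels[call.patient_id]
        if label not in recist_map:
            raise KeyError(
                f"radiographic label {label!r} for {call.patient_id} has no "
                f"responder mapping (known: {sorted(recist_map)})"
            )
        radiographic = recist_map[label]
        if call.responder and radiographic:
            counts["both_pos"] += 1
        elif call.responder:
            counts["a_only"] += 1
        elif radiographic:
            counts["b_only"] += 1
        else:
            counts["both_neg"] += 1
    return ContingencyTable(**counts)


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    endpoint: Endpoint
    time_months: float
    event: bool
    group: str = ""

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError(
                f"time_months must be positive (patient {self.patient_id})"
            )


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate reported at the distinct event times."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    n_at_risk: tuple[int, ...]
    median: float | None


def _durations_events(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray([r.time_months for r in records], dtype=float)
    e = np.asarray([r.event for r in records], dtype=bool)
    return t, e


def km_fit(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Right-censored Kaplan-Meier estimate over the given records.

    The median is the smallest event time with survival <= 0.5, or None when
    the curve never reaches 0.5.
    """
    if not records:
        raise ValueError("km_fit requires at least one record")
    durations, events = _durations_events(records)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = tuple(float(t) for t in event_rows.index)
    surv = tuple(float(kmf.survival_function_.loc[t].iloc[0]) for t in event_rows.index)
    at_risk = tuple(int(n) for n in event_rows["at_risk"])
    median = None
    for t, s in zip(times, surv):
        if s <= 0.5:
            median = t
            break
    return KMEstimate(times=times, survival=surv, n_at_risk=at_risk, median=median)


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value.

    With no events in either group the contrast is vacuous: (0.0, 1.0).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _durations_events(group_a)
    tb, eb = _durations_events(group_b)
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def univariate_hr(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, tuple[float, float]]:
    """Hazard ratio of group A relative to group B with a Wald 95% CI.

    Fit is a single-covariate Cox proportional-hazards partial likelihood
    (group indicator = 1 for A). Raises when no events are observed.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _durations_events(group_a)
    tb, eb = _durations_events(group_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("hazard ratio undefined with zero events")
    df = pd.DataFrame(
        {
            "time": np.concatenate([ta, tb]),
            "event": np.concatenate([ea, eb]).astype(int),
            "group": np.concatenate([np.ones_like(ta), np.zeros_like(tb)]),
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(math.exp(cph.params_["group"]))
    lo, hi = cph.confidence_intervals_.loc["group"]
    return hr, (float(math.exp(lo)), float(math.exp(hi)))
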