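"""Native Kaplan–Meier estimation and Mantel–Cox log-rank comparison.

The product-limit estimator handles right censoring with the standard
tie convention (deaths precede censorings at the same time, so a
patient censored at t is still at risk for deaths at t). The log-rank
test is the Mantel–Cox form: at each distinct event time the expected
event count per group comes from the hypergeometric mean, the variance
from the hypergeometric variance, and the chi-square statistic (1 df)
is (O − E)² / ΣV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .io_model import SurvivalRecord

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "km_median",
    "survival_at",
    "logrank_test",
    "stratify_by_gene",
]

logger = logging.getLogger(__name__)

# Cumulative float products drift below exact rationals (12/24 computed
# as a running product is 0.4999999999999999); the median rule S <= 0.5
# therefore uses a small absolute tolerance.
_S_TOL = 1e-9


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve over the distinct event times."""

    event_times: np.ndarray  # distinct times with >=1 death, ascending
    n_at_risk: np.ndarray  # risk-set size just before each event time
    n_events: np.ndarray  # deaths at each event time
    survival: np.ndarray  # S(t) just after each event time
    censor_times: np.ndarray  # all censoring times (for plotting marks)
    n_total: int


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan–Meier product-limit estimate from survival records."""
    if not records:
        raise ValueError("km_estimate requires at least one record")
    times = np.array([r.os_months for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    event_times = []
    n_at_risk = []
    n_events = []
    survival = []
    s = 1.0
    n = len(times)
    i = 0
    at_risk = n
    while i < n:
        t = times[i]
        j = i
        deaths = censored = 0
        while j < n and times[j] == t:
            if events[j]:
                deaths += 1
            else:
                censored += 1
            j += 1
        if deaths > 0:
            s *= 1.0 - deaths / at_risk
            event_times.append(t)
            n_at_risk.append(at_risk)
            n_events.append(deaths)
            survival.append(s)
        at_risk -= deaths + censored
        i = j
    return KMCurve(
        event_times=np.array(event_times),
        n_at_risk=np.array(n_at_risk, dtype=int),
        n_events=np.array(n_events, dtype=int),
        survival=np.array(survival),
        censor_times=np.sort(np.array([r.os_months for r in records if not r.event])),
        n_total=n,
    )


def survival_at(curve: KMCurve, t_months: float) -> float:
    """S(t) with right-continuity: the step value at the last event ≤ t."""
    if t_months < 0:
        raise ValueError("t_months must be nonnegative")
    idx = np.searchsorted(curve.event_times, t_months, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def km_median(curve: KMCurve) -> Optional[float]:
    """Median survival: smallest event time t with S(t) ≤ 0.5.

    Returns None when the curve never reaches 0.5 (median undefined).
    When the curve sits exactly on a 0.5 plateau, the plateau start is
    returned (the first time the rule's condition holds).
    """
    below = np.nonzero(curve.survival <= 0.5 + _S_TOL)[0]
    if below.size == 0:
        return None
    return float(curve.event_times[below[0]])


@dataclass(frozen=True)
class LogRankResult:
    """Mantel–Cox log-rank comparison of two survival curves."""

    observed: tuple[float, float]
    expected: tuple[float, float]
    variance: float
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogRankResult:
    """Two-sample Mantel–Cox log-rank test (chi-square, 1 df)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    times = np.array([r.os_months for r in group_a] + [r.os_months for r in group_b])
    events = np.array([r.event for r in group_a] + [r.event for r in group_b])
    labels = np.array([0] * len(group_a) + [1] * len(group_b))
    if not events.any():
        raise ValueError("no events in either group; log-rank undefined")

    o_a = e_a = var = 0.0
    total_events = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (labels == 0)).sum()
        dying = events & (times == t)
        d = dying.sum()
        d_a = (dying & (labels == 0)).sum()
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            n_b = n - n_a
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
        total_events += d
    o_b = total_events - o_a
    e_b = total_events - e_a
    if var == 0.0:
        statistic, p = 0.0, 1.0
    else:
        statistic = (o_a - e_a) ** 2 / var
        p = float(sps.chi2.sf(statistic, df=1))
    return LogRankResult(
        observed=(float(o_a), float(o_b)),
        expected=(float(e_a), float(e_b)),
        variance=float(var),
        statistic=float(statistic),
        p_value=p,
    )


def stratify_by_gene(
    mutated_samples_by_gene: Mapping[str, Iterable[str]],
    clinical: Sequence[SurvivalRecord],
    gene: str,
) -> tuple[list[SurvivalRecord], list[SurvivalRecord]]:
    """Partition clinical records by mutation status for one gene.

    ``mutated_samples_by_gene`` maps each gene to the patients carrying
    at least one retained nonsynonymous variant in it (sample ids double
    as patient ids). Patients appearing in the calls but lacking a
    clinical record are excluded from both groups and logged.
    """
    if gene not in mutated_samples_by_gene:
        raise KeyError(
            f"gene {gene!r} not present in the retained-call gene set"
        )
    mutated_ids = set(mutated_samples_by_gene[gene])
    clinical_ids = {r.patient_id for r in clinical}
    missing = mutated_ids - clinical_ids
    if missing:
        logger.info(
            "%d mutated patients lack clinical records and are excluded: %s",
            len(missing),
            sorted(missing),
        )
    mutated = [
        SurvivalRecord(r.patient_id, r.os_months, r.event, group="mutated")
        for r in clinical
        if r.patient_id in mutated_ids
    ]
    wildtype = [
        SurvivalRecord(r.patient_id, r.os_months, r.event, group="wild_type")
        for r in clinical
        if r.patient_id not in mutated_ids
    ]
    return mutated, wildtype
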