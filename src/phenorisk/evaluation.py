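"""Day-level alarm evaluation against risk events.

Alarms are scored per patient-day, pooled over the cohort: an alarm on
day ``d`` is a true positive iff the patient's (first) risk event falls
in the forward window ``(d, d + horizon]``; an alarm with no event in
window is a false positive; a silent day with an event in window is a
false negative; everything else is a true negative.  Monitoring is
truncated at the first event, and burn-in days are excluded.

The ROC sweeps a fixed grid of stability thresholds equally spaced
inside (0, 1) and reports the trapezoidal AUC of the pooled curve
anchored at (0,0) and (1,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .detection import DEFAULT_BURN_IN, AlarmSeries, detect_alarms

__all__ = [
    "EVENT_TYPES",
    "RiskEvent",
    "ConfusionCounts",
    "RocResult",
    "DegenerateCohortError",
    "threshold_grid",
    "label_days",
    "roc_curve",
    "cohort_summary",
]

EVENT_TYPES = ("suicide_attempt", "ed_visit")


class DegenerateCohortError(ValueError):
    """ROC is undefined: the cohort lacks a positive or negative class."""


@dataclass(frozen=True)
class RiskEvent:
    patient_id: str
    day: int
    type: str

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}; expected one of {EVENT_TYPES}")
        if self.day < 0:
            raise ValueError("event day must be >= 0")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def tpr(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def fpr(self) -> float:
        neg = self.fp + self.tn
        return self.fp / neg if neg else float("nan")


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    counts: list = field(default_factory=list)

    def to_records(self):
        return [
            {"threshold": float(t), "fpr": float(f), "tpr": float(s)}
            for t, f, s in zip(self.thresholds, self.fpr, self.tpr)
        ]


def threshold_grid(n_thresholds: int = 50) -> np.ndarray:
    """``n`` equally spaced interior points of (0, 1): k/(n+1), k=1..n."""
    if n_thresholds < 1:
        raise ValueError("n_thresholds must be >= 1")
    return np.arange(1, n_thresholds + 1) / (n_thresholds + 1)


def label_days(alarms: AlarmSeries, event: RiskEvent | None,
               horizon: int = 7) -> ConfusionCounts:
    """Confusion counts for one patient at one threshold.

    Evaluated days run from burn-in to the day before the first event
    (or the end of monitoring if event-free).  A day ``d`` is positive
    iff the event day lies in ``(d, d + horizon]``.  Patients whose
    event precedes the end of burn-in have no evaluable days and are
    excluded with a warning.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    last = alarms.n_days - 1
    if event is not None:
        if event.day <= alarms.burn_in:
            warnings.warn(
                f"patient {event.patient_id}: event on day {event.day} is within "
                f"burn-in ({alarms.burn_in} days); patient excluded from evaluation",
                stacklevel=2)
            return ConfusionCounts()
        last = min(last, event.day - 1)
    counts = ConfusionCounts()
    for d in range(alarms.burn_in, last + 1):
        positive = event is not None and d < event.day <= d + horizon
        alarmed = bool(alarms.alarm[d])
        if alarmed and positive:
            counts.tp += 1
        elif alarmed:
            counts.fp += 1
        elif positive:
            counts.fn += 1
        else:
            counts.tn += 1
    return counts


def _first_events(events: Iterable[RiskEvent]) -> dict[str, RiskEvent]:
    first: dict[str, RiskEvent] = {}
    for ev in events:
        cur = first.get(ev.patient_id)
        if cur is None or ev.day < cur.day:
            first[ev.patient_id] = ev
    return first


def roc_curve(series_by_patient: Mapping[str, np.ndarray],
              events: Iterable[RiskEvent],
              n_thresholds: int = 50, horizon: int = 7,
              burn_in: int = DEFAULT_BURN_IN) -> RocResult:
    """Pooled day-level ROC over the stability-threshold grid.

    ``series_by_patient`` maps patient id to that patient's change-
    probability series.  All patient-days are pooled at each threshold;
    the curve is anchored at (0,0) and (1,1) and integrated by the
    trapezoidal rule.
    """
    first = _first_events(events)
    has_pos = any(pid in first and first[pid].day > burn_in for pid in series_by_patient)
    has_neg = any(pid not in first for pid in series_by_patient)
    if not has_pos:
        raise DegenerateCohortError("no patient with an evaluable risk event (positive class missing)")
    if not has_neg:
        raise DegenerateCohortError("no event-free patient (negative class missing)")

    taus = threshold_grid(n_thresholds)
    fprs, tprs, all_counts = [], [], []
    for tau in taus:
        pooled = ConfusionCounts()
        for pid, series in series_by_patient.items():
            alarms = detect_alarms(series, tau, burn_in=burn_in)
            pooled = pooled + label_days(alarms, first.get(pid), horizon=horizon)
        fprs.append(pooled.fpr)
        tprs.append(pooled.tpr)
        all_counts.append(pooled)

    fpr = np.asarray(fprs)
    tpr = np.asarray(tprs)
    order = np.lexsort((tpr, fpr))
    fx = np.concatenate([[0.0], fpr[order], [1.0]])
    fy = np.concatenate([[0.0], tpr[order], [1.0]])
    auc = float(np.trapezoid(fy, fx))
    return RocResult(thresholds=taus, fpr=fpr, tpr=tpr, auc=auc, counts=all_counts)


def cohort_summary(events: Iterable[RiskEvent], n_patients: int) -> dict:
    """Cohort event proportions (percent, rounded to one decimal).

    Only each patient's first event counts; ``any_event`` is the union
    of the two event types.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    first = _first_events(events)
    n_attempt = sum(1 for ev in first.values() if ev.type == "suicide_attempt")
    n_ed = sum(1 for ev in first.values() if ev.type == "ed_visit")
    n_any = len(first)

    def pct(k: int) -> float:
        return round(100.0 * k / n_patients, 1)

    return {
        "n_patients": int(n_patients),
        "n_suicide_attempt": n_attempt,
        "n_ed_visit": n_ed,
        "n_any_event": n_any,
        "suicide_attempt_pct": pct(n_attempt),
        "ed_visit_pct": pct(n_ed),
        "any_event_pct": pct(n_any),
    }
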