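"""Real-world survival endpoints derived from therapy-line timelines.

Two endpoints are supported, both anchored at the start of a therapy
line (typically first-line):

* overall survival (OS): time to death, censored at last follow-up;
* real-world progression-free survival (rwPFS): time to the earliest
  progression / new-metastasis / death event occurring at least 14 days
  after the line start and strictly before the line end (or, when the
  end date is unknown, before the next line's start); otherwise censored
  at that upper bound.

The 14-day blanking window guards against baseline disease assessments
recorded shortly after treatment start being counted as progression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from lifelines import KaplanMeierFitter

from .clinical import PatientRecord, ProgressionEvent, TherapyLine

RWPFS_MIN_EVENT_DAYS = 14


class TimelineError(ValueError):
    """Raised for internally inconsistent patient timelines."""


@dataclass(frozen=True)
class SurvivalOutcome:
    patient_id: str
    endpoint: str  # "os" | "rwpfs"
    time_days: int
    event: bool
    anchor_line: int

    def __post_init__(self):
        if self.time_days < 0:
            raise TimelineError(
                f"{self.patient_id}: negative {self.endpoint} time {self.time_days}"
            )


def derive_os(patient: PatientRecord, line: TherapyLine) -> SurvivalOutcome:
    """OS from the line start: death if recorded, else censored at last follow-up."""
    if patient.death_day is not None:
        if patient.death_day < line.start_day:
            raise TimelineError(
                f"{patient.patient_id}: death day {patient.death_day} precedes "
                f"line start {line.start_day}"
            )
        return SurvivalOutcome(
            patient.patient_id, "os", patient.death_day - line.start_day, True,
            line.line_number,
        )
    if patient.last_followup_day < line.start_day:
        raise TimelineError(
            f"{patient.patient_id}: last follow-up {patient.last_followup_day} "
            f"precedes line start {line.start_day}"
        )
    return SurvivalOutcome(
        patient.patient_id, "os", patient.last_followup_day - line.start_day, False,
        line.line_number,
    )


def derive_rwpfs(
    patient: PatientRecord,
    line: TherapyLine,
    next_line: Optional[TherapyLine],
    events: Iterable[ProgressionEvent],
) -> SurvivalOutcome:
    """rwPFS from the line start.

    The event window is ``[start + 14, U)`` where ``U`` is the line end
    day when recorded, else the next line's start day.  The earliest
    qualifying progression/metastasis/death event in the window counts
    as an event; otherwise the outcome is censored at ``U``.  A recorded
    death day qualifies whether or not it also appears in the event
    table.  With neither an end day nor a next line, censoring falls
    back to the last follow-up day.
    """
    start = line.start_day
    if line.end_day is not None:
        upper = line.end_day
    elif next_line is not None:
        upper = next_line.start_day
    else:
        upper = patient.last_followup_day
        if upper is None:
            raise TimelineError(
                f"{patient.patient_id}: no end date, next line, or follow-up "
                "to bound rwPFS"
            )
    if upper < start:
        raise TimelineError(
            f"{patient.patient_id}: rwPFS upper bound {upper} precedes start {start}"
        )

    days = [e.day for e in events if e.patient_id == patient.patient_id]
    if patient.death_day is not None:
        days.append(patient.death_day)
    qualifying = [d for d in days if d >= start + RWPFS_MIN_EVENT_DAYS and d < upper]
    if qualifying:
        return SurvivalOutcome(
            patient.patient_id, "rwpfs", min(qualifying) - start, True,
            line.line_number,
        )
    return SurvivalOutcome(
        patient.patient_id, "rwpfs", upper - start, False, line.line_number
    )


@dataclass
class KMEstimate:
    """Product-limit survival estimate: S(t) right-continuous step function."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each time
    median: Optional[float]    # smallest t with S(t) <= 0.5, None if never reached

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(outcomes: Iterable[SurvivalOutcome]) -> KMEstimate:
    """Kaplan–Meier estimate with median survival.

    The median is the smallest observed time at which the estimated
    survival drops to 0.5 or below; ``None`` when never reached.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("km_estimate requires at least one outcome")
    t = np.array([o.time_days for o in outcomes], dtype=float)
    e = np.array([o.event for o in outcomes], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    # drop the t=0 anchor row unless an event/censor actually occurred at 0
    if times.size and times[0] == 0.0 and not np.any(t == 0):
        times, surv = times[1:], surv[1:]
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMEstimate(times=times, survival=surv, median=median)
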