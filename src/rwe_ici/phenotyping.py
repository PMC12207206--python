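"""Rule-based resistance phenotyping of post-ICI biopsies.

A biopsy is first anchored to the end of an immune-checkpoint-inhibitor
(ICI or ICI+chemo) treatment line:

* with a recorded end date, end-of-treatment (EOT) means collection
  within ±30 days of the end (closed interval);
* without one, EOT means collection at least 60 days after the line
  start.

EOT samples are resistant when the next therapy line starts within 90
days of the treatment end, or a progressive-disease event (progression,
new metastasis, or death) is recorded within 90 days of the sample
collection date.  Note the two clocks intentionally differ — the
next-line clause runs from the treatment end, the event clause from the
biopsy collection day.

Resistant samples split into primary resistance (ICI duration < 180
days) and acquired resistance (duration >= 180 days).  All "within N
days" windows are closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .clinical import BiopsySample, ProgressionEvent, TherapyLine

LABELS = ("not_eot", "eot_nonresistant", "primary", "acquired", "unclassifiable")


@dataclass(frozen=True)
class PhenotypeConfig:
    eot_window_days: int = 30
    missing_end_min_days: int = 60
    resistance_window_days: int = 90
    acquired_min_duration_days: int = 180

    def __post_init__(self):
        for f in (
            self.eot_window_days, self.missing_end_min_days,
            self.resistance_window_days, self.acquired_min_duration_days,
        ):
            if f <= 0:
                raise ValueError("phenotype window constants must be positive")


@dataclass(frozen=True)
class ResistanceLabel:
    sample_id: str
    label: str
    supporting_rule: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"invalid resistance label {self.label!r}")


def classify_eot(
    sample: BiopsySample, ici_line: TherapyLine, cfg: PhenotypeConfig = PhenotypeConfig()
) -> bool:
    """Is the biopsy an end-of-treatment sample for this ICI line?"""
    if sample.patient_id != ici_line.patient_id:
        raise ValueError(
            f"sample {sample.sample_id} and line belong to different patients"
        )
    if ici_line.end_day is not None:
        return abs(sample.collection_day - ici_line.end_day) <= cfg.eot_window_days
    return sample.collection_day - ici_line.start_day >= cfg.missing_end_min_days


def classify_resistance(
    sample: BiopsySample,
    ici_line: TherapyLine,
    next_line: Optional[TherapyLine],
    events: Iterable[ProgressionEvent],
    cfg: PhenotypeConfig = PhenotypeConfig(),
) -> bool:
    """Is an EOT sample resistant?

    Either the next line starts within the resistance window of the
    treatment end (requires a recorded end day), or a progressive-disease
    event falls within the window after the collection day.
    """
    if (
        next_line is not None
        and ici_line.end_day is not None
        and 0 <= next_line.start_day - ici_line.end_day <= cfg.resistance_window_days
    ):
        return True
    for ev in events:
        if ev.patient_id != sample.patient_id:
            continue
        if 0 <= ev.day - sample.collection_day <= cfg.resistance_window_days:
            return True
    return False


def classify_primary_acquired(
    ici_line: TherapyLine, cfg: PhenotypeConfig = PhenotypeConfig()
) -> str:
    """Split a resistant sample by ICI treatment duration."""
    if ici_line.end_day is None:
        return "unclassifiable"
    duration = ici_line.end_day - ici_line.start_day
    return "acquired" if duration >= cfg.acquired_min_duration_days else "primary"


def link_sample_to_ici_line(
    sample: BiopsySample,
    lines: Iterable[TherapyLine],
    cfg: PhenotypeConfig = PhenotypeConfig(),
) -> Optional[TherapyLine]:
    """Most recent ICI line starting on or before collection + EOT window."""
    candidates = [
        ln for ln in lines
        if ln.patient_id == sample.patient_id
        and ln.is_ici
        and ln.start_day <= sample.collection_day + cfg.eot_window_days
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda ln: (ln.start_day, ln.line_number))


def _next_line(
    ici_line: TherapyLine, lines: Iterable[TherapyLine]
) -> Optional[TherapyLine]:
    later = [
        ln for ln in lines
        if ln.patient_id == ici_line.patient_id
        and ln.line_number > ici_line.line_number
    ]
    if not later:
        return None
    return min(later, key=lambda ln: ln.line_number)


def phenotype_cohort(
    samples: Iterable[BiopsySample],
    lines: Iterable[TherapyLine],
    events: Iterable[ProgressionEvent],
    cfg: PhenotypeConfig = PhenotypeConfig(),
) -> tuple[list, dict]:
    """Label every biopsy and report the filter cascade.

    The cascade report counts samples at each stage: all samples, EOT
    samples, resistance-evaluable samples (EOT with a recorded treatment
    end day, so the primary/acquired split is well defined), resistant
    samples, and the primary/acquired split.  Labels are deterministic
    and invariant to input row order.
    """
    samples = sorted(samples, key=lambda s: s.sample_id)
    lines = list(lines)
    events = list(events)
    by_patient_lines: dict = {}
    for ln in lines:
        by_patient_lines.setdefault(ln.patient_id, []).append(ln)
    by_patient_events: dict = {}
    for ev in events:
        by_patient_events.setdefault(ev.patient_id, []).append(ev)

    labels = []
    cascade = {
        "all": len(samples), "eot": 0, "resistance_evaluable": 0,
        "resistant": 0, "primary": 0, "acquired": 0, "unclassifiable": 0,
    }
    for s in samples:
        plines = by_patient_lines.get(s.patient_id, [])
        pevents = by_patient_events.get(s.patient_id, [])
        ici = link_sample_to_ici_line(s, plines, cfg)
        if ici is None:
            labels.append(ResistanceLabel(s.sample_id, "not_eot", "no linkable ICI line"))
            continue
        if not classify_eot(s, ici, cfg):
            labels.append(ResistanceLabel(s.sample_id, "not_eot", "outside EOT window"))
            continue
        cascade["eot"] += 1
        if ici.end_day is not None:
            cascade["resistance_evaluable"] += 1
        nxt = _next_line(ici, plines)
        if not classify_resistance(s, ici, nxt, pevents, cfg):
            labels.append(
                ResistanceLabel(s.sample_id, "eot_nonresistant", "no resistance signal")
            )
            continue
        cascade["resistant"] += 1
        split = classify_primary_acquired(ici, cfg)
        cascade[split] += 1
        rule = (
            "missing treatment end day" if split == "unclassifiable"
            else f"ICI duration {ici.end_day - ici.start_day}d"
        )
        labels.append(ResistanceLabel(s.sample_id, split, rule))
    return labels, cascade
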