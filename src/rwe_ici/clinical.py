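"""Clinical domain records, delimited-table IO, and cohort filters.

Timelines are represented as integer days from a configurable epoch
(default 2015-01-01).  Files on disk carry ISO-8601 dates; the readers
convert to days and the writers convert back, so a write/read cycle is
the identity on valid tables.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

DEFAULT_EPOCH = "2015-01-01"

STAGES = frozenset({"III", "IV"})
HISTOLOGIES = frozenset({"nonsquamous", "squamous"})
PDL1_CLASSES = frozenset({"lt1", "r1_49", "ge50"})
REGIMEN_CLASSES = frozenset({"ici", "ici_chemo", "platinum_chemo", "other"})
ICI_REGIMENS = frozenset({"ici", "ici_chemo"})
EVENT_TYPES = frozenset({"progression", "metastasis", "death"})
TISSUE_SITES = frozenset({"lung", "lymph_node", "liver", "other"})
VARIANT_CLASSES = frozenset({"snv_indel", "cnv", "fusion"})
PATHOGENICITIES = frozenset(
    {"pathogenic", "likely_pathogenic", "vus", "benign", "likely_benign"}
)
PATHOGENIC = frozenset({"pathogenic", "likely_pathogenic"})


class ClinicalDataError(ValueError):
    """Raised for structurally invalid clinical inputs."""


def iso_to_day(date: str, epoch: str = DEFAULT_EPOCH) -> int:
    """Convert an ISO-8601 date string to integer days from ``epoch``."""
    d = datetime.date.fromisoformat(str(date))
    e = datetime.date.fromisoformat(epoch)
    return (d - e).days


def day_to_iso(day: int, epoch: str = DEFAULT_EPOCH) -> str:
    e = datetime.date.fromisoformat(epoch)
    return (e + datetime.timedelta(days=int(day))).isoformat()


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    stage: str
    histology: str
    diagnosis_year: int
    age_known: bool
    pdl1_ihc_class: Optional[str] = None
    kras_mut: bool = False
    death_day: Optional[int] = None
    last_followup_day: int = 0

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ClinicalDataError(f"invalid stage {self.stage!r}")
        if self.histology not in HISTOLOGIES:
            raise ClinicalDataError(f"invalid histology {self.histology!r}")
        if self.pdl1_ihc_class is not None and self.pdl1_ihc_class not in PDL1_CLASSES:
            raise ClinicalDataError(f"invalid PD-L1 class {self.pdl1_ihc_class!r}")


@dataclass(frozen=True)
class TherapyLine:
    patient_id: str
    line_number: int
    regimen_class: str
    start_day: int
    end_day: Optional[int] = None

    def __post_init__(self):
        if self.regimen_class not in REGIMEN_CLASSES:
            raise ClinicalDataError(f"invalid regimen class {self.regimen_class!r}")
        if self.line_number < 1:
            raise ClinicalDataError("line_number must be positive")
        if self.end_day is not None and self.end_day < self.start_day:
            raise ClinicalDataError(
                f"therapy line for {self.patient_id}: end_day {self.end_day} "
                f"< start_day {self.start_day}"
            )

    @property
    def is_ici(self) -> bool:
        return self.regimen_class in ICI_REGIMENS


@dataclass(frozen=True)
class ProgressionEvent:
    patient_id: str
    day: int
    event_type: str

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ClinicalDataError(f"invalid event type {self.event_type!r}")


@dataclass(frozen=True)
class BiopsySample:
    sample_id: str
    patient_id: str
    collection_day: int
    tissue_site: str = "other"
    pdl1_ihc_class: Optional[str] = None
    expression_column: Optional[str] = None

    def __post_init__(self):
        if self.tissue_site not in TISSUE_SITES:
            raise ClinicalDataError(f"invalid tissue site {self.tissue_site!r}")
        if self.pdl1_ihc_class is not None and self.pdl1_ihc_class not in PDL1_CLASSES:
            raise ClinicalDataError(f"invalid PD-L1 class {self.pdl1_ihc_class!r}")


@dataclass(frozen=True)
class VariantCall:
    patient_id: str
    gene: str
    variant_class: str
    pathogenicity: Optional[str] = None

    def __post_init__(self):
        if self.variant_class not in VARIANT_CLASSES:
            raise ClinicalDataError(f"invalid variant class {self.variant_class!r}")
        if self.variant_class == "snv_indel" and self.pathogenicity is None:
            raise ClinicalDataError("snv_indel variants require a pathogenicity call")


@dataclass(frozen=True)
class CohortConfig:
    """Inclusion/exclusion rules for cohort derivation.

    Patients are kept when they were diagnosed in ``min_diagnosis_year``
    or later, have an allowed stage and histology, a known age, and carry
    no actionable alteration in ``excluded_driver_genes`` (pathogenic or
    likely-pathogenic short variants, or copy-number events) nor a fusion
    involving one of ``excluded_fusion_genes``.
    """

    min_diagnosis_year: int = 2016
    allowed_stages: frozenset = frozenset({"III", "IV"})
    allowed_histology: frozenset = frozenset({"nonsquamous"})
    excluded_driver_genes: tuple = ("EGFR", "BRAF", "MET")
    excluded_fusion_genes: tuple = ("ALK", "ROS1", "NTRK1", "NTRK2")

    def __post_init__(self):
        if not self.excluded_driver_genes or not self.excluded_fusion_genes:
            raise ClinicalDataError("exclusion gene lists must be non-empty")


@dataclass
class ParseIssue:
    table: str
    row: int
    reason: str


@dataclass
class ParseReport:
    n_read: dict = field(default_factory=dict)
    n_kept: dict = field(default_factory=dict)
    dropped: list = field(default_factory=list)

    def add_drop(self, table: str, row: int, reason: str) -> None:
        self.dropped.append(ParseIssue(table, row, reason))


@dataclass
class ClinicalTables:
    patients: list
    lines: list
    events: list
    biopsies: list
    variants: list = field(default_factory=list)

    def patient_index(self) -> dict:
        return {p.patient_id: p for p in self.patients}

    def lines_by_patient(self) -> dict:
        out: dict = {}
        for ln in sorted(self.lines, key=lambda x: (x.patient_id, x.start_day)):
            out.setdefault(ln.patient_id, []).append(ln)
        return out

    def events_by_patient(self) -> dict:
        out: dict = {}
        for ev in sorted(self.events, key=lambda x: (x.patient_id, x.day)):
            out.setdefault(ev.patient_id, []).append(ev)
        return out


# ---------------------------------------------------------------------------
# Table IO

_PATIENT_COLS = [
    "patient_id", "stage", "histology", "diagnosis_year", "age_known",
    "pdl1_ihc_class", "kras_mut", "death_date", "last_followup_date",
]
_LINE_COLS = ["patient_id", "line_number", "regimen_class", "start_date", "end_date"]
_EVENT_COLS = ["patient_id", "event_date", "event_type"]
_BIOPSY_COLS = [
    "sample_id", "patient_id", "collection_date", "tissue_site",
    "pdl1_ihc_class", "expression_column",
]
_VARIANT_COLS = ["patient_id", "gene", "variant_class", "pathogenicity"]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ClinicalDataError(f"{table}: missing mandatory column(s) {missing}")


def _opt(value):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return value


def _bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"true", "1", "yes"}


def _parse_date(value, epoch: str) -> Optional[int]:
    value = _opt(value)
    if value is None:
        return None
    return iso_to_day(value, epoch)


def read_clinical_tables(
    paths: Mapping[str, str | Path], epoch: str = DEFAULT_EPOCH
) -> tuple[ClinicalTables, ParseReport]:
    """Read the clinical CSV file set into typed records.

    ``paths`` maps table names (``patients``, ``therapy_lines``,
    ``progression_events``, ``biopsies``, and optionally ``variants``)
    to file paths.  Rows violating an invariant (e.g. a therapy line
    ending before it starts, an unparseable date) are dropped and
    reported; a missing mandatory column is a hard error.
    """
    report = ParseReport()

    def load(name, cols):
        df = pd.read_csv(paths[name], dtype=str, keep_default_na=False)
        _require_columns(df, cols, name)
        report.n_read[name] = len(df)
        return df

    patients, lines, events, biopsies, variants = [], [], [], [], []

    df = load("patients", _PATIENT_COLS)
    for i, row in df.iterrows():
        try:
            patients.append(PatientRecord(
                patient_id=row["patient_id"],
                stage=row["stage"],
                histology=row["histology"],
                diagnosis_year=int(row["diagnosis_year"]),
                age_known=_bool(row["age_known"]),
                pdl1_ihc_class=_opt(row["pdl1_ihc_class"]),
                kras_mut=_bool(row["kras_mut"]),
                death_day=_parse_date(row["death_date"], epoch),
                last_followup_day=_parse_date(row["last_followup_date"], epoch),
            ))
        except (ClinicalDataError, ValueError) as exc:
            report.add_drop("patients", int(i), str(exc))
    report.n_kept["patients"] = len(patients)

    df = load("therapy_lines", _LINE_COLS)
    for i, row in df.iterrows():
        try:
            lines.append(TherapyLine(
                patient_id=row["patient_id"],
                line_number=int(row["line_number"]),
                regimen_class=row["regimen_class"],
                start_day=_parse_date(row["start_date"], epoch),
                end_day=_parse_date(row["end_date"], epoch),
            ))
        except (ClinicalDataError, ValueError, TypeError) as exc:
            report.add_drop("therapy_lines", int(i), str(exc))
    report.n_kept["therapy_lines"] = len(lines)

    df = load("progression_events", _EVENT_COLS)
    for i, row in df.iterrows():
        try:
            events.append(ProgressionEvent(
                patient_id=row["patient_id"],
                day=_parse_date(row["event_date"], epoch),
                event_type=row["event_type"],
            ))
        except (ClinicalDataError, ValueError, TypeError) as exc:
            report.add_drop("progression_events", int(i), str(exc))
    report.n_kept["progression_events"] = len(events)

    df = load("biopsies", _BIOPSY_COLS)
    seen_samples = set()
    for i, row in df.iterrows():
        try:
            rec = BiopsySample(
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                collection_day=_parse_date(row["collection_date"], epoch),
                tissue_site=row["tissue_site"],
                pdl1_ihc_class=_opt(row["pdl1_ihc_class"]),
                expression_column=_opt(row["expression_column"]),
            )
            if rec.sample_id in seen_samples:
                raise ClinicalDataError(f"duplicate sample_id {rec.sample_id!r}")
            seen_samples.add(rec.sample_id)
            biopsies.append(rec)
        except (ClinicalDataError, ValueError, TypeError) as exc:
            report.add_drop("biopsies", int(i), str(exc))
    report.n_kept["biopsies"] = len(biopsies)

    if "variants" in paths:
        df = load("variants", _VARIANT_COLS)
        for i, row in df.iterrows():
            try:
                variants.append(VariantCall(
                    patient_id=row["patient_id"],
                    gene=row["gene"],
                    variant_class=row["variant_class"],
                    pathogenicity=_opt(row["pathogenicity"]),
                ))
            except (ClinicalDataError, ValueError) as exc:
                report.add_drop("variants", int(i), str(exc))
        report.n_kept["variants"] = len(variants)

    return ClinicalTables(patients, lines, events, biopsies, variants), report


def write_clinical_tables(
    tables: ClinicalTables, outdir: str | Path, epoch: str = DEFAULT_EPOCH
) -> dict:
    """Write the table set as CSV files; returns the path map read_clinical_tables accepts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def date(day):
        return "" if day is None else day_to_iso(day, epoch)

    def opt(v):
        return "" if v is None else v

    def bool_(v):
        return "true" if v else "false"

    paths = {}
    rows = [
        [p.patient_id, p.stage, p.histology, p.diagnosis_year, bool_(p.age_known),
         opt(p.pdl1_ihc_class), bool_(p.kras_mut), date(p.death_day),
         date(p.last_followup_day)]
        for p in tables.patients
    ]
    paths["patients"] = outdir / "patients.csv"
    pd.DataFrame(rows, columns=_PATIENT_COLS).to_csv(paths["patients"], index=False)

    rows = [
        [l.patient_id, l.line_number, l.regimen_class, date(l.start_day), date(l.end_day)]
        for l in tables.lines
    ]
    paths["therapy_lines"] = outdir / "therapy_lines.csv"
    pd.DataFrame(rows, columns=_LINE_COLS).to_csv(paths["therapy_lines"], index=False)

    rows = [[e.patient_id, date(e.day), e.event_type] for e in tables.events]
    paths["progression_events"] = outdir / "progression_events.csv"
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(
        paths["progression_events"], index=False
    )

    rows = [
        [b.sample_id, b.patient_id, date(b.collection_day), b.tissue_site,
         opt(b.pdl1_ihc_class), opt(b.expression_column)]
        for b in tables.biopsies
    ]
    paths["biopsies"] = outdir / "biopsies.csv"
    pd.DataFrame(rows, columns=_BIOPSY_COLS).to_csv(paths["biopsies"], index=False)

    rows = [
        [v.patient_id, v.gene, v.variant_class, opt(v.pathogenicity)]
        for v in tables.variants
    ]
    paths["variants"] = outdir / "variants.csv"
    pd.DataFrame(rows, columns=_VARIANT_COLS).to_csv(paths["variants"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Variant filter and cohort criteria


def derive_gene_alteration_status(
    variants: Iterable[VariantCall],
) -> tuple[dict, list]:
    """Collapse variant calls to per-patient gene alteration status.

    Short variants (snv_indel) count as alterations only when called
    pathogenic or likely pathogenic — except KEAP1, where every short
    variant is retained because the gene is poorly annotated.  Copy-number
    and fusion records always count.

    Returns ``(status, warnings)`` where ``status`` maps
    patient_id -> gene -> set of altered variant classes.
    """
    status: dict = {}
    warnings: list = []
    for v in variants:
        if v.variant_class == "snv_indel":
            if v.pathogenicity not in PATHOGENICITIES:
                warnings.append(
                    f"{v.patient_id}/{v.gene}: unknown pathogenicity "
                    f"{v.pathogenicity!r}; record skipped"
                )
                continue
            if v.gene != "KEAP1" and v.pathogenicity not in PATHOGENIC:
                continue
        status.setdefault(v.patient_id, {}).setdefault(v.gene, set()).add(
            v.variant_class
        )
    return status, warnings


# Rule order is fixed; exclusions are attributed to the first failing rule.
EXCLUSION_RULES = (
    "diagnosis_year", "stage", "histology", "age_known", "driver_mutation", "fusion",
)


def apply_cohort_criteria(
    patients: Iterable[PatientRecord],
    alteration_status: Mapping[str, Mapping[str, set]],
    config: CohortConfig = CohortConfig(),
) -> tuple[set, dict]:
    """Apply inclusion/exclusion rules; returns (included ids, per-rule counts).

    A patient is included iff every rule passes.  Counts attribute each
    excluded patient to the first failing rule, in the documented order.
    """
    included: set = set()
    counts = {rule: 0 for rule in EXCLUSION_RULES}

    for p in patients:
        genes = alteration_status.get(p.patient_id, {})
        failed = None
        if p.diagnosis_year < config.min_diagnosis_year:
            failed = "diagnosis_year"
        elif p.stage not in config.allowed_stages:
            failed = "stage"
        elif p.histology not in config.allowed_histology:
            failed = "histology"
        elif not p.age_known:
            failed = "age_known"
        elif any(
            genes.get(g, set()) & {"snv_indel", "cnv"}
            for g in config.excluded_driver_genes
        ):
            failed = "driver_mutation"
        elif any("fusion" in genes.get(g, set()) for g in config.excluded_fusion_genes):
            failed = "fusion"

        if failed is None:
            included.add(p.patient_id)
        else:
            counts[failed] += 1
    return included, counts
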