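"""Seeded generator of synthetic multimodal real-world cohorts.

The generator emulates the structure of a real-world NSCLC cohort with
post-ICI biopsies: staggered therapy lines with start/end dates,
biopsies timed relative to treatment, PD-L1 IHC classes coupled to
CD274 mRNA through known latent thresholds, negative-binomial bulk
counts with planted immune-module effects per resistance arm, survival
times driven by planted prognostic gene programs, and a small
single-cell atlas aggregated to pseudobulk.  Everything is deterministic
given the seed, and every planted quantity is recorded in a truth
object so downstream recovery tests have exact targets.

Timelines are constructed strictly inside or outside the phenotyping
rule windows with a configurable margin (default 2 days), so the
rule-based phenotyper must reproduce the planted labels exactly; a
separate fuzz mode samples unconstrained timelines for oracle
equivalence testing of the endpoint rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .clinical import (
    BiopsySample, ClinicalTables, PatientRecord, ProgressionEvent, TherapyLine,
    VariantCall,
)
from .expression import GeneSignature
from .phenotyping import PhenotypeConfig, phenotype_cohort

ARMS = ("naive", "eot_nonresistant", "primary", "acquired")
ARM_TO_LABEL = {
    "naive": "not_eot",
    "eot_nonresistant": "eot_nonresistant",
    "primary": "primary",
    "acquired": "acquired",
}
CELL_TYPES = ("tumor", "tcell", "bcell", "dc", "macrophage", "monocyte", "ciliated")
MYELOID_TYPES = ("dc", "macrophage", "monocyte")


@dataclass(frozen=True)
class ModuleSpec:
    """A planted gene module: member genes and per-arm log2 effects."""

    name: str
    n_genes: int
    effects: dict        # arm -> log2 shift in bulk samples of that arm
    celltypes: tuple     # atlas cell types where the module is enriched
    celltype_log2: float = 3.0


def default_modules() -> tuple:
    return (
        ModuleSpec("IFNG", 18, {"acquired": 1.0}, ("tcell",), 2.0),
        ModuleSpec("BCELL", 12, {"primary": -1.0}, ("bcell",), 3.0),
        ModuleSpec("DC", 10, {"primary": -1.0}, ("dc",), 3.0),
    )


@dataclass(frozen=True)
class SynthConfig:
    n_patients: int = 300
    arm_fractions: dict = field(
        default_factory=lambda: {
            "naive": 0.40, "eot_nonresistant": 0.20,
            "primary": 0.15, "acquired": 0.25,
        }
    )
    n_genes: int = 2000
    modules: tuple = field(default_factory=default_modules)
    dispersion: float = 0.1
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    depth_mean: float = 2.0e6
    depth_log_sd: float = 0.15
    # PD-L1 / CD274 coupling: class means on the log2 CPM scale; the
    # generating thresholds are the midpoints between adjacent means.
    cd274_class_means: tuple = (5.0, 7.0, 9.0)   # lt1, r1_49, ge50
    cd274_sd: float = 0.45
    cd274_dispersion: float = 0.02
    pdl1_class_probs: tuple = (0.45, 0.30, 0.25)
    pdl1_observed_frac: float = 0.6
    # survival model
    n_prognostic_favorable: int = 15
    n_prognostic_unfavorable: int = 15
    prognostic_log_hr: float = 0.8
    prognostic_gene_noise_sd: float = 0.0  # extra latent noise per prognostic gene
    baseline_hazard: float = 1.0 / 500.0   # per day
    stage_log_hr: float = 0.4
    horizon_days: int = 1095
    # timeline construction
    margin_days: int = 2
    phenotype: PhenotypeConfig = PhenotypeConfig()
    # single-cell atlas
    n_atlas_patients: int = 12
    cells_per_type: int = 20
    cell_depth_divisor: float = 400.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.arm_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("arm fractions must sum to 1")
        if self.margin_days < 1:
            raise ValueError("margin must be >= 1 day")
        p = self.phenotype
        if self.margin_days >= min(
            p.eot_window_days, p.resistance_window_days, p.missing_end_min_days
        ):
            raise ValueError("margin must be smaller than every rule window")
        if self.horizon_days <= 0:
            raise ValueError("degenerate config: non-positive follow-up horizon")
        if self.baseline_hazard <= 0 or self.baseline_hazard > 1.0:
            raise ValueError("baseline hazard outside a sane per-day range")


@dataclass
class Truth:
    """Planted ground truth emitted next to every synthetic cohort."""

    seed: int
    arm_by_patient: dict          # patient_id -> arm
    label_by_sample: dict         # sample_id -> expected resistance label
    pdl1_class_by_patient: dict
    cd274_thresholds: tuple       # generating (ge1, ge50) log2 CPM thresholds
    module_genes: dict            # module name -> gene list
    module_effects: dict          # module name -> {arm: log2}
    prognostic: dict              # gene -> {"log_hr": float, "direction": str}
    survival_anchor: dict         # patient_id -> anchor day for the event clock
    factor_scores: dict           # patient_id -> {"favorable": u, "unfavorable": u}

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "arm_by_patient": self.arm_by_patient,
            "label_by_sample": self.label_by_sample,
            "pdl1_class_by_patient": self.pdl1_class_by_patient,
            "cd274_thresholds": list(self.cd274_thresholds),
            "module_genes": self.module_genes,
            "module_effects": self.module_effects,
            "prognostic": self.prognostic,
            "survival_anchor": self.survival_anchor,
        }


@dataclass
class SyntheticCohort:
    config: SynthConfig
    tables: ClinicalTables
    truth: Truth
    counts: Optional[pd.DataFrame] = None            # bulk, genes x samples
    sample_to_patient: Optional[pd.Series] = None
    cell_counts: Optional[pd.DataFrame] = None       # atlas, genes x cells
    cell_meta: Optional[pd.DataFrame] = None
    signatures: Optional[list] = None


# ---------------------------------------------------------------------------
# Stage 1: clinical timelines


def generate_cohort(cfg: SynthConfig) -> SyntheticCohort:
    """Construct clinical timelines realizing the planted resistance arms."""
    rng = np.random.default_rng(cfg.seed)
    m = cfg.margin_days
    p = cfg.phenotype
    n = cfg.n_patients

    arms = []
    for arm in ARMS:
        arms += [arm] * int(round(cfg.arm_fractions.get(arm, 0.0) * n))
    while len(arms) < n:
        arms.append("naive")
    arms = arms[:n]
    rng.shuffle(arms)

    patients, lines, events, biopsies = [], [], [], []
    truth = Truth(
        seed=cfg.seed, arm_by_patient={}, label_by_sample={},
        pdl1_class_by_patient={}, cd274_thresholds=(
            (cfg.cd274_class_means[0] + cfg.cd274_class_means[1]) / 2.0,
            (cfg.cd274_class_means[1] + cfg.cd274_class_means[2]) / 2.0,
        ),
        module_genes={}, module_effects={}, prognostic={},
        survival_anchor={}, factor_scores={},
    )

    pdl1_levels = ("lt1", "r1_49", "ge50")
    for i, arm in enumerate(arms):
        pid = f"P{i:04d}"
        sid = f"S{i:04d}"
        truth.arm_by_patient[pid] = arm
        truth.label_by_sample[sid] = ARM_TO_LABEL[arm]

        stage = "IV" if rng.random() < 0.7 else "III"
        pdl1 = pdl1_levels[rng.choice(3, p=np.asarray(cfg.pdl1_class_probs))]
        truth.pdl1_class_by_patient[pid] = pdl1
        observed = rng.random() < cfg.pdl1_observed_frac
        site = ("lung", "lymph_node", "liver", "other")[
            rng.choice(4, p=np.array([0.5, 0.25, 0.1, 0.15]))
        ]
        kras = bool(rng.random() < 0.35)
        regimen = "ici_chemo" if rng.random() < 0.6 else "ici"

        if arm == "naive":
            start = int(rng.integers(100, 200))
            collection = int(
                rng.integers(
                    max(0, start - p.eot_window_days - m - 60),
                    start - p.eot_window_days - m,
                )
            )
            lines.append(TherapyLine(pid, 1, regimen, start, None))
            anchor = start
        else:
            start = int(rng.integers(30, 120))
            if arm == "primary":
                dur = int(rng.integers(40, p.acquired_min_duration_days - m))
            elif arm == "acquired":
                dur = int(
                    rng.integers(p.acquired_min_duration_days + m, 520)
                )
            else:  # eot_nonresistant: duration straddles the 180-day split
                dur = int(rng.integers(70, 400))
            end = start + dur
            lines.append(TherapyLine(pid, 1, regimen, start, end))
            collection = end + int(
                rng.integers(-(p.eot_window_days - m), p.eot_window_days - m + 1)
            )
            anchor = collection + p.resistance_window_days + m + 1
            if arm in ("primary", "acquired"):
                next_start = end + int(
                    rng.integers(0, p.resistance_window_days - m + 1)
                )
                lines.append(TherapyLine(pid, 2, "platinum_chemo", next_start, None))
                ev_day = collection + int(
                    rng.integers(0, p.resistance_window_days - m + 1)
                )
                ev_type = "progression" if rng.random() < 0.7 else "metastasis"
                events.append(ProgressionEvent(pid, ev_day, ev_type))
                anchor = max(anchor, next_start + 1, ev_day + 1)

        truth.survival_anchor[pid] = int(anchor)
        patients.append(PatientRecord(
            patient_id=pid, stage=stage, histology="nonsquamous",
            diagnosis_year=int(rng.integers(2016, 2023)), age_known=True,
            pdl1_ihc_class=pdl1 if observed else None, kras_mut=kras,
            death_day=None, last_followup_day=int(anchor + cfg.horizon_days),
        ))
        biopsies.append(BiopsySample(
            sample_id=sid, patient_id=pid, collection_day=collection,
            tissue_site=site, pdl1_ihc_class=pdl1 if observed else None,
            expression_column=sid,
        ))
        if kras:
            # non-excluding background alteration
            pass

    variants = _generate_variants(rng, patients)
    tables = ClinicalTables(patients, lines, events, biopsies, variants)
    cohort = SyntheticCohort(config=cfg, tables=tables, truth=truth)
    _audit_labels(cohort)
    return cohort


def _generate_variants(rng, patients) -> list:
    """Background (non-excluding) alteration calls: KRAS/STK11/KEAP1/TP53."""
    variants = []
    for p in patients:
        if p.kras_mut:
            variants.append(VariantCall(p.patient_id, "KRAS", "snv_indel", "pathogenic"))
        if rng.random() < 0.15:
            variants.append(VariantCall(p.patient_id, "STK11", "snv_indel", "pathogenic"))
        if rng.random() < 0.12:
            variants.append(VariantCall(p.patient_id, "KEAP1", "snv_indel", "vus"))
        if rng.random() < 0.4:
            variants.append(VariantCall(p.patient_id, "TP53", "snv_indel",
                                        "likely_pathogenic"))
    return variants


def _audit_labels(cohort: SyntheticCohort) -> None:
    """Self-audit: the rule-based phenotyper must reproduce planted labels."""
    labels, _ = phenotype_cohort(
        cohort.tables.biopsies, cohort.tables.lines, cohort.tables.events,
        cohort.config.phenotype,
    )
    for lab in labels:
        want = cohort.truth.label_by_sample[lab.sample_id]
        if lab.label != want:
            raise AssertionError(
                f"generator self-audit failed: {lab.sample_id} labeled "
                f"{lab.label}, planted {want}"
            )


# ---------------------------------------------------------------------------
# Stage 2: expression


def _gene_universe(cfg: SynthConfig) -> tuple[list, dict]:
    names: list = []
    modules: dict = {}
    for mod in cfg.modules:
        modules[mod.name] = [f"{mod.name}_{i + 1:02d}" for i in range(mod.n_genes)]
        names += modules[mod.name]
    fav = [f"PROGF_{i + 1:02d}" for i in range(cfg.n_prognostic_favorable)]
    unf = [f"PROGU_{i + 1:02d}" for i in range(cfg.n_prognostic_unfavorable)]
    names += fav + unf + ["CD274"]
    n_fill = cfg.n_genes - len(names)
    if n_fill < 0:
        raise ValueError("module gene count exceeds configured gene universe")
    names += [f"G{i + 1:05d}" for i in range(n_fill)]
    modules["_prognostic_favorable"] = fav
    modules["_prognostic_unfavorable"] = unf
    return names, modules


def generate_expression(cohort: SyntheticCohort) -> SyntheticCohort:
    """Negative-binomial bulk counts with planted module and survival effects."""
    cfg = cohort.config
    rng = np.random.default_rng(cfg.seed + 1)
    genes, modules = _gene_universe(cfg)
    pids = [p.patient_id for p in cohort.tables.patients]
    sids = [b.sample_id for b in cohort.tables.biopsies]
    n_s = len(sids)
    g_index = {g: i for i, g in enumerate(genes)}

    base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, len(genes))
    base = np.clip(base, 1.0, 12.0)
    log2_mu = np.tile(base[:, None], (1, n_s))

    # planted arm effects
    arm_of = np.array([cohort.truth.arm_by_patient[pid] for pid in pids])
    for mod in cfg.modules:
        rows = [g_index[g] for g in modules[mod.name]]
        eff = np.array([mod.effects.get(a, 0.0) for a in arm_of])
        log2_mu[rows, :] += eff[None, :]
        cohort.truth.module_genes[mod.name] = modules[mod.name]
        cohort.truth.module_effects[mod.name] = dict(mod.effects)

    # prognostic programs: shared per-patient factor scores
    u_fav = rng.normal(0.0, 1.0, n_s)
    u_unf = rng.normal(0.0, 1.0, n_s)
    for j, pid in enumerate(pids):
        cohort.truth.factor_scores[pid] = {
            "favorable": float(u_fav[j]), "unfavorable": float(u_unf[j]),
        }
    for g in modules["_prognostic_favorable"]:
        log2_mu[g_index[g]] += u_fav
        cohort.truth.prognostic[g] = {
            "log_hr": -cfg.prognostic_log_hr, "direction": "favorable",
        }
    for g in modules["_prognostic_unfavorable"]:
        log2_mu[g_index[g]] += u_unf
        cohort.truth.prognostic[g] = {
            "log_hr": cfg.prognostic_log_hr, "direction": "unfavorable",
        }

    depth = cfg.depth_mean * np.exp(
        rng.normal(0.0, cfg.depth_log_sd, n_s)
    )
    frac = 2.0 ** log2_mu
    frac /= frac.sum(axis=0, keepdims=True)
    mu = frac * depth[None, :]

    r = 1.0 / cfg.dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)

    # CD274 coupled to the PD-L1 class via latent log2-CPM values
    cls_idx = {"lt1": 0, "r1_49": 1, "ge50": 2}
    target = np.array([
        cfg.cd274_class_means[
            cls_idx[cohort.truth.pdl1_class_by_patient[pid]]
        ]
        for pid in pids
    ])
    latent = target + rng.normal(0.0, cfg.cd274_sd, n_s)
    cd_mu = 2.0 ** latent / 1e6 * depth
    r_cd = 1.0 / cfg.cd274_dispersion
    counts[g_index["CD274"], :] = rng.negative_binomial(
        r_cd, r_cd / (r_cd + cd_mu)
    )

    cohort.counts = pd.DataFrame(counts, index=genes, columns=sids)
    cohort.sample_to_patient = pd.Series(pids, index=sids, name="patient_id")
    cohort.signatures = [
        GeneSignature(mod.name, modules[mod.name]) for mod in cfg.modules
    ]
    _generate_atlas(cohort, rng, genes, modules, base, g_index)
    return cohort


def _generate_atlas(cohort, rng, genes, modules, base, g_index) -> None:
    """Small single-cell atlas with cell-type-specific module enrichment."""
    cfg = cohort.config
    cell_ids, meta_rows = [], []
    n_cells = cfg.n_atlas_patients * len(CELL_TYPES) * cfg.cells_per_type
    log2_mu = np.empty((len(genes), n_cells))
    col = 0
    type_boost = {ct: np.zeros(len(genes)) for ct in CELL_TYPES}
    for mod in cfg.modules:
        for ct in mod.celltypes:
            for g in modules[mod.name]:
                type_boost[ct][g_index[g]] += mod.celltype_log2
    for ct in MYELOID_TYPES:
        for g in modules["_prognostic_favorable"]:
            type_boost[ct][g_index[g]] += 2.0
    for ct in ("ciliated", "tumor"):
        for g in modules["_prognostic_unfavorable"]:
            type_boost[ct][g_index[g]] += 2.0

    for ap in range(cfg.n_atlas_patients):
        pid = f"A{ap:03d}"
        for ct in CELL_TYPES:
            for c in range(cfg.cells_per_type):
                cell_ids.append(f"{pid}_{ct}_{c:03d}")
                meta_rows.append({"patient_id": pid, "cell_type": ct})
                log2_mu[:, col] = base + type_boost[ct]
                col += 1

    frac = 2.0 ** log2_mu
    frac /= frac.sum(axis=0, keepdims=True)
    depth = cfg.depth_mean / cfg.cell_depth_divisor
    mu = frac * depth
    r = 1.0 / max(cfg.dispersion, 1e-6)
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
    cohort.cell_counts = pd.DataFrame(counts, index=genes, columns=cell_ids)
    cohort.cell_meta = pd.DataFrame(meta_rows, index=cell_ids)


# ---------------------------------------------------------------------------
# Stage 3: survival


def generate_survival(cohort: SyntheticCohort) -> SyntheticCohort:
    """Exponential event times driven by planted prognostic factors and stage.

    hazard = h0 * exp(beta * (u_unfavorable - u_favorable) + beta_stage * IV).
    The event clock starts at each patient's timeline-safe anchor day
    (recorded in the truth file), which equals the line start for naive
    patients and clears the resistance window for post-ICI patients so
    that planted phenotype labels survive the merge of death events.
    Administrative censoring at the configured horizon.
    """
    cfg = cohort.config
    if cohort.counts is None:
        raise ValueError("generate_expression must run before generate_survival")
    rng = np.random.default_rng(cfg.seed + 2)
    patients = []
    events = list(cohort.tables.events)
    for p in cohort.tables.patients:
        scores = cohort.truth.factor_scores[p.patient_id]
        lp = cfg.prognostic_log_hr * (scores["unfavorable"] - scores["favorable"])
        lp += cfg.stage_log_hr * (1.0 if p.stage == "IV" else 0.0)
        hazard = cfg.baseline_hazard * np.exp(lp)
        if not np.isfinite(hazard) or hazard > 1e6:
            raise ValueError(f"hazard overflow for {p.patient_id}: check config")
        t = rng.exponential(1.0 / hazard)
        anchor = cohort.truth.survival_anchor[p.patient_id]
        if t <= cfg.horizon_days:
            death = int(anchor + np.ceil(t))
            patients.append(
                _with(p, death_day=death, last_followup_day=death)
            )
            events.append(ProgressionEvent(p.patient_id, death, "death"))
        else:
            patients.append(
                _with(p, death_day=None,
                      last_followup_day=int(anchor + cfg.horizon_days))
            )
    cohort.tables = ClinicalTables(
        patients, cohort.tables.lines, events, cohort.tables.biopsies,
        cohort.tables.variants,
    )
    _audit_labels(cohort)
    return cohort


def _with(p: PatientRecord, **kw) -> PatientRecord:
    from dataclasses import replace

    return replace(p, **kw)


def generate_all(cfg: SynthConfig) -> SyntheticCohort:
    """Full synthetic cohort: timelines, expression, atlas, survival."""
    return generate_survival(generate_expression(generate_cohort(cfg)))


# ---------------------------------------------------------------------------
# Fuzz mode: unconstrained random timelines for endpoint-oracle testing


def fuzz_timelines(n: int, seed: int = 0) -> list:
    """Random (patient, line, next_line, events) tuples with valid invariants.

    Dates are sampled freely (no rule-window margins), producing boundary
    cases for the endpoint derivations; invariants that must hold in any
    valid table (end >= start, death consistent with follow-up windows)
    are respected.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        pid = f"F{i:05d}"
        start = int(rng.integers(0, 100))
        has_end = rng.random() < 0.7
        end = start + int(rng.integers(0, 400)) if has_end else None
        has_next = rng.random() < 0.5
        next_start = (
            (end if end is not None else start) + int(rng.integers(0, 200))
            if has_next else None
        )
        followup = start + int(rng.integers(0, 800))
        if end is not None:
            followup = max(followup, end)
        if next_start is not None:
            followup = max(followup, next_start)
        dead = rng.random() < 0.5
        death = start + int(rng.integers(0, 800)) if dead else None
        if death is not None:
            followup = max(followup, death)
        patient = PatientRecord(
            patient_id=pid, stage="IV", histology="nonsquamous",
            diagnosis_year=2018, age_known=True, death_day=death,
            last_followup_day=followup,
        )
        line = TherapyLine(pid, 1, "ici", start, end)
        next_line = (
            TherapyLine(pid, 2, "platinum_chemo", next_start, None)
            if next_start is not None else None
        )
        events = [
            ProgressionEvent(
                pid, start + int(rng.integers(-20, 500)),
                ("progression", "metastasis", "death")[rng.integers(0, 3)],
            )
            for _ in range(rng.integers(0, 4))
        ]
        out.append((patient, line, next_line, events))
    return out
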