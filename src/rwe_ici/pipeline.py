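"""End-to-end orchestration: simulate -> filter -> endpoints -> phenotype ->
impute -> normalize -> signatures -> DE -> enrichment -> screen -> projection.

Every stage hands plain files to the next (CSV/TSV/GMT/JSON under the
run directory), so each intermediate is inspectable and reproducible in
isolation.  The run report records per-stage input/output row counts,
the seed, a hash of the resolved configuration, and any warnings; a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clinical, de, endpoints, expression, pdl1, phenotyping, screen, synth

STAGES = (
    "simulate", "cohort_filter", "endpoints", "phenotype", "impute_pdl1",
    "normalize", "signatures", "de", "gsea", "screen", "project",
)

DEFAULT_CONFIG = {
    "seed": 7,
    "outdir": "rwe_run",
    "stages": list(STAGES),
    "simulate": {},          # SynthConfig overrides
    "de": {"covariates": ["tissue_site", "kras_mut"], "arms": ["naive", "acquired"]},
    "gsea": {"n_perm": 1000, "min_size": 5, "max_size": 500},
    "screen": {"alpha": 0.05, "second_cohort_seed_offset": 1000},
    "impute": {},
    "phenotype": {},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for k, v in user.items():
        if k not in cfg and k not in ("stages",):
            raise ValueError(f"unknown pipeline config key {k!r}")
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable fingerprint of the analysis configuration (output path excluded)."""
    keyed = {k: v for k, v in cfg.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(keyed, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


class PipelineRun:
    """Mutable context threaded through the stages."""

    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.outdir = Path(cfg["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.report = {
            "config_hash": config_hash(cfg),
            "seed": cfg["seed"],
            "stages": [],
            "warnings": [],
        }
        self.cohort: Optional[synth.SyntheticCohort] = None
        self.cohort_b: Optional[synth.SyntheticCohort] = None
        self.norm: Optional[pd.DataFrame] = None
        self.labels = None
        self.outcomes_os = None
        self.pdl1_by_patient: Optional[pd.Series] = None
        self.hits: Optional[dict] = None

    def record(self, stage: str, **counts) -> None:
        self.report["stages"].append({"stage": stage, **counts})


def _stage_simulate(run: PipelineRun) -> None:
    overrides = dict(run.cfg["simulate"])
    overrides.setdefault("seed", run.cfg["seed"])
    cohort = synth.generate_all(synth.SynthConfig(**overrides))
    run.cohort = cohort
    paths = clinical.write_clinical_tables(cohort.tables, run.outdir)
    expression.write_counts_tsv(cohort.counts, run.outdir / "counts.tsv")
    expression.write_gmt(cohort.signatures, run.outdir / "signatures.gmt")
    _write_json(cohort.truth.to_json_dict(), run.outdir / "truth.json")
    run.record(
        "simulate", n_patients=len(cohort.tables.patients),
        n_biopsies=len(cohort.tables.biopsies),
        n_genes=int(cohort.counts.shape[0]),
    )


def _stage_cohort_filter(run: PipelineRun) -> None:
    t = run.cohort.tables
    status, warns = clinical.derive_gene_alteration_status(t.variants)
    included, counts = clinical.apply_cohort_criteria(t.patients, status)
    run.report["warnings"] += warns
    _write_json(
        {"included": sorted(included), "exclusion_counts": counts},
        run.outdir / "cohort_filter.json",
    )
    run.record("cohort_filter", n_in=len(t.patients), n_included=len(included))


def _stage_endpoints(run: PipelineRun) -> None:
    t = run.cohort.tables
    lines = t.lines_by_patient()
    events = t.events_by_patient()
    rows = []
    outcomes_os = []
    for p in t.patients:
        plines = lines.get(p.patient_id, [])
        if not plines:
            continue
        first = plines[0]
        nxt = plines[1] if len(plines) > 1 else None
        os_o = endpoints.derive_os(p, first)
        pfs_o = endpoints.derive_rwpfs(p, first, nxt, events.get(p.patient_id, []))
        outcomes_os.append(os_o)
        for o in (os_o, pfs_o):
            rows.append({
                "patient_id": o.patient_id, "endpoint": o.endpoint,
                "time_days": o.time_days, "event": int(o.event),
                "anchor_line": o.anchor_line,
            })
    run.outcomes_os = outcomes_os
    pd.DataFrame(rows).to_csv(run.outdir / "outcomes.csv", index=False)
    km = endpoints.km_estimate(outcomes_os)
    run.record(
        "endpoints", n_outcomes=len(rows),
        os_median_days=km.median if km.median is not None else float("nan"),
    )


def _stage_phenotype(run: PipelineRun) -> None:
    t = run.cohort.tables
    pcfg = phenotyping.PhenotypeConfig(**run.cfg["phenotype"])
    labels, cascade = phenotyping.phenotype_cohort(
        t.biopsies, t.lines, t.events, pcfg
    )
    run.labels = labels
    pd.DataFrame(
        [{"sample_id": l.sample_id, "label": l.label, "rule": l.supporting_rule}
         for l in labels]
    ).to_csv(run.outdir / "labels.csv", index=False)
    _write_json(cascade, run.outdir / "cascade.json")
    run.record("phenotype", **cascade)


def _stage_impute_pdl1(run: PipelineRun) -> None:
    cohort = run.cohort
    norm = run.norm if run.norm is not None else expression.normalize_counts(
        cohort.counts
    )
    cd274 = norm.loc["CD274"]
    observed = {
        b.sample_id: b.pdl1_ihc_class for b in cohort.tables.biopsies
    }
    train_mask = np.array([observed[s] is not None for s in norm.columns])
    x = cd274.to_numpy()
    obs_cls = np.array([observed[s] or "" for s in norm.columns])
    models = {}
    for target in ("ge1", "ge50"):
        pos = {"ge1": {"r1_49", "ge50"}, "ge50": {"ge50"}}[target]
        y = np.array([c in pos for c in obs_cls])
        models[target] = pdl1.fit_expression_threshold(
            x[train_mask], y[train_mask], target_class=target
        )
    calls = pdl1.classify_pdl1(
        models["ge1"], models["ge50"], x,
        observed=[observed[s] for s in norm.columns],
    )
    imputed = pd.DataFrame({
        "sample_id": list(norm.columns),
        "cd274_log2cpm": x,
        "observed_class": [observed[s] or "" for s in norm.columns],
        "pdl1_class": calls,
    })
    imputed.to_csv(run.outdir / "pdl1_imputed.csv", index=False)
    _write_json(
        {t: vars(m) for t, m in models.items()}, run.outdir / "pdl1_models.json"
    )
    run.pdl1_by_patient = pd.Series(
        calls, index=cohort.sample_to_patient.reindex(norm.columns).to_numpy()
    )
    run.pdl1_calls = pd.Series(calls, index=norm.columns)
    run.record(
        "impute_pdl1", n_train=int(train_mask.sum()),
        n_imputed=int((~train_mask).sum()),
        kappa_ge1=models["ge1"].kappa, kappa_ge50=models["ge50"].kappa,
    )


def _stage_normalize(run: PipelineRun) -> None:
    counts = run.cohort.counts
    factors = expression.tmm_factors(counts)
    run.norm = expression.log_cpm(counts, factors)
    run.norm.round(6).to_csv(run.outdir / "norm_log2cpm.tsv", sep="\t")
    factors.round(8).to_csv(run.outdir / "tmm_factors.csv")
    run.record("normalize", n_genes=int(counts.shape[0]),
               n_samples=int(counts.shape[1]))


def _arm_samples(run: PipelineRun, arms) -> tuple[list, list]:
    truth = run.cohort.truth
    s2p = run.cohort.sample_to_patient
    cols, grp = [], []
    for s in run.norm.columns:
        arm = truth.arm_by_patient[s2p[s]]
        if arm in arms:
            cols.append(s)
            grp.append(arm)
    return cols, grp


def _covariate_frame(run: PipelineRun, cols) -> pd.DataFrame:
    t = run.cohort.tables
    by_sample = {b.sample_id: b for b in t.biopsies}
    pat = t.patient_index()
    rows = []
    for s in cols:
        b = by_sample[s]
        p = pat[b.patient_id]
        rows.append({
            "tissue_site": b.tissue_site,
            "kras_mut": str(p.kras_mut),
            "pdl1_class": str(run.pdl1_calls[s]) if hasattr(run, "pdl1_calls")
            else str(p.pdl1_ihc_class),
        })
    return pd.DataFrame(rows)


def _stage_signatures(run: PipelineRun) -> None:
    arms = run.cfg["de"]["arms"]
    cols, grp = _arm_samples(run, arms)
    cov_names = run.cfg["de"]["covariates"]
    cov = _covariate_frame(run, cols)
    cov = cov[[c for c in cov.columns if c in cov_names or c == "pdl1_class"]]
    rows = []
    for sig in run.cohort.signatures:
        scores = expression.signature_score(run.norm[cols], sig)
        adj = expression.adjusted_group_means(
            scores.to_numpy(), grp, covariates=cov
        )
        for lv, r in adj.means.iterrows():
            rows.append({
                "signature": sig.name, "group": lv, "adjusted_mean": r["mean"],
                "se": r["se"], "n": r["n"], "contrast_p": adj.contrast_p,
            })
    pd.DataFrame(rows).round(6).to_csv(
        run.outdir / "signature_means.csv", index=False
    )
    run.record("signatures", n_signatures=len(run.cohort.signatures))


def _stage_de(run: PipelineRun) -> None:
    arms = run.cfg["de"]["arms"]
    cols, grp = _arm_samples(run, arms)
    cov_names = run.cfg["de"]["covariates"]
    cov = _covariate_frame(run, cols)
    cov = cov[[c for c in cov.columns if c in cov_names or c == "pdl1_class"]]
    res = de.fit_gene_linear_models(
        run.norm[cols], grp, covariates=cov, reference=str(arms[0])
    )
    res.round(6).to_csv(run.outdir / "de.tsv", sep="\t", index_label="gene")
    run.de_results = res
    run.record(
        "de", n_genes=len(res),
        n_q05=int((res["q_value"] < 0.05).sum()),
    )


def _stage_gsea(run: PipelineRun) -> None:
    gcfg = run.cfg["gsea"]
    ranking = run.de_results["t_stat"]
    table, _ = de.preranked_enrichment(
        ranking, run.cohort.signatures,
        n_perm=int(gcfg["n_perm"]), seed=run.cfg["seed"],
        min_size=int(gcfg["min_size"]), max_size=int(gcfg["max_size"]),
    )
    table.round(6).to_csv(run.outdir / "gsea.tsv", sep="\t")
    run.report["warnings"] += table.attrs.get("warnings", [])
    run.record("gsea", n_sets=len(table))


def _stage_screen(run: PipelineRun) -> None:
    scfg = run.cfg["screen"]
    cohort_a = run.cohort
    overrides = dict(run.cfg["simulate"])
    overrides["seed"] = run.cfg["seed"] + int(scfg["second_cohort_seed_offset"])
    cohort_b = synth.generate_all(synth.SynthConfig(**overrides))
    run.cohort_b = cohort_b

    results = {}
    for name, cohort in (("a", cohort_a), ("b", cohort_b)):
        norm = (
            run.norm if name == "a"
            else expression.normalize_counts(cohort.counts)
        )
        lines = cohort.tables.lines_by_patient()
        outcomes = [
            endpoints.derive_os(p, lines[p.patient_id][0])
            for p in cohort.tables.patients
        ]
        res = screen.per_gene_cox_screen(
            norm, outcomes, screen.ScreenConfig(alpha=float(scfg["alpha"])),
            sample_to_patient=cohort.sample_to_patient,
        )
        res.round(6).to_csv(
            run.outdir / f"screen_{name}.tsv", sep="\t", index_label="gene"
        )
        results[name] = res
    hits = screen.intersect_cohort_hits(
        results["a"], results["b"], alpha=float(scfg["alpha"])
    )
    run.hits = hits
    _write_json(hits, run.outdir / "screen_hits.json")
    run.record(
        "screen", n_favorable=len(hits["favorable"]),
        n_unfavorable=len(hits["unfavorable"]),
        n_discordant=len(hits["discordant"]),
    )


def _stage_project(run: PipelineRun) -> None:
    cohort = run.cohort
    pb, pb_report = expression.pseudobulk_aggregate(
        cohort.cell_counts, cohort.cell_meta, min_cells=5
    )
    proj = screen.project_hits_to_celltypes(run.hits, pb)
    rows = []
    for part, res in proj.items():
        for ct, r in res["summary"].iterrows():
            rows.append({
                "partition": part, "cell_type": ct,
                "median_score": r["median_score"], "rank": int(r["rank"]),
            })
    pd.DataFrame(rows).round(6).to_csv(
        run.outdir / "celltype_projection.csv", index=False
    )
    run.record(
        "project", n_pseudobulk_columns=pb_report["n_columns"],
        n_excluded_cells=pb_report["n_excluded_cells"],
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cohort_filter": _stage_cohort_filter,
    "endpoints": _stage_endpoints,
    "phenotype": _stage_phenotype,
    "normalize": _stage_normalize,
    "impute_pdl1": _stage_impute_pdl1,
    "signatures": _stage_signatures,
    "de": _stage_de,
    "gsea": _stage_gsea,
    "screen": _stage_screen,
    "project": _stage_project,
}

# dependency-ordered execution regardless of the order given in config
_ORDER = (
    "simulate", "cohort_filter", "endpoints", "phenotype", "normalize",
    "impute_pdl1", "signatures", "de", "gsea", "screen", "project",
)

_DEPENDS = {
    "cohort_filter": {"simulate"},
    "endpoints": {"simulate"},
    "phenotype": {"simulate"},
    "normalize": {"simulate"},
    "impute_pdl1": {"normalize"},
    "signatures": {"normalize", "impute_pdl1"},
    "de": {"normalize", "impute_pdl1"},
    "gsea": {"de"},
    "screen": {"normalize"},
    "project": {"screen"},
}


def run_pipeline(config) -> dict:
    """Execute the configured stages in dependency order; returns the report."""
    cfg = load_config(config)
    requested = set(cfg["stages"])
    for stage in requested:
        missing = _DEPENDS.get(stage, set()) - requested
        if missing:
            raise ValueError(
                f"stage {stage!r} requires {sorted(missing)} to be enabled"
            )
    run = PipelineRun(cfg)
    try:
        for stage in _ORDER:
            if stage in requested:
                _STAGE_FUNCS[stage](run)
    finally:
        _write_json(run.report, run.outdir / "run_report.json")
    return run.report
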