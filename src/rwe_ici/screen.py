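"""Per-gene Cox proportional-hazards screening and cross-cohort intersection.

Every gene's log2 expression enters a Cox model for the chosen endpoint
(continuous, per log2 unit), optionally adjusted for clinical
covariates.  Genes significant in two independent cohorts with the same
direction of effect form the replicated hit set, which can then be
projected onto single-cell pseudobulk profiles to ask which cell types
express it.

The univariate screen uses an internal vectorized Newton solver for the
Breslow partial likelihood (all genes iterated simultaneously), which
keeps genome-wide screens and permutation calibrations fast; the
covariate-adjusted mode delegates each fit to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test

from .endpoints import SurvivalOutcome, km_estimate


@dataclass(frozen=True)
class ScreenConfig:
    alpha: float = 0.05
    endpoint: str = "os"
    covariates: tuple = ()            # column names in the covariate table
    subgroup: Optional[dict] = None   # e.g. {"pdl1_ihc_class": "lt1"}
    min_events: int = 10

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Vectorized Breslow partial-likelihood Newton solver (single covariate,
# shared across G genes)


def _cox_univariate(
    X: np.ndarray, time: np.ndarray, event: np.ndarray,
    max_iter: int = 25, tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column Cox fits of ``time``/``event`` on X (n x G).

    Returns (beta, se, converged).  Breslow tie handling.  Columns with
    zero variance or failed convergence are flagged.
    """
    n, G = X.shape
    order = np.argsort(-time, kind="mergesort")  # descending time
    Xs = X[order]
    ev = event[order].astype(bool)
    ts = time[order]
    # risk set of subject i (ascending-time event) = prefix in descending order;
    # with ties, all subjects at the same time share the risk set: use the last
    # index of each tied block.
    # block end index per position (inclusive) in descending order:
    # subjects j with ts[j] >= t belong to the risk set of an event at t.
    uniq, inv = np.unique(-ts, return_inverse=True)
    # for each position, the largest index with the same time
    last_of_block = np.zeros(n, dtype=int)
    idx = np.arange(n)
    for u in range(uniq.size):
        members = idx[inv == u]
        last_of_block[members] = members.max()

    var = Xs.var(axis=0)
    active = var > 1e-12
    beta = np.zeros(G)
    converged = np.zeros(G, dtype=bool)
    se = np.full(G, np.nan)

    ev_idx = np.where(ev)[0]
    d_total = ev_idx.size

    b = np.zeros(G)
    for _ in range(max_iter):
        eta = Xs * b  # n x G
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        s0 = np.cumsum(w, axis=0)
        s1 = np.cumsum(Xs * w, axis=0)
        s2 = np.cumsum(Xs ** 2 * w, axis=0)
        rows = last_of_block[ev_idx]
        s0e = s0[rows]
        s1e = s1[rows]
        s2e = s2[rows]
        mu = s1e / s0e
        grad = (Xs[ev_idx] - mu).sum(axis=0)
        hess = (s2e / s0e - mu ** 2).sum(axis=0)
        step = np.where((hess > 1e-12) & active, grad / np.maximum(hess, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        b = b + np.where(active, step, 0.0)
        done = np.abs(step) < tol
        converged = converged | (done & active)
        if bool(np.all(done | ~active)):
            break

    # final information for standard errors
    eta = np.clip(Xs * b, -500, 500)
    w = np.exp(eta)
    s0 = np.cumsum(w, axis=0)
    s1 = np.cumsum(Xs * w, axis=0)
    s2 = np.cumsum(Xs ** 2 * w, axis=0)
    rows = last_of_block[ev_idx]
    mu = s1[rows] / s0[rows]
    info = (s2[rows] / s0[rows] - mu ** 2).sum(axis=0)
    ok = converged & (info > 1e-12) & (d_total > 0)
    se = np.where(ok, 1.0 / np.sqrt(np.maximum(info, 1e-12)), np.nan)
    beta = np.where(ok, b, np.nan)
    return beta, se, ok


def _align(
    norm: pd.DataFrame,
    outcomes: Sequence[SurvivalOutcome],
    sample_to_patient: Optional[pd.Series],
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list]:
    """Match expression columns to outcomes via patient linkage."""
    by_patient = {o.patient_id: o for o in outcomes}
    cols, time, event = [], [], []
    for col in norm.columns:
        pid = (
            str(sample_to_patient.get(col))
            if sample_to_patient is not None and col in sample_to_patient.index
            else col
        )
        o = by_patient.get(pid)
        if o is None:
            continue
        cols.append(col)
        time.append(o.time_days)
        event.append(o.event)
    if not cols:
        raise ValueError("no expression columns could be linked to outcomes")
    return norm[cols], np.array(time, float), np.array(event, bool), cols


def per_gene_cox_screen(
    norm: pd.DataFrame,
    outcomes: Sequence[SurvivalOutcome],
    cfg: ScreenConfig = ScreenConfig(),
    covariate_table: Optional[pd.DataFrame] = None,
    sample_to_patient: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Screen every gene's log2 expression against survival.

    Returns a DataFrame indexed by gene with ``log_hr`` (per log2
    expression unit), ``hazard_ratio``, ``p_value``, ``direction``
    (favorable when HR < 1) and ``converged``.  Samples are matched to
    outcomes by patient id (optionally via ``sample_to_patient``); a
    subgroup filter restricts on ``covariate_table`` columns.  When
    ``cfg.covariates`` is empty the fast vectorized univariate solver is
    used, otherwise each gene is fit with lifelines including the
    covariates.
    """
    mat, time, event, cols = _align(norm, outcomes, sample_to_patient)
    covs = (
        covariate_table.reindex(cols) if covariate_table is not None else None
    )
    if cfg.subgroup:
        mask = np.ones(len(cols), dtype=bool)
        if covs is None:
            raise ValueError("subgroup filter requires a covariate table")
        for key, val in cfg.subgroup.items():
            mask &= (covs[key].astype(str) == str(val)).to_numpy()
        mat = mat.loc[:, mask]
        time, event = time[mask], event[mask]
        covs = covs.loc[mask]
    if int(event.sum()) < cfg.min_events:
        raise ValueError(
            f"subgroup has {int(event.sum())} events; need >= {cfg.min_events}"
        )

    X = mat.to_numpy(dtype=float).T  # samples x genes
    if not cfg.covariates:
        beta, se, ok = _cox_univariate(X, time, event)
        z = beta / se
        p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    else:
        cov_design = pd.get_dummies(
            covs[list(cfg.covariates)], drop_first=True, dtype=float
        )
        beta = np.full(X.shape[1], np.nan)
        se = np.full(X.shape[1], np.nan)
        p = np.full(X.shape[1], np.nan)
        ok = np.zeros(X.shape[1], dtype=bool)
        for j in range(X.shape[1]):
            df = cov_design.copy()
            df["expr"] = X[:, j]
            df["time"] = time
            df["event"] = event.astype(int)
            if df["expr"].var() <= 1e-12:
                continue
            try:
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="event")
                beta[j] = cph.params_["expr"]
                se[j] = cph.standard_errors_["expr"]
                p[j] = cph.summary.loc["expr", "p"]
                ok[j] = True
            except Exception:
                continue
        z = beta / se

    out = pd.DataFrame(
        {
            "log_hr": beta,
            "hazard_ratio": np.exp(beta),
            "se": se,
            "p_value": p,
            "converged": ok,
        },
        index=mat.index,
    )
    out["direction"] = np.where(out["hazard_ratio"] < 1, "favorable", "unfavorable")
    out.loc[~out["converged"], "direction"] = "na"
    out.attrs["n_samples"] = int(time.size)
    out.attrs["n_events"] = int(event.sum())
    out.attrs["n_nonconverged"] = int((~ok).sum())
    return out


def intersect_cohort_hits(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    alpha: float = 0.05,
    require_concordant_direction: bool = True,
) -> dict:
    """Replicated screen hits: significant in both cohorts.

    Returns a dict with ``favorable`` and ``unfavorable`` gene lists
    (shared direction), plus ``discordant`` (significant in both but
    with opposite directions; dropped when concordance is required).
    """
    universe = results_a.index.intersection(results_b.index)
    if universe.empty:
        raise ValueError("cohorts share no genes")

    def hits(res):
        r = res.loc[universe]
        return r[(r["p_value"] < alpha) & r["converged"]]

    ha, hb = hits(results_a), hits(results_b)
    common = ha.index.intersection(hb.index)
    favorable, unfavorable, discordant = [], [], []
    for g in common:
        da, db = ha.loc[g, "direction"], hb.loc[g, "direction"]
        if da != db:
            discordant.append(g)
        elif da == "favorable":
            favorable.append(g)
        else:
            unfavorable.append(g)
    out = {
        "favorable": sorted(favorable),
        "unfavorable": sorted(unfavorable),
        "discordant": sorted(discordant),
        "n_universe": int(len(universe)),
    }
    if not require_concordant_direction:
        out["favorable"] = sorted(favorable + [g for g in discordant])
    return out


def dichotomize_and_km(
    scores: pd.Series,
    outcomes: Sequence[SurvivalOutcome],
    split: str = "median",
    min_per_arm: int = 10,
) -> dict:
    """High/low signature-score survival comparison.

    Splits patients at the median score (or keeps the extreme tertiles),
    returns Kaplan-Meier estimates per arm, the log-rank p-value, and
    the high-vs-low hazard ratio from a two-group Cox fit.
    """
    by_patient = {o.patient_id: o for o in outcomes}
    common = [pid for pid in scores.index if pid in by_patient]
    s = scores.loc[common]
    if s.nunique() <= 1:
        raise ValueError("constant scores cannot be dichotomized")
    if split == "median":
        cut = s.median()
        high = s > cut
        keep = pd.Series(True, index=s.index)
    elif split == "tertile-extremes":
        lo_cut, hi_cut = s.quantile([1 / 3, 2 / 3])
        keep = (s <= lo_cut) | (s > hi_cut)
        high = s > hi_cut
    else:
        raise ValueError(f"unknown split {split!r}")
    s = s[keep]
    high = high[keep]
    if high.sum() < min_per_arm or (~high).sum() < min_per_arm:
        raise ValueError(
            f"arms too small after split: {int(high.sum())}/{int((~high).sum())}"
        )
    arm_out = {
        arm: [by_patient[pid] for pid in s.index[high == (arm == "high")]]
        for arm in ("high", "low")
    }
    time = np.array([by_patient[p].time_days for p in s.index], float)
    event = np.array([by_patient[p].event for p in s.index], bool)
    grp = high.to_numpy()
    lr = logrank_test(time[grp], time[~grp], event[grp], event[~grp])
    cph = CoxPHFitter()
    cph.fit(
        pd.DataFrame({"time": time, "event": event.astype(int), "high": grp.astype(float)}),
        duration_col="time", event_col="event",
    )
    return {
        "km_high": km_estimate(arm_out["high"]),
        "km_low": km_estimate(arm_out["low"]),
        "logrank_p": float(lr.p_value),
        "hazard_ratio": float(np.exp(cph.params_["high"])),
        "hr_p": float(cph.summary.loc["high", "p"]),
        "n_high": int(grp.sum()),
        "n_low": int((~grp).sum()),
    }


def project_hits_to_celltypes(
    hits: dict,
    pseudobulk: pd.DataFrame,
    prior_count: float = 0.5,
) -> dict:
    """Score replicated hit sets across cell-type pseudobulk columns.

    For each non-empty partition (favorable / unfavorable) a signature
    is built from the hit genes present in the atlas and scored per
    (patient, cell type); cell types are ranked by median score.
    Reports genes absent from the atlas.
    """
    from .expression import GeneSignature, celltype_signature_profile

    out = {}
    for part in ("favorable", "unfavorable"):
        genes = hits.get(part, [])
        if not genes:
            continue
        present = [g for g in genes if g in pseudobulk.index]
        absent = [g for g in genes if g not in pseudobulk.index]
        if not present:
            raise ValueError(f"no {part} hit genes detectable in the atlas")
        sig = GeneSignature(f"{part}_hits", present)
        table, summary = celltype_signature_profile(
            pseudobulk, sig, prior_count=prior_count
        )
        out[part] = {
            "scores": table,
            "summary": summary,
            "n_detectable": len(present),
            "absent_genes": absent,
        }
    if not out:
        raise ValueError("no hit genes provided")
    return out
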