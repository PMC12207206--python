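"""Count normalization, signature scoring, and pseudobulk aggregation.

Raw gene-by-sample count matrices are normalized by trimmed-mean-of-
M-values (TMM) scaling followed by log2 counts-per-million.  Signature
scores are the unweighted mean of log-scale normalized expression over
the signature genes present in the matrix.  Single-cell data enters as
cell-level counts plus (patient, cell type) labels and is aggregated to
pseudobulk columns by exact summation before the same normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import scipy.stats
import statsmodels.api as sm


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set; duplicate symbols are removed preserving order."""

    name: str
    genes: tuple

    def __init__(self, name: str, genes: Iterable[str]):
        seen, uniq = set(), []
        for g in genes:
            if g not in seen:
                seen.add(g)
                uniq.append(g)
        if not uniq:
            raise ExpressionError(f"signature {name!r} is empty")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", tuple(uniq))

    def __len__(self):
        return len(self.genes)


# ---------------------------------------------------------------------------
# IO: count matrices (TSV / MatrixMarket) and GMT signatures


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample counts from TSV with a header row and gene-symbol index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _validate_counts(df)
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_mtx(
    mtx_path: str | Path, genes_path: str | Path, samples_path: str | Path
) -> pd.DataFrame:
    """Counts from MatrixMarket plus one-column gene and sample TSV files."""
    m = scipy.io.mmread(mtx_path)
    genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].tolist()
    samples = pd.read_csv(samples_path, sep="\t", header=None).iloc[:, 0].tolist()
    df = pd.DataFrame(
        np.asarray(m.todense() if scipy.sparse.issparse(m) else m),
        index=genes, columns=samples,
    )
    _validate_counts(df)
    return df


def _validate_counts(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ExpressionError(f"duplicate gene symbols in count matrix: {dupes}")
    if (df.to_numpy() < 0).any():
        raise ExpressionError("count matrix contains negative entries")


def read_gmt(path: str | Path) -> list:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sigs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sigs.append(GeneSignature(parts[0], [g for g in parts[2:] if g]))
    return sigs


def write_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "na", *sig.genes]) + "\n")


# ---------------------------------------------------------------------------
# TMM normalization


def _quantile_fraction(col: np.ndarray, lib: float, p: float = 0.75) -> float:
    return np.quantile(col, p) / lib


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Per-sample TMM scaling factors.

    The reference sample is the one whose 75th-percentile count fraction
    is closest to the mean across samples.  Against the reference, each
    sample's gene-wise log ratios (M) and log abundances (A) over genes
    nonzero in both are doubly trimmed (default 30% per M tail, 5% per A
    tail by rank) and combined as a precision-weighted mean of the
    surviving M values; the factor is 2 to that mean.  Factors are
    rescaled so their geometric mean is exactly 1.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ExpressionError("TMM requires at least two samples")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ExpressionError("every sample needs at least one nonzero gene")

    f75 = np.array([_quantile_fraction(x[:, j], lib[j]) for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        both = (x[:, j] > 0) & (x[:, ref] > 0)
        if not both.any():
            log_factors[j] = 0.0  # nothing shared with the reference
            continue
        obs, refv = x[both, j], x[both, ref]
        p_obs, p_ref = obs / lib[j], refv / lib[ref]
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        w = (lib[j] - obs) / (lib[j] * obs) + (lib[ref] - refv) / (lib[ref] * refv)
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = scipy.stats.rankdata(m)
        ra = scipy.stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            continue
        log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])

    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=counts.columns, name="tmm_factor")


def log_cpm(
    counts: pd.DataFrame,
    factors: Optional[pd.Series] = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes.

    value = log2( (count + prior_j) / (eff_lib_j + 2 * prior_j) * 1e6 ) with
    eff_lib_j = factor_j * libsize_j and the prior expressed per million:
    prior_j = prior_count * eff_lib_j / 1e6.  Scaling the prior with the
    effective library makes the value a function of the count fraction
    only, hence exactly invariant to uniform count scaling and to
    rescaling any single sample's depth at fixed composition.
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ExpressionError("zero library size")
    f = (
        np.ones(x.shape[1])
        if factors is None
        else factors.reindex(counts.columns).to_numpy(dtype=float)
    )
    if np.isnan(f).any() or (f <= 0).any():
        raise ExpressionError("invalid TMM factors")
    eff = f * lib
    prior = prior_count * eff / 1e6
    vals = np.log2((x + prior) / (eff + 2.0 * prior) * 1e6)
    out = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    out.attrs["tmm_factors"] = f
    out.attrs["lib_sizes"] = lib
    return out


def normalize_counts(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """Convenience: TMM factors then log2 CPM."""
    return log_cpm(counts, tmm_factors(counts), prior_count=prior_count)


# ---------------------------------------------------------------------------
# Signature scoring


def signature_score(norm: pd.DataFrame, sig: GeneSignature) -> pd.Series:
    """Per-sample score: mean log-scale expression over present signature genes."""
    present = [g for g in sig.genes if g in norm.index]
    if not present:
        raise ExpressionError(f"no genes of signature {sig.name!r} in the matrix")
    s = norm.loc[present].mean(axis=0)
    s.name = sig.name
    s.attrs["n_genes_used"] = len(present)
    return s


@dataclass
class AdjustedMeans:
    means: pd.DataFrame    # index group level; columns: mean, se, n
    contrast_p: float      # p-value for the (first) non-reference group effect
    contrasts: pd.DataFrame  # per non-reference level: estimate, se, t, p
    model: object


def adjusted_group_means(
    scores: Sequence[float],
    group: Sequence[str],
    covariates: Optional[pd.DataFrame] = None,
    weighting: str = "balanced",
) -> AdjustedMeans:
    """Covariate-adjusted (estimated marginal) group means.

    Fits ``score ~ group + covariates`` by least squares, then evaluates
    the fit for each group level averaged over a reference grid of the
    covariates: with ``weighting="balanced"`` each factor-covariate level
    gets equal weight and numeric covariates sit at their mean; with
    ``weighting="observed"`` the observed covariate rows are used.
    """
    y = np.asarray(scores, dtype=float)
    g = pd.Series(group).astype(str).reset_index(drop=True)
    levels = sorted(g.unique())
    if len(levels) < 2:
        raise ExpressionError("adjusted means require >= 2 group levels")
    if weighting not in {"balanced", "observed"}:
        raise ExpressionError(f"unknown weighting {weighting!r}")

    cov = covariates.reset_index(drop=True) if covariates is not None else None

    def design(gvals: pd.Series, cvals: Optional[pd.DataFrame]) -> pd.DataFrame:
        parts = [pd.get_dummies(pd.Categorical(gvals, categories=levels),
                                drop_first=True, dtype=float, prefix="group")]
        if cvals is not None:
            for col in cvals.columns:
                c = cvals[col]
                if pd.api.types.is_numeric_dtype(c) and c.dtype != bool:
                    parts.append(c.astype(float).rename(col).to_frame())
                else:
                    cats = sorted(pd.Series(c).astype(str).unique())
                    parts.append(pd.get_dummies(
                        pd.Categorical(c.astype(str), categories=cats),
                        drop_first=True, dtype=float, prefix=col,
                    ))
        X = pd.concat(parts, axis=1)
        X.insert(0, "Intercept", 1.0)
        return X

    X = design(g, cov)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        u, s, vt = np.linalg.svd(X.to_numpy())
        aliased = [X.columns[i] for i in np.where(np.abs(vt[rank:]).max(axis=0) > 1e-8)[0]]
        raise ExpressionError(f"rank-deficient design; aliased columns: {aliased}")
    fit = sm.OLS(y, X).fit()

    # reference grid: per group level, averaged covariate design vector
    if cov is None:
        grid = pd.DataFrame(index=[0])
        grid_cov = None
    elif weighting == "observed":
        grid_cov = cov.copy()
    else:
        cols = {}
        factor_levels = []
        for col in cov.columns:
            c = cov[col]
            if pd.api.types.is_numeric_dtype(c) and c.dtype != bool:
                cols[col] = [np.nan]  # placeholder; filled below
            else:
                factor_levels.append((col, sorted(pd.Series(c).astype(str).unique())))
        # cartesian product over factor levels, numerics at their mean
        grid_cov = pd.DataFrame(index=[0])
        for col, lv in factor_levels:
            grid_cov = grid_cov.merge(pd.DataFrame({col: lv}), how="cross")
        for col in cov.columns:
            c = cov[col]
            if pd.api.types.is_numeric_dtype(c) and c.dtype != bool:
                grid_cov[col] = float(c.astype(float).mean())
        grid_cov = grid_cov[list(cov.columns)] if len(grid_cov.columns) else None

    rows = []
    covp = fit.cov_params().to_numpy()
    for lv in levels:
        n_grid = 1 if grid_cov is None else len(grid_cov)
        gv = pd.Series([lv] * n_grid)
        Xg = design(gv, grid_cov)
        Xg = Xg.reindex(columns=X.columns, fill_value=0.0)
        cvec = Xg.to_numpy().mean(axis=0)
        est = float(cvec @ fit.params.to_numpy())
        se = float(np.sqrt(cvec @ covp @ cvec))
        rows.append({"group": lv, "mean": est, "se": se, "n": int((g == lv).sum())})
    means = pd.DataFrame(rows).set_index("group")

    contrasts = []
    for lv in levels[1:]:
        name = f"group_{lv}"
        contrasts.append({
            "level": lv,
            "estimate": float(fit.params[name]),
            "se": float(fit.bse[name]),
            "t": float(fit.tvalues[name]),
            "p": float(fit.pvalues[name]),
        })
    contrasts = pd.DataFrame(contrasts).set_index("level")
    return AdjustedMeans(
        means=means, contrast_p=float(contrasts["p"].iloc[0]),
        contrasts=contrasts, model=fit,
    )


# ---------------------------------------------------------------------------
# Pseudobulk


def pseudobulk_aggregate(
    cell_counts: pd.DataFrame,
    cell_meta: pd.DataFrame,
    min_cells: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Sum cell-level counts into (patient, cell type) pseudobulk columns.

    ``cell_meta`` is indexed by cell id with columns ``patient_id`` and
    ``cell_type``.  Cells absent from the metadata or with a missing
    label are excluded and counted in the report.  Columns built from
    fewer than ``min_cells`` cells are flagged (not dropped).
    """
    meta = cell_meta.reindex(cell_counts.columns)
    labeled = meta["patient_id"].notna() & meta["cell_type"].notna()
    n_excluded = int((~labeled).sum())
    kept = cell_counts.loc[:, labeled.to_numpy()]
    keys = list(zip(meta.loc[labeled, "patient_id"], meta.loc[labeled, "cell_type"]))
    cols = pd.MultiIndex.from_tuples(keys, names=["patient_id", "cell_type"])
    kt = kept.T
    kt.index = cols
    pb = kt.groupby(level=["patient_id", "cell_type"]).sum().T
    cell_n = pd.Series(1, index=cols).groupby(level=[0, 1]).sum()
    flagged = [tuple(k) for k in cell_n.index[cell_n < min_cells]]
    report = {
        "n_cells": int(cell_counts.shape[1]),
        "n_excluded_cells": n_excluded,
        "n_columns": int(pb.shape[1]),
        "cells_per_column": cell_n,
        "flagged_columns": flagged,
    }
    return pb, report


def celltype_signature_profile(
    pb: pd.DataFrame, sig: GeneSignature, prior_count: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signature scores per (patient, cell type) pseudobulk column.

    Pseudobulk counts are TMM + log2-CPM normalized across columns, the
    signature is scored per column, and per-cell-type medians are ranked
    (1 = highest median score).
    """
    if pb.shape[1] == 0:
        raise ExpressionError("empty pseudobulk matrix")
    norm = normalize_counts(pb, prior_count=prior_count)
    scores = signature_score(norm, sig)
    table = scores.rename("score").reset_index()
    summary = (
        table.groupby("cell_type")["score"]
        .median()
        .rename("median_score")
        .to_frame()
        .sort_values("median_score", ascending=False)
    )
    summary["rank"] = np.arange(1, len(summary) + 1)
    return table, summary
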