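"""Per-gene differential expression and preranked gene-set enrichment.

Differential expression fits, for every gene, an ordinary least-squares
model of log-scale expression on a two-level group factor plus optional
covariates; the group coefficient is the log2 fold change and its
t-statistic carries the test.  An optional simple variance-shrinkage
mode pools gene-wise residual variances toward their mean with a fixed
prior weight.  Paired designs are handled by a one-sample t-test on
within-patient (post - pre) differences.  Multiple testing uses the
Benjamini-Hochberg step-up.  Enrichment follows the weighted
Kolmogorov-Smirnov running-sum statistic on a ranked gene list, with
significance from gene-label permutations and sign-matched
normalization of the enrichment score (NES).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .expression import GeneSignature


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; stable under input reordering."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design_matrix(
    n: int, group: Sequence, covariates: Optional[pd.DataFrame],
    reference: Optional[str] = None,
) -> tuple[np.ndarray, list]:
    g = pd.Series(group).astype(str).reset_index(drop=True)
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    if reference is not None:
        if str(reference) not in levels:
            raise ValueError(f"reference level {reference!r} not in {levels}")
        levels = [str(reference)] + [lv for lv in levels if lv != str(reference)]
    cols = [np.ones(n), (g == levels[1]).to_numpy(dtype=float)]
    names = ["Intercept", f"group_{levels[1]}"]
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        for col in cov.columns:
            c = cov[col]
            if pd.api.types.is_numeric_dtype(c) and c.dtype != bool:
                cols.append(c.to_numpy(dtype=float))
                names.append(col)
            else:
                cats = sorted(pd.Series(c).astype(str).unique())
                for lv in cats[1:]:
                    cols.append((c.astype(str) == lv).to_numpy(dtype=float))
                    names.append(f"{col}_{lv}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return X, names


def fit_gene_linear_models(
    norm: pd.DataFrame,
    group: Sequence,
    covariates: Optional[pd.DataFrame] = None,
    moderation: bool = False,
    prior_df: float = 4.0,
    reference: Optional[str] = None,
) -> pd.DataFrame:
    """Per-gene least-squares DE against a two-level group factor.

    Returns a DataFrame indexed by gene with ``log2_fc`` (the group
    coefficient: non-reference level vs ``reference``, defaulting to the
    first sorted level as reference), ``t_stat``, ``p_value``,
    ``q_value``, ``df`` and a ``zero_variance`` flag.  With
    ``moderation=True`` residual variances are shrunk toward their mean:
    s2_g' = (d0 * s0^2 + df * s2_g) / (d0 + df) with d0 = ``prior_df``,
    and the t reference distribution gains the prior degrees of freedom.
    """
    Y = norm.to_numpy(dtype=float).T  # samples x genes
    n = Y.shape[0]
    X, names = _design_matrix(n, group, covariates, reference=reference)
    gcol = 1  # group indicator column
    for lv in pd.Series(group).astype(str).unique():
        counts = (pd.Series(group).astype(str) == lv).sum()
        if counts < 2:
            raise ValueError(f"group level {lv!r} has fewer than 2 samples")

    pinv = np.linalg.pinv(X)
    beta = pinv @ Y                          # p x genes
    resid = Y - X @ beta
    rank = X.shape[1]
    df = n - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = (resid ** 2).sum(axis=0) / df
    zero_var = s2 <= 1e-18  # numerically constant gene

    xtx_inv = np.linalg.inv(X.T @ X)
    c_gg = xtx_inv[gcol, gcol]

    if moderation:
        s0_sq = float(np.mean(s2[~zero_var])) if (~zero_var).any() else 0.0
        s2_used = (prior_df * s0_sq + df * s2) / (prior_df + df)
        df_used = df + prior_df
    else:
        s2_used = s2
        df_used = float(df)

    se = np.sqrt(np.maximum(s2_used, 1e-300) * c_gg)
    t = np.where(zero_var, 0.0, beta[gcol] / se)
    p = np.where(zero_var, 1.0, 2.0 * scipy.stats.t.sf(np.abs(t), df_used))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "log2_fc": beta[gcol],
            "t_stat": t,
            "p_value": p,
            "q_value": bh_adjust(p),
            "df": df_used,
            "zero_variance": zero_var,
        },
        index=norm.index,
    )
    out.attrs["design_columns"] = names
    return out


def paired_difference_test(
    norm: pd.DataFrame, pairs: Mapping[str, tuple]
) -> pd.DataFrame:
    """Per-gene one-sample t-test on within-patient (post - pre) differences.

    ``pairs`` maps patient id to (pre_sample, post_sample) column names.
    Incomplete pairs (either column missing from the matrix) are dropped
    and reported in ``attrs["dropped_pairs"]``.  This is a deliberately
    simple treatment of intrapatient correlation: differencing removes
    the patient-level term exactly in a paired design.
    """
    complete, dropped = [], []
    for pid, (pre, post) in pairs.items():
        if pre in norm.columns and post in norm.columns:
            complete.append((pid, pre, post))
        else:
            dropped.append(pid)
    if len(complete) < 3:
        raise ValueError(
            f"paired test requires >= 3 complete pairs, got {len(complete)}"
        )
    d = np.column_stack(
        [norm[post].to_numpy() - norm[pre].to_numpy() for _, pre, post in complete]
    )
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    zero_var = sd <= 1e-12
    se = np.where(zero_var, np.inf, sd / np.sqrt(n))
    t = np.where(zero_var, 0.0, mean / se)
    p = np.where(zero_var, 1.0, 2.0 * scipy.stats.t.sf(np.abs(t), n - 1))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "log2_fc": mean,
            "t_stat": t,
            "p_value": p,
            "q_value": bh_adjust(p),
            "df": float(n - 1),
            "zero_variance": zero_var,
        },
        index=norm.index,
    )
    out.attrs["dropped_pairs"] = dropped
    out.attrs["n_pairs"] = n
    return out


# ---------------------------------------------------------------------------
# Preranked enrichment


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    q_value: float
    leading_edge: tuple
    n_hits: int


def _order_ranking(ranking: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Sort descending by stat, ties broken by gene symbol ascending."""
    df = pd.DataFrame({"gene": ranking.index.astype(str), "stat": ranking.to_numpy()})
    df = df.sort_values(["stat", "gene"], ascending=[False, True], kind="mergesort")
    return df["gene"].to_numpy(), df["stat"].to_numpy(dtype=float)


def _es_at_positions(
    pos_sorted: np.ndarray, weights: np.ndarray, n_total: int
) -> tuple[float, int]:
    """Enrichment score for hit positions (sorted ascending, 2-d supported).

    The running sum increases by weight/sum(weights) at each hit and
    decreases by 1/(N - n_hits) at each miss; only values at and just
    before hits are extrema candidates, so the full N-length walk is
    unnecessary.  Returns (ES, index-of-extremum-hit) for 1-d input.
    """
    k = pos_sorted.shape[-1]
    miss = 1.0 / (n_total - k)
    wsum = weights.sum(axis=-1, keepdims=True)
    wsum = np.where(wsum == 0, 1.0, wsum)
    cum_hit = np.cumsum(weights, axis=-1) / wsum
    ranks = np.arange(1, k + 1, dtype=float)
    misses_before = (pos_sorted + 1 - ranks) * miss
    after = cum_hit - misses_before            # running sum just after each hit
    before = after - weights / wsum            # just before each hit
    top = after.max(axis=-1)
    bottom = before.min(axis=-1)
    es = np.where(top >= -bottom, top, bottom)
    if pos_sorted.ndim == 1:
        idx = int(np.argmax(after)) if top >= -bottom else int(np.argmin(before))
        return float(es), idx
    return es, None


def preranked_enrichment(
    ranking: pd.Series,
    sets: Iterable[GeneSignature],
    weight_exp: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> tuple[pd.DataFrame, list]:
    """Preranked gene-set enrichment with permutation NES.

    Genes are ranked by the statistic (descending, stable gene-symbol
    tie-break).  For each set the weighted running-sum enrichment score
    is computed (hit increments proportional to |stat|^weight_exp); the
    null is gene-label permutation: ``n_perm`` random same-size sets.
    NES = ES / mean(|permuted ES| of the same sign); the p-value is the
    same-sign permutation tail with the +1 correction; q-values are BH
    across the retained sets.  Sets falling outside [min_size, max_size]
    after intersection with the ranking are skipped with a warning; a
    set covering every ranked gene is an error (the miss decrement is
    undefined).

    Returns ``(results DataFrame, warnings)``.
    """
    genes, stats = _order_ranking(ranking)
    n_total = genes.size
    gene_pos = {g: i for i, g in enumerate(genes)}
    w_all = np.abs(stats) ** weight_exp
    rng = np.random.default_rng(seed)

    rows, warnings, leading = [], [], {}
    for sig in sets:
        pos = np.array(sorted(gene_pos[g] for g in sig.genes if g in gene_pos))
        if pos.size == 0:
            warnings.append(f"set {sig.name!r} has no genes in the ranking; skipped")
            continue
        if pos.size >= n_total:
            raise ValueError(
                f"set {sig.name!r} covers all ranked genes; ES undefined"
            )
        if not (min_size <= pos.size <= max_size):
            warnings.append(
                f"set {sig.name!r}: size {pos.size} outside "
                f"[{min_size}, {max_size}]; skipped"
            )
            continue
        k = pos.size
        es, ext_idx = _es_at_positions(pos, w_all[pos], n_total)
        if es >= 0:
            lead = tuple(genes[pos[: ext_idx + 1]])
        else:
            lead = tuple(genes[pos[ext_idx:]][::-1])

        # permutation null: random k-subsets of the ranked genes
        perm_pos = np.sort(
            rng.random((n_perm, n_total)).argpartition(k - 1, axis=1)[:, :k], axis=1
        )
        perm_es, _ = _es_at_positions(perm_pos, w_all[perm_pos], n_total)
        same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            nes, p = np.nan, 1.0 / (n_perm + 1)
        else:
            denom = float(np.mean(np.abs(perm_es[same_sign])))
            nes = es / denom if denom > 0 else np.nan
            tail = int(np.sum(np.abs(perm_es[same_sign]) >= abs(es)))
            p = (1.0 + tail) / (1.0 + n_same)
        rows.append({
            "set_name": sig.name, "es": es, "nes": nes, "p_value": p,
            "n_hits": k,
        })
        leading[sig.name] = lead

    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        df = df.set_index("set_name")
    results = [
        EnrichmentResult(
            set_name=name, es=float(r["es"]), nes=float(r["nes"]),
            p_value=float(r["p_value"]), q_value=float(r["q_value"]),
            leading_edge=leading[name], n_hits=int(r["n_hits"]),
        )
        for name, r in df.iterrows()
    ] if len(df) else []
    df.attrs["warnings"] = warnings
    return df, results
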