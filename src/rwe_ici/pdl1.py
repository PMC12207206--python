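"""PD-L1 IHC class imputation from CD274 mRNA expression.

Tumor PD-L1 IHC status (tumor proportion score bins <1%, 1-49%, >=50%)
is often missing in real-world cohorts.  Because CD274 encodes PD-L1,
its normalized mRNA level can stand in: on samples with both IHC and
RNA-seq, we search every candidate expression threshold and keep the one
maximizing Cohen's kappa against the binary IHC label.  Two binary
models (>=1% and >=50%) combine into the three-class call; an observed
IHC value always overrides imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

TARGET_CLASSES = ("ge1", "ge50")


def cohen_kappa(confusion) -> float:
    """Cohen's kappa for a 2x2 confusion matrix [[TP, FN], [FP, TN]].

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the chance agreement from the marginals.  For a constant table
    (p_e = 1) kappa is defined as 0.
    """
    m = np.asarray(confusion, dtype=float)
    if m.shape != (2, 2):
        raise ValueError("confusion matrix must be 2x2")
    if (m < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    n = m.sum()
    if n <= 0:
        raise ValueError("confusion matrix must have positive total count")
    p_o = (m[0, 0] + m[1, 1]) / n
    row = m.sum(axis=1) / n
    col = m.sum(axis=0) / n
    p_e = row @ col
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _confusion(expr: np.ndarray, labels: np.ndarray, t: float) -> np.ndarray:
    pred = expr >= t
    tp = np.sum(pred & labels)
    fn = np.sum(~pred & labels)
    fp = np.sum(pred & ~labels)
    tn = np.sum(~pred & ~labels)
    return np.array([[tp, fn], [fp, tn]], dtype=float)


def _metrics(conf: np.ndarray) -> tuple[float, float, float]:
    tp, fn = conf[0]
    fp, tn = conf[1]
    acc = (tp + tn) / conf.sum()
    sens = tp / (tp + fn) if tp + fn > 0 else np.nan
    spec = tn / (tn + fp) if tn + fp > 0 else np.nan
    return float(acc), float(sens), float(spec)


@dataclass(frozen=True)
class ThresholdModel:
    target_class: str          # "ge1" | "ge50"
    threshold: float           # log2 CPM cut; expr >= threshold -> positive
    kappa: float
    accuracy: float
    sensitivity: float
    specificity: float
    n_train: int

    def predict(self, expr) -> np.ndarray:
        return np.asarray(expr, dtype=float) >= self.threshold


def fit_expression_threshold(
    expr: Sequence[float],
    labels: Sequence[bool],
    target_class: str = "ge50",
    grid: str = "observed",
) -> ThresholdModel:
    """Exhaustive kappa-maximal threshold search.

    The candidate grid is the sorted unique observed expression values
    (``grid="midpoints"`` switches to midpoints between consecutive
    uniques).  Prediction at threshold t is ``expr >= t``; ties in kappa
    break to the smallest threshold.
    """
    if target_class not in TARGET_CLASSES:
        raise ValueError(f"unknown target class {target_class!r}")
    x = np.asarray(expr, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expr and labels must be aligned 1-d sequences")
    if y.all() or (~y).all():
        raise ValueError(
            "threshold fitting requires both IHC classes in the training labels"
        )
    uniq = np.unique(x)
    if grid == "observed":
        candidates = uniq
    elif grid == "midpoints":
        if uniq.size < 2:
            raise ValueError("midpoint grid requires >= 2 distinct values")
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    else:
        raise ValueError(f"unknown grid {grid!r}")

    best_t, best_k = None, -np.inf
    for t in candidates:  # ascending, so the smallest t wins ties
        k = cohen_kappa(_confusion(x, y, t))
        if k > best_k:
            best_t, best_k = float(t), k
    conf = _confusion(x, y, best_t)
    acc, sens, spec = _metrics(conf)
    return ThresholdModel(
        target_class=target_class, threshold=best_t, kappa=best_k,
        accuracy=acc, sensitivity=sens, specificity=spec, n_train=int(x.size),
    )


def evaluate_threshold(
    model: ThresholdModel, expr: Sequence[float], labels: Sequence[bool]
) -> dict:
    """Confusion-matrix metrics of a fitted threshold on held-out data."""
    x = np.asarray(expr, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if x.size == 0:
        raise ValueError("evaluation set is empty")
    if y.all() or (~y).all():
        raise ValueError("evaluation requires both classes")
    conf = _confusion(x, y, model.threshold)
    acc, sens, spec = _metrics(conf)
    return {
        "accuracy": acc, "sensitivity": sens, "specificity": spec,
        "kappa": cohen_kappa(conf), "n": int(x.size),
    }


def classify_pdl1(
    model_ge1: ThresholdModel,
    model_ge50: ThresholdModel,
    expr: Sequence[float],
    observed: Optional[Iterable[Optional[str]]] = None,
) -> list:
    """Three-class PD-L1 call from the two binary threshold models.

    ``expr >= t_ge50 -> ge50``, else ``expr >= t_ge1 -> r1_49``, else
    ``lt1``.  Requires ``t_ge1 <= t_ge50`` for coherence.  When an
    ``observed`` IHC class is provided for a sample it always wins.
    """
    if model_ge1.target_class != "ge1" or model_ge50.target_class != "ge50":
        raise ValueError("models must target ge1 and ge50 respectively")
    if model_ge1.threshold > model_ge50.threshold:
        raise ValueError(
            f"incoherent model pair: t_ge1={model_ge1.threshold} > "
            f"t_ge50={model_ge50.threshold}"
        )
    x = np.asarray(expr, dtype=float)
    obs = list(observed) if observed is not None else [None] * x.size
    if len(obs) != x.size:
        raise ValueError("observed labels must align with expr")
    out = []
    for value, o in zip(x, obs):
        if o is not None:
            out.append(o)
        elif value >= model_ge50.threshold:
            out.append("ge50")
        elif value >= model_ge1.threshold:
            out.append("r1_49")
        else:
            out.append("lt1")
    return out
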