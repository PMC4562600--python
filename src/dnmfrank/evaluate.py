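"""Benchmarking a gene ranking against known fold-change truth.

The benchmark treats ranking as a retrieval problem: at a given |log2
fold change| cutoff, genes at or above the cutoff are the positives and
the AUC measures how well the score magnitude separates them from the
rest (Mann-Whitney formulation, ties at half credit).  The canonical
cutoffs are 0.58, 1 and 2, plus a 0.5..2 sweep in steps of 0.1; an MA
table (mean log2 expression vs between-class log2 ratio, with the top-k
scored genes flagged) supports the usual bias diagnostics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import ExpressionMatrix

__all__ = [
    "DEFAULT_THRESHOLDS",
    "sweep_thresholds",
    "roc_auc",
    "benchmark_thresholds",
    "ma_data",
]

DEFAULT_THRESHOLDS = (0.58, 1.0, 2.0)


def sweep_thresholds() -> np.ndarray:
    """The |logFC| sweep 0.5, 0.6, ..., 2.0."""
    return np.round(np.arange(0.5, 2.0 + 1e-9, 0.1), 10)


def roc_auc(scores, truth) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 * P(tie).

    ``truth`` is binary; raises if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must align")
    if truth.all() or not truth.any():
        raise ValueError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(truth, scores))


def benchmark_thresholds(
    scores,
    true_logfc,
    thresholds=DEFAULT_THRESHOLDS,
    absolute: bool = True,
) -> pd.DataFrame:
    """AUC per |logFC| threshold; one row per threshold.

    Positives at threshold ``t`` are genes with ``|true_logfc| >= t``.  By
    default the score magnitude is used (two-sided benchmark); set
    ``absolute=False`` to rank by the signed score.  Thresholds that leave
    an empty class yield ``auc = NaN`` with ``defined = False`` rather
    than a silent 0.
    """
    scores = np.asarray(scores, dtype=float)
    true_logfc = np.asarray(true_logfc, dtype=float)
    if scores.shape != true_logfc.shape:
        raise ValueError("scores and true_logfc must align")
    use = np.abs(scores) if absolute else scores
    rows = []
    for t in np.atleast_1d(thresholds):
        if t <= 0:
            raise ValueError("thresholds must be positive")
        positive = np.abs(true_logfc) >= t
        n_pos, n_neg = int(positive.sum()), int((~positive).sum())
        defined = n_pos > 0 and n_neg > 0
        rows.append(
            {
                "threshold": float(t),
                "auc": roc_auc(use, positive) if defined else float("nan"),
                "n_positive": n_pos,
                "n_negative": n_neg,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


def ma_data(
    V,
    labels,
    scores,
    top_k: int = 1000,
    gene_ids=None,
) -> pd.DataFrame:
    """Per-gene MA table from log2 expression.

    ``A`` is the mean over all samples, ``M`` the treatment-minus-control
    difference of class means; ``is_top`` flags the ``top_k`` genes by
    score magnitude.  ``labels`` is the per-sample class index (control =
    0) or label array.
    """
    if isinstance(V, ExpressionMatrix):
        if gene_ids is None:
            gene_ids = V.gene_ids
        V = V.values
    V = np.asarray(V, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind not in "iu":
        _, first = np.unique(y, return_index=True)
        order = y[np.sort(first)]
        lut = {c: r for r, c in enumerate(order)}
        y = np.array([lut[c] for c in y], dtype=np.intp)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("MA data requires exactly two classes")
    scores = np.asarray(scores, dtype=float)
    n = V.shape[0]
    if scores.shape[0] != n:
        raise ValueError("one score per gene is required")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    if top_k > n:
        warnings.warn(f"top_k={top_k} exceeds {n} genes; flagging all", stacklevel=2)
        top_k = n
    A = V.mean(axis=1)
    M = V[:, y == 1].mean(axis=1) - V[:, y == 0].mean(axis=1)
    is_top = np.zeros(n, dtype=bool)
    is_top[np.argsort(-np.abs(scores), kind="stable")[:top_k]] = True
    return pd.DataFrame(
        {"gene_id": list(gene_ids), "A": A, "M": M, "is_top": is_top}
    )
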