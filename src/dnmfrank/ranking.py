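"""Metagene orientation, the gene-ranking statistic, and permutation P-values.

After a two-metagene fit, the rows of ``H`` are identified as the up- and
down-regulated metagene by comparing class means: row ``k`` is
down-regulated if its mean coefficient is higher in the control class than
in the treatment class, up-regulated in the opposite case.  Genes are then
ranked by

    d_i = W[i, up] - W[i, down],

so positive ``d`` marks up-regulation in the treatment class and the
magnitude orders genes by the strength of the differential signal.  An
empirical P-value per gene is obtained by shuffling all entries of ``W``
jointly ``B`` times, recomputing the column difference, and counting how
often a permuted magnitude exceeds the observed one, pooled over genes:

    p_i = (1 / (n B)) * sum_b sum_j 1[ |d_i| < |d^b_j| ].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dnmf import DiscriminantNMF, class_statistics
from .io import ClassLabels, CountMatrix, normalize_log, size_factors

__all__ = [
    "MetageneOrientation",
    "orient_metagenes",
    "rank_genes",
    "permutation_pvalues",
    "write_rnk",
    "read_rnk",
    "DNMFRanker",
    "rank_from_counts",
]


@dataclass
class MetageneOrientation:
    """Which row of ``H`` is the up- and which the down-regulated metagene."""

    up_row: int | None
    down_row: int | None
    degenerate: bool

    def __post_init__(self) -> None:
        if not self.degenerate and self.up_row == self.down_row:
            raise ValueError("up and down metagene must differ")


def orient_metagenes(H, labels) -> MetageneOrientation:
    """Assign up/down roles to the two rows of ``H`` by class means.

    Row ``k`` is down-regulated if its control-class mean exceeds its
    treatment-class mean, up-regulated if it is lower.  The orientation is
    degenerate — and the fit must be rerun — when both rows fall on the
    same side or any class means tie exactly.
    """
    H = np.asarray(H, dtype=float)
    if H.shape[0] != 2:
        raise ValueError("orientation is defined for exactly two metagenes")
    stats = class_statistics(H, labels)
    if stats.class_means.shape[0] != 2:
        raise ValueError("orientation is defined for exactly two classes")
    control, treatment = stats.class_means  # (K,) each
    up, down = [], []
    for k in range(2):
        if control[k] < treatment[k]:
            up.append(k)
        elif control[k] > treatment[k]:
            down.append(k)
        # ties fall through: neither role
    if len(up) == 1 and len(down) == 1:
        return MetageneOrientation(up_row=up[0], down_row=down[0], degenerate=False)
    return MetageneOrientation(up_row=None, down_row=None, degenerate=True)


def _direction(d: np.ndarray) -> np.ndarray:
    return np.where(d > 0, "up", np.where(d < 0, "down", "neutral"))


def rank_genes(W, orientation: MetageneOrientation, gene_ids=None) -> pd.DataFrame:
    """Ranking table sorted descending by ``d = W[:, up] - W[:, down]``.

    Ties keep the input gene order (stable sort).  Columns: ``gene_id``,
    ``d``, ``rank`` (1 = largest d), ``direction``.
    """
    if orientation.degenerate:
        raise ValueError(
            "degenerate metagene orientation: rerun the factorization with a "
            "different seed before ranking"
        )
    W = np.asarray(W, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(W.shape[0])]
    d = W[:, orientation.up_row] - W[:, orientation.down_row]
    order = np.argsort(-d, kind="stable")
    result = pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids, dtype=object)[order],
            "d": d[order],
            "rank": np.arange(1, len(d) + 1),
            "direction": _direction(d[order]),
        }
    ).reset_index(drop=True)
    return result


def permutation_pvalues(
    W,
    orientation: MetageneOrientation,
    B: int = 1000,
    random_state: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Pooled permutation P-values for ``d`` (input gene order).

    The null — the weight matrix carries no discriminative structure — is
    simulated by jointly shuffling all ``n * K`` entries of ``W`` and
    re-taking the up-minus-down column difference.  For gene ``i``,
    ``p_i`` is the fraction of all ``n * B`` permuted magnitudes strictly
    exceeding ``|d_i|``.
    """
    if B < 1:
        raise ValueError("at least one permutation is required")
    if orientation.degenerate:
        raise ValueError("degenerate orientation: no d statistic to test")
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    d = W[:, orientation.up_row] - W[:, orientation.down_row]
    rng = (
        random_state
        if isinstance(random_state, np.random.Generator)
        else np.random.default_rng(random_state)
    )
    flat = W.ravel()
    perm_abs = np.empty(n * B)
    for b in range(B):
        shuffled = rng.permutation(flat).reshape(W.shape)
        perm_abs[b * n : (b + 1) * n] = np.abs(
            shuffled[:, orientation.up_row] - shuffled[:, orientation.down_row]
        )
    perm_abs.sort()
    # count of permuted |d^b_j| strictly greater than |d_i|
    exceed = n * B - np.searchsorted(perm_abs, np.abs(d), side="right")
    return exceed / (n * B)


def write_rnk(result: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the GSEAPreranked ``.rnk`` dialect.

    Two tab-separated columns — gene identifier, then ``d`` — sorted
    descending by ``d``, no header.
    """
    if len(result) == 0:
        raise ValueError("refusing to write an empty ranking")
    out = result.sort_values("d", ascending=False, kind="stable")
    out[["gene_id", "d"]].to_csv(path, sep="\t", header=False, index=False)


def read_rnk(path: Union[str, Path]) -> pd.DataFrame:
    """Read a ``.rnk`` file back into a (gene_id, d) table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "d"], dtype={0: str})
    if df["d"].isna().any():
        raise ValueError(f"malformed score in {path}")
    return df


class DNMFRanker(BaseEstimator):
    """Rank genes between two conditions by discriminant NMF.

    End-to-end: median-of-ratios size factors, ``log2(count/sf + pc)``
    transform, two-metagene discriminant factorization (rerun on
    degenerate orientation), the ``d = W_up - W_down`` statistic, and
    optional pooled permutation P-values.

    ``X`` is samples x genes **raw counts**; ``y`` is one class label per
    sample, the first label encountered being the control.

    Attributes (after ``fit``)
    --------------------------
    size_factors_ : per-sample normalization factors.
    model_ : the fitted :class:`~dnmfrank.dnmf.DiscriminantNMF`.
    orientation_ : which metagene is up-/down-regulated.
    d_ : per-gene statistic, in input gene order.
    pvalues_ : per-gene permutation P-values (if ``n_permutations > 0``).
    results_ : tidy ranking table sorted descending by ``d``.
    """

    def __init__(
        self,
        gamma: float = 0.1,
        delta: float = 1e-4,
        pseudocount: float = 1.0,
        max_iter: int = 1000,
        tol: float = 1e-6,
        n_permutations: int = 1000,
        max_reruns: int = 10,
        random_state: int | None = 0,
    ) -> None:
        self.gamma = gamma
        self.delta = delta
        self.pseudocount = pseudocount
        self.max_iter = max_iter
        self.tol = tol
        self.n_permutations = n_permutations
        self.max_reruns = max_reruns
        self.random_state = random_state

    def fit(self, X, y, gene_ids=None):
        if isinstance(X, pd.DataFrame):
            if gene_ids is None:
                gene_ids = list(X.columns)
            X = X.to_numpy()
        X = np.asarray(X)
        seed = 0 if self.random_state is None else int(self.random_state)
        self.size_factors_ = size_factors(X.T)
        V = normalize_log(X.T, self.size_factors_, self.pseudocount)
        model = DiscriminantNMF(
            n_components=2,
            gamma=self.gamma,
            delta=self.delta,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=seed,
            max_reruns=self.max_reruns,
            ensure_orientation=True,
        )
        model.fit(V.T, np.asarray(y))
        self.model_ = model
        self.orientation_ = orient_metagenes(
            model.H_, _labels_to_index(y)
        )
        self.d_ = (
            model.W_[:, self.orientation_.up_row]
            - model.W_[:, self.orientation_.down_row]
        )
        self.results_ = rank_genes(model.W_, self.orientation_, gene_ids)
        if self.n_permutations > 0:
            # independent stream so ranking and fitting stay decoupled
            perm_rng = np.random.default_rng((seed + 7_919) % 2**31)
            pvals = permutation_pvalues(
                model.W_, self.orientation_, self.n_permutations, perm_rng
            )
            self.pvalues_ = pvals
            if gene_ids is None:
                gene_ids = [f"g{i}" for i in range(len(pvals))]
            lut = dict(zip((str(g) for g in gene_ids), pvals))
            self.results_["p_value"] = [lut[str(g)] for g in self.results_["gene_id"]]
        return self

    def fit_predict(self, X, y, gene_ids=None) -> pd.DataFrame:
        """Fit and return the ranking table."""
        return self.fit(X, y, gene_ids=gene_ids).results_


def _labels_to_index(y) -> np.ndarray:
    y = np.asarray(y)
    _, first = np.unique(y, return_index=True)
    order = y[np.sort(first)]
    lut = {c: r for r, c in enumerate(order)}
    return np.array([lut[c] for c in y], dtype=np.intp)


def rank_from_counts(
    counts: CountMatrix,
    labels: ClassLabels,
    **ranker_params,
) -> pd.DataFrame:
    """Convenience wrapper: counts + labels in, ranking table out."""
    idx = labels.indices(counts.sample_ids)
    if labels.R != 2:
        raise ValueError("gene ranking requires exactly two sample classes")
    ranker = DNMFRanker(**ranker_params)
    ranker.fit(counts.values.T, idx, gene_ids=counts.gene_ids)
    return ranker.results_
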