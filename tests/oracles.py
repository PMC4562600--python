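"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, literal way (explicit
loops, direct summation) and shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def leeseung_update_H(V, W, H):
    """Standard Lee-Seung KL multiplicative update for H, entry by entry."""
    V, W, H = (np.asarray(x, dtype=float) for x in (V, W, H))
    WH = W @ H
    out = np.empty_like(H)
    for k in range(H.shape[0]):
        for l in range(H.shape[1]):
            num = sum(W[i, k] * V[i, l] / WH[i, l] for i in range(V.shape[0]))
            den = sum(W[i, k] for i in range(V.shape[0]))
            out[k, l] = H[k, l] * num / den
    return out


def leeseung_update_W(V, W, H):
    """Standard Lee-Seung KL multiplicative update for W, entry by entry."""
    V, W, H = (np.asarray(x, dtype=float) for x in (V, W, H))
    WH = W @ H
    out = np.empty_like(W)
    for i in range(W.shape[0]):
        for k in range(W.shape[1]):
            num = sum(H[k, l] * V[i, l] / WH[i, l] for l in range(V.shape[1]))
            den = sum(H[k, l] for l in range(V.shape[1]))
            out[i, k] = W[i, k] * num / den
    return out


def column_normalize(W):
    W = np.asarray(W, dtype=float).copy()
    for k in range(W.shape[1]):
        W[:, k] /= W[:, k].sum()
    return W


def kl_direct(V, WH):
    """Direct double-loop generalized KL with the 0*ln0 = 0 convention."""
    total = 0.0
    V, WH = np.asarray(V, dtype=float), np.asarray(WH, dtype=float)
    for i in range(V.shape[0]):
        for l in range(V.shape[1]):
            v, x = V[i, l], WH[i, l]
            if v > 0:
                total += v * math.log(v / x) - v + x
            else:
                total += x
    return total


def scatter_direct(H, class_index):
    """Double-summation within/between-class scatter matrices."""
    H = np.asarray(H, dtype=float)
    idx = np.asarray(class_index)
    K, L = H.shape
    classes = sorted(set(idx.tolist()))
    mu_r = {r: H[:, idx == r].mean(axis=1) for r in classes}
    mu = H.sum(axis=1) / L
    Sw = np.zeros((K, K))
    for r in classes:
        for col in np.where(idx == r)[0]:
            dev = H[:, col] - mu_r[r]
            Sw += np.outer(dev, dev)
    Sb = np.zeros((K, K))
    for r in classes:
        Nr = int((idx == r).sum())
        dev = mu_r[r] - mu
        Sb += Nr * np.outer(dev, dev)
    return Sw, Sb


def objective_direct(V, W, H, class_index, gamma, delta):
    Sw, Sb = scatter_direct(H, class_index)
    return kl_direct(V, np.asarray(W) @ np.asarray(H)) + gamma * np.trace(
        Sw
    ) - delta * np.trace(Sb)


def median_of_ratios(counts):
    """Brute-force DESeq-style size factors."""
    counts = np.asarray(counts, dtype=float)
    geomeans = [
        math.exp(sum(math.log(c) for c in row) / len(row)) if all(c > 0 for c in row)
        else 0.0
        for row in counts
    ]
    sf = []
    for j in range(counts.shape[1]):
        ratios = [
            counts[i, j] / geomeans[i]
            for i in range(counts.shape[0])
            if geomeans[i] > 0
        ]
        sf.append(float(np.median(ratios)))
    return np.array(sf)


def auc_pairwise(scores, truth):
    """O(n^2) Mann-Whitney AUC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    pos = scores[truth]
    neg = scores[~truth]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def pooled_pvalues_direct(d_obs, permuted_d):
    """Eq-by-the-book pooled permutation P-values.

    ``permuted_d`` is a list of B arrays, each the permuted statistic for
    all n genes.
    """
    d_obs = np.asarray(d_obs, dtype=float)
    n = len(d_obs)
    B = len(permuted_d)
    p = np.zeros(n)
    for i in range(n):
        count = 0
        for b in range(B):
            for j in range(n):
                if abs(d_obs[i]) < abs(permuted_d[b][j]):
                    count += 1
        p[i] = count / (n * B)
    return p
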