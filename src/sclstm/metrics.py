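"""External clustering validation: NMI, Hungarian-mapped ACC, ARI, BAS.

All indices are computed from the contingency table of the two partitions
and are invariant to consistent relabeling of either side.
"""

from __future__ import annotations

from math import comb, log
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment


def _as_codes(labels: Sequence) -> tuple[np.ndarray, list]:
    arr = np.asarray(labels)
    uniq, codes = np.unique(arr, return_inverse=True)
    return codes, uniq.tolist()


def contingency(T: Sequence, P: Sequence) -> np.ndarray:
    """k_T x k_P table of co-occurrence counts n_ij."""
    t, _ = _as_codes(T)
    p, _ = _as_codes(P)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    table = np.zeros((t.max() + 1, p.max() + 1), dtype=np.int64)
    np.add.at(table, (t, p), 1)
    return table


def nmi(T: Sequence, P: Sequence) -> float:
    """Normalized mutual information 2 I(T,P) / (H(T) + H(P)).

    Natural-log entropies (the ratio is base-invariant). Returns 0 when both
    partitions are single-cluster (zero total entropy).
    """
    table = contingency(T, P)
    n = table.sum()
    if n == 0:
        raise ValueError("empty label vectors")
    pij = table / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    h_t = -sum(p * log(p) for p in pi if p > 0)
    h_p = -sum(p * log(p) for p in pj if p > 0)
    if h_t + h_p == 0:
        return 0.0
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            if pij[i, j] > 0:
                mi += pij[i, j] * log(pij[i, j] / (pi[i] * pj[j]))
    return float(2.0 * mi / (h_t + h_p))


def _hungarian_map(table: np.ndarray) -> dict[int, int]:
    """Optimal injective map of predicted-class index -> true-class index.

    Rectangular tables are zero-padded to square; predicted classes matched
    to a padding column receive -1 (no true counterpart, counted as errors).
    """
    k_t, k_p = table.shape
    size = max(k_t, k_p)
    cost = np.zeros((size, size), dtype=np.int64)
    cost[:k_t, :k_p] = table
    rows, cols = linear_sum_assignment(-cost)
    mapping = {}
    for r, c in zip(rows, cols):
        if c < k_p:
            mapping[int(c)] = int(r) if r < k_t else -1
    return mapping


def acc(T: Sequence, P: Sequence) -> float:
    """Clustering accuracy: max agreement over one-to-one label mappings."""
    table = contingency(T, P)
    mapping = _hungarian_map(table)
    n = table.sum()
    matched = sum(
        table[t_idx, p_idx]
        for p_idx, t_idx in mapping.items()
        if t_idx >= 0
    )
    return float(matched / n)


def map_labels(T: Sequence, P: Sequence) -> np.ndarray:
    """Rewrite P onto T's label set via the Hungarian assignment.

    Predicted classes without a true counterpart keep synthetic labels of the
    form ``"unmapped<i>"`` so they can never agree with any true label.
    """
    t_codes, t_uniq = _as_codes(T)
    p_codes, _ = _as_codes(P)
    if len(t_codes) != len(p_codes):
        raise ValueError("length mismatch")
    table = contingency(T, P)
    mapping = _hungarian_map(table)
    out = np.empty(len(p_codes), dtype=object)
    for i, code in enumerate(p_codes):
        t_idx = mapping.get(int(code), -1)
        out[i] = t_uniq[t_idx] if t_idx >= 0 else f"unmapped{code}"
    return out


def ari(T: Sequence, P: Sequence) -> float:
    """Adjusted Rand index via binomial coefficients over the contingency table."""
    table = contingency(T, P)
    n = int(table.sum())
    if n < 2:
        raise ValueError("ARI requires n >= 2")
    sum_ij = sum(comb(int(nij), 2) for nij in table.ravel())
    sum_a = sum(comb(int(a), 2) for a in table.sum(axis=1))
    sum_b = sum(comb(int(b), 2) for b in table.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def bas(T: Sequence, P_mapped: Sequence, strict: bool = True) -> float:
    """Balanced accuracy of an already label-mapped prediction.

    Binary case: (TPR + TNR) / 2. More than two classes: unweighted mean of
    per-class recall, the standard multiclass generalization.

    With ``strict`` (default), predicted labels outside T's label set raise —
    call :func:`map_labels` (or :func:`acc`'s mapping) first.
    """
    t = np.asarray(T)
    p = np.asarray(P_mapped)
    if len(t) != len(p):
        raise ValueError("length mismatch")
    t_set = set(t.tolist())
    extra = set(p.tolist()) - t_set
    if extra and strict:
        raise ValueError(
            f"predicted labels {sorted(map(str, extra))[:3]} not in the true label "
            "set; Hungarian-map the prediction first (metrics.map_labels)"
        )
    recalls = []
    for cls in sorted(t_set, key=str):
        mask = t == cls
        recalls.append(float(np.mean(p[mask] == cls)))
    return float(np.mean(recalls))


def evaluate(T: Sequence, P: Sequence) -> dict[str, float]:
    """All four indices; BAS is computed after Hungarian mapping."""
    return {
        "ari": ari(T, P),
        "nmi": nmi(T, P),
        "acc": acc(T, P),
        "bas": bas(T, map_labels(T, P), strict=False),
    }
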