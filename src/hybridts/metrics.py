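"""Top-k ranking metrics for identifying superior genotypes.

Given true breeding values (TBVs) and predicted values (GEBVs) for a
candidate population, the candidates holding the k largest GEBVs are mapped
to their TBV ranks π = (π₁, …, π_k) (1 = largest TBV).  Three metrics score
how well the prediction identifies the true top k:

* NDCG@k — discounted cumulative gain of the predicted ordering relative to
  the ideal ordering, gain f(v) = v and discount d(i) = 1/log₂(i+1);
* SRC@k — Pearson correlation of the pairs (i, πᵢ), the Spearman rank
  correlation between predicted and true top-k ranks;
* RS_ratio@k — ideal rank sum Σi divided by observed rank sum Σπᵢ.

RIP summarizes a method's mean metric as percent improvement over the
random-sampling baseline.
"""

from __future__ import annotations

import warnings

import numpy as np


def _ranks_desc(v: np.ndarray) -> np.ndarray:
    """rank[i] = 1-based rank of candidate i when sorting v descending.

    Ties are broken by ascending candidate index, so the result is a
    permutation even for tied values.
    """
    nc = v.size
    order = np.lexsort((np.arange(nc), -v))
    ranks = np.empty(nc, dtype=np.intp)
    ranks[order] = np.arange(1, nc + 1)
    return ranks


def tbv_rank_permutation(tbv, gebv, k: int) -> np.ndarray:
    """TBV ranks of the k candidates with the largest GEBVs, in GEBV order."""
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    nc = tbv.size
    if gebv.size != nc:
        raise ValueError("tbv and gebv must have equal length")
    if not (1 <= k <= nc):
        raise ValueError(f"k must be in [1, {nc}], got {k}")
    tbv_rank = _ranks_desc(tbv)
    gebv_order = np.lexsort((np.arange(nc), -gebv))
    return tbv_rank[gebv_order[:k]]


def ndcg_at_k(tbv, gebv, k: int) -> float:
    """Normalized discounted cumulative gain at position k.

    In [0, 1] when all top-k gains are positive; negative gains void the
    range guarantee and trigger a warning.
    """
    tbv = np.asarray(tbv, dtype=float)
    pi = tbv_rank_permutation(tbv, gebv, k)
    v_sorted = np.sort(tbv)[::-1]  # v(1) >= v(2) >= ...
    discount = 1.0 / np.log2(np.arange(1, k + 1) + 1)
    gains_pred = v_sorted[pi - 1]
    gains_ideal = v_sorted[:k]
    if (gains_pred < 0).any() or (gains_ideal < 0).any():
        warnings.warn(
            "negative gains in NDCG@k: the [0, 1] range no longer holds",
            stacklevel=2,
        )
    ideal = float(gains_ideal @ discount)
    if ideal == 0.0:
        raise ValueError("ideal DCG is zero (all-zero gains)")
    return float(gains_pred @ discount) / ideal


def src_at_k(tbv, gebv, k: int) -> float:
    """Spearman rank correlation at k: Pearson correlation of (i, πᵢ)."""
    if k < 2:
        raise ValueError("src_at_k needs k >= 2")
    pi = tbv_rank_permutation(tbv, gebv, k).astype(float)
    i = np.arange(1, k + 1, dtype=float)
    if np.ptp(pi) == 0:
        raise ValueError("zero variance in TBV ranks")
    return float(np.corrcoef(i, pi)[0, 1])


def rs_ratio_at_k(tbv, gebv, k: int) -> float:
    """Ideal-to-observed rank-sum ratio; 1 iff the top-k sets coincide."""
    pi = tbv_rank_permutation(tbv, gebv, k)
    return float(k * (k + 1) / 2) / float(pi.sum())


def rip(mean_method: float, mean_random: float) -> float:
    """Relative improvement percentage over the random-sampling baseline."""
    if mean_random == 0:
        raise ValueError("random-baseline mean is zero; RIP undefined")
    return 100.0 * (mean_method - mean_random) / mean_random


def evaluate_ranking(tbv, gebv, k: int) -> dict[str, float]:
    """All three metrics for one (tbv, gebv) pair at position k."""
    return {
        "ndcg": ndcg_at_k(tbv, gebv, k),
        "src": src_at_k(tbv, gebv, k),
        "rs_ratio": rs_ratio_at_k(tbv, gebv, k),
    }
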