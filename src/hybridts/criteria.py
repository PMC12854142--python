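"""Training-set scoring criteria.

Three criteria score a candidate subset of size nt for use as a genomic
prediction training set:

* ``mspe_ridge_v2`` — mean squared prediction error of a ridge predictor of
  candidate scores from the training rows (lower is better), evaluated on
  PC-reduced merged additive+dominance scores;
* ``cdmean_v2`` — sum over candidates of squared correlations between true
  and BLUP-estimated genotypic values (higher is better);
* ``gv_scores`` — per-candidate genomic variance, the diagonal of the
  weighted kinship, whose top-nt ranking is the A-optimality-like method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)


@dataclass
class CriterionConfig:
    """Tunable weights for the criteria (defaults are all 1)."""

    lambda_ridge: float = 1.0
    alpha_A: float = 1.0
    alpha_D: float = 1.0
    sigmaA2_gv: float = 1.0
    sigmaD2_gv: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_ridge <= 0:
            raise ValueError("lambda_ridge must be > 0")
        if self.alpha_A < 0 or self.alpha_D < 0:
            raise ValueError("alphas must be >= 0")
        if self.alpha_A == 0 and self.alpha_D == 0:
            raise ValueError("alpha_A and alpha_D cannot both be 0")


@dataclass
class TrainingSet:
    """A selected subset of candidates with provenance.

    ``indices`` are sorted, distinct, 0-based candidate indices.
    """

    indices: np.ndarray
    method: str = ""
    criterion_value: float | None = None
    seed: int | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 1 or idx.size == 0:
            raise ValueError("indices must be a nonempty 1-D array")
        if np.unique(idx).size != idx.size:
            raise ValueError("indices must be distinct")
        if idx.min() < 0:
            raise ValueError("indices must be nonnegative")
        self.indices = np.sort(idx)

    @property
    def size(self) -> int:
        return int(self.indices.size)


def _as_indices(train) -> np.ndarray:
    if isinstance(train, TrainingSet):
        return train.indices
    return np.sort(np.asarray(train, dtype=np.intp))


def mspe_ridge_v2(Z: np.ndarray, train, lam: float = 1.0) -> float:
    """Simplified ridge MSPE criterion over a training subset (minimize).

    With Xc the full candidate score matrix (rows of ``Z``) and Xt its
    training rows, and A = Xtᵀ(Xt Xtᵀ + λ I)⁻¹:

        Tr[Xc A Aᵀ Xcᵀ] + Tr[(Xc − Xc A Xt)(Xc − Xc A Xt)ᵀ]

    The nt x nt system is solved, never explicitly inverted.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    Xc = np.asarray(Z, dtype=float)
    idx = _as_indices(train)
    Xt = Xc[idx]
    nt = Xt.shape[0]
    M = Xt @ Xt.T + lam * np.eye(nt)
    S = Xc @ Xt.T  # nc x nt
    try:
        cho = scipy.linalg.cho_factor(M, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - λ>0 guards this
        raise np.linalg.LinAlgError(f"singular ridge system: {exc}") from exc
    XcA = scipy.linalg.cho_solve(cho, S.T).T  # Xc A, nc x nt
    term1 = float(np.sum(XcA**2))
    resid = Xc - XcA @ Xt
    term2 = float(np.sum(resid**2))
    return term1 + term2


def cdmean_v2(
    KA: np.ndarray,
    KD: np.ndarray,
    train,
    alpha_A: float = 1.0,
    alpha_D: float = 1.0,
) -> float:
    """Heuristic CD criterion: sum of per-candidate squared correlations
    between true and BLUP-estimated genotypic values (maximize).

    With Gt the α-weighted training kinship, Gct the candidate-by-training
    cross block and Mt the centering matrix, each candidate contributes
    Aᵢ/Bᵢ where Aᵢ = diag[Gct(MtGt + I)⁻¹Mt Gctᵀ]ᵢ and Bᵢ is the candidate's
    own weighted genomic variance.
    """
    idx = _as_indices(train)
    nt = idx.size
    if nt < 2:
        raise ValueError("cdmean_v2 needs nt >= 2")
    KA = np.asarray(KA, float)
    KD = np.asarray(KD, float)
    Gct = alpha_A * KA[:, idx] + alpha_D * KD[:, idx]  # nc x nt
    Gt = Gct[idx]  # nt x nt
    Mt = np.eye(nt) - np.full((nt, nt), 1.0 / nt)
    N = Mt @ Gt + np.eye(nt)  # nonsymmetric: general solve
    W = np.linalg.solve(N.T, Gct.T).T  # Gct N^{-1}, nc x nt
    A = np.einsum("ij,ij->i", W @ Mt, Gct)
    B = alpha_A * np.diag(KA) + alpha_D * np.diag(KD)
    degenerate = B <= 1e-12
    if degenerate.any():
        logger.warning(
            "%d candidates with ~zero genomic variance contribute 0 to CDmean",
            int(degenerate.sum()),
        )
    ratios = np.where(degenerate, 0.0, A / np.where(degenerate, 1.0, B))
    return float(ratios.sum())


def gv_scores(
    KA: np.ndarray,
    KD: np.ndarray,
    sigmaA2: float = 1.0,
    sigmaD2: float = 1.0,
) -> np.ndarray:
    """Per-candidate genomic variance score σ²A·KA[i,i] + σ²D·KD[i,i].

    The trace of the weighted kinship submatrix of any subset is the sum of
    its members' scores, so ranking by score solves the subset-trace
    maximization exactly.
    """
    if sigmaA2 < 0 or sigmaD2 < 0:
        raise ValueError("variance components must be >= 0")
    if sigmaA2 == 0 and sigmaD2 == 0:
        raise ValueError("sigmaA2 and sigmaD2 cannot both be 0")
    return sigmaA2 * np.diag(np.asarray(KA, float)) + sigmaD2 * np.diag(
        np.asarray(KD, float)
    )
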