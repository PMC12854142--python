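"""Closed-form BLUP of genotypic values under an additive+dominance GBLUP model.

The model is y = 1μ + gA + gD + e with gA ~ N(0, σ²A KA), gD ~ N(0, σ²D KD)
and e ~ N(0, σ²e I).  With variance ratios αA = σ²A/σ²e and αD = σ²D/σ²e, the
BLUP of the training genotypic values is

    ĝt = (Mt + Gt⁻¹)⁻¹ Mt yt,

and for the whole candidate population (including training members)

    ĝc = Gct (Mt Gt + I)⁻¹ Mt yt,

where Gt = αA KAt + αD KDt, Gct the candidate-by-training cross block, and
Mt = I − J̄ the centering matrix that absorbs the unknown mean.  These are
algebraically the genetic-effect solutions of Henderson's mixed-model
equations after eliminating the intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .criteria import TrainingSet, _as_indices

logger = logging.getLogger(__name__)

_COND_LIMIT = 1e12
_JITTER = 1e-8


@dataclass
class BlupInputs:
    """Everything needed to predict genotypic values from a training set."""

    yt: np.ndarray
    train: TrainingSet | np.ndarray
    KA: np.ndarray
    KD: np.ndarray
    alpha_A: float
    alpha_D: float

    def __post_init__(self) -> None:
        self.yt = np.asarray(self.yt, dtype=float)
        idx = _as_indices(self.train)
        if idx.size < 2:
            raise ValueError("training set must have nt >= 2")
        if self.yt.shape != (idx.size,):
            raise ValueError("yt length must equal training-set size")
        if self.alpha_A < 0 or self.alpha_D < 0:
            raise ValueError("alphas must be >= 0")
        if self.alpha_A == 0 and self.alpha_D == 0:
            raise ValueError("alpha_A and alpha_D cannot both be 0")

    @property
    def indices(self) -> np.ndarray:
        return _as_indices(self.train)

    def cross_kernel(self) -> np.ndarray:
        idx = self.indices
        return (
            self.alpha_A * np.asarray(self.KA, float)[:, idx]
            + self.alpha_D * np.asarray(self.KD, float)[:, idx]
        )

    def training_kernel(self) -> np.ndarray:
        return self.cross_kernel()[self.indices]


def centering_matrix(nt: int) -> np.ndarray:
    """Mt = I − J̄: symmetric idempotent, annihilates constant vectors."""
    if nt < 1:
        raise ValueError("nt must be >= 1")
    return np.eye(nt) - np.full((nt, nt), 1.0 / nt)


def _stabilized(Gt: np.ndarray) -> np.ndarray:
    """Add diagonal jitter only when Gt is numerically ill-conditioned."""
    cond = np.linalg.cond(Gt)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        jitter = _JITTER * float(np.mean(np.diag(Gt)))
        logger.info(
            "training kernel condition %.3g; adding diagonal jitter %.3g",
            cond,
            jitter,
        )
        Gt = Gt + jitter * np.eye(Gt.shape[0])
    return Gt

def blup_train(inp: BlupInputs) -> np.ndarray:
    """BLUP ĝt = (Mt + Gt⁻¹)⁻¹ Mt yt for the training set itself."""
    Gt = _stabilized(inp.training_kernel())
    nt = Gt.shape[0]
    Mt = centering_matrix(nt)
    try:
        Gt_inv = np.linalg.solve(Gt, np.eye(nt))
        return np.linalg.solve(Mt + Gt_inv, Mt @ inp.yt)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"training kernel singular even after jitter: {exc}"
        ) from exc


def blup_candidates(inp: BlupInputs) -> np.ndarray:
    """GEBVs ĝc = Gct (Mt Gt + I)⁻¹ Mt yt for every candidate."""
    Gct = inp.cross_kernel()
    Gt = _stabilized(Gct[inp.indices])
    nt = Gt.shape[0]
    Mt = centering_matrix(nt)
    N = Mt @ Gt + np.eye(nt)
    try:
        return Gct @ np.linalg.solve(N, Mt @ inp.yt)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"prediction system singular: {exc}"
        ) from exc


def candidate_predictor(
    KA: np.ndarray,
    KD: np.ndarray,
    train,
    alpha_A: float,
    alpha_D: float,
) -> np.ndarray:
    """Linear map P with ĝc = P yt, precomputable once per training set.

    Useful when many phenotype replicates share one training set: prediction
    per replicate reduces to a single matrix-vector product.
    """
    idx = _as_indices(train)
    Gct = alpha_A * np.asarray(KA, float)[:, idx] + alpha_D * np.asarray(
        KD, float
    )[:, idx]
    Gt = _stabilized(Gct[idx])
    nt = Gt.shape[0]
    Mt = centering_matrix(nt)
    N = Mt @ Gt + np.eye(nt)
    return Gct @ np.linalg.solve(N, Mt)
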