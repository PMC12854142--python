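"""Marker coding, normalization and genomic relationship matrices.

Hybrid genotype calls (``AA`` major homozygote, ``AB`` heterozygote, ``BB``
minor homozygote) are coded into additive scores (1, 0, -1) and dominance
scores (0, 1, 0), column-standardized, and turned into the additive and
dominance genomic relationship (kinship) matrices ``K = X Xᵀ / p``.  A PCA
reduction of the merged score matrix is provided for the ridge-based
training-set criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Integer dialect: major-allele dosage.  2 <-> AA, 1 <-> AB, 0 <-> BB.
CALL_TO_DOSAGE = {"AA": 2, "AB": 1, "BB": 0}
DOSAGE_TO_CALL = {2: "AA", 1: "AB", 0: "BB"}


@dataclass
class GenotypeTable:
    """Complete hybrid x SNP genotype calls.

    ``calls`` holds the major-allele dosage (2 = AA, 1 = AB, 0 = BB) as an
    ``nc x p`` int8 matrix.  Missing entries are not representable: inputs
    with missing genotypes are rejected at read time.
    """

    calls: np.ndarray
    hybrid_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D matrix")
        nc, p = self.calls.shape
        if nc < 2:
            raise ValueError(f"need at least 2 hybrids, got {nc}")
        if p < 1:
            raise ValueError("need at least 1 marker")
        if len(self.hybrid_ids) != nc or len(self.marker_ids) != p:
            raise ValueError("id lists do not match calls shape")
        bad = (self.calls < 0) | (self.calls > 2)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"unknown genotype call at hybrid {self.hybrid_ids[i]!r}, "
                f"marker {self.marker_ids[j]!r}: {self.calls[i, j]}"
            )

    @property
    def n_hybrids(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @classmethod
    def from_strings(
        cls, calls: np.ndarray, hybrid_ids=None, marker_ids=None
    ) -> "GenotypeTable":
        """Build from an array of ``AA``/``AB``/``BB`` strings."""
        calls = np.asarray(calls, dtype=object)
        nc, p = calls.shape
        coded = np.empty((nc, p), dtype=np.int8)
        for i in range(nc):
            for j in range(p):
                c = str(calls[i, j])
                if c not in CALL_TO_DOSAGE:
                    raise ValueError(
                        f"unknown genotype call at row {i}, column {j}: {c!r}"
                    )
                coded[i, j] = CALL_TO_DOSAGE[c]
        hybrid_ids = list(hybrid_ids) if hybrid_ids is not None else [
            f"H{i + 1}" for i in range(nc)
        ]
        marker_ids = list(marker_ids) if marker_ids is not None else [
            f"M{j + 1}" for j in range(p)
        ]
        return cls(coded, hybrid_ids, marker_ids)


@dataclass
class ScorePair:
    """Column-standardized additive (XA) and dominance (XD) score matrices."""

    XA: np.ndarray
    XD: np.ndarray
    retained_A: list[int]
    retained_D: list[int]
    dropped_A: list[int]
    dropped_D: list[int]


@dataclass
class KinshipPair:
    """Additive and dominance genomic relationship matrices."""

    KA: np.ndarray
    KD: np.ndarray


@dataclass
class PCScores:
    """Principal-component scores of the merged [XA, XD] score matrix."""

    Z: np.ndarray
    explained_cumvar: float

    @property
    def n_components(self) -> int:
        return self.Z.shape[1]


def code_markers(g: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Raw additive and dominance effect scores.

    Additive: AA -> 1, AB -> 0, BB -> -1 (major-allele dosage minus one).
    Dominance: AB -> 1, homozygotes -> 0.
    """
    WA = g.calls.astype(np.int64) - 1
    WD = (g.calls == 1).astype(np.int64)
    return WA, WD


def standardize(W: np.ndarray) -> tuple[np.ndarray, list[int], list[int]]:
    """Center and scale each column by its sample mean and sample sd (n-1).

    Zero-variance columns carry no information and are dropped; their indices
    are returned so callers can report them.  Raises if nothing is left.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[0] < 2:
        raise ValueError("standardization needs at least 2 rows")
    mean = W.mean(axis=0)
    sd = W.std(axis=0, ddof=1)
    keep = sd > 0
    retained = np.flatnonzero(keep)
    dropped = np.flatnonzero(~keep)
    if retained.size == 0:
        raise ValueError("no usable markers: every column has zero variance")
    X = (W[:, keep] - mean[keep]) / sd[keep]
    return X, retained.tolist(), dropped.tolist()


def build_scores(g: GenotypeTable) -> ScorePair:
    """Code and standardize both score matrices for a candidate population."""
    WA, WD = code_markers(g)
    XA, retained_A, dropped_A = standardize(WA)
    XD, retained_D, dropped_D = standardize(WD)
    if dropped_A:
        logger.info("dropped %d zero-variance additive columns", len(dropped_A))
    if dropped_D:
        logger.info(
            "dropped %d zero-variance dominance columns (no segregating cross)",
            len(dropped_D),
        )
    return ScorePair(XA, XD, retained_A, retained_D, dropped_A, dropped_D)


def kinship(X: np.ndarray, p_used: int) -> np.ndarray:
    """Genomic relationship matrix K = X Xᵀ / p for standardized scores.

    ``p_used`` is the number of retained columns of the matrix itself, so
    trace(K) = nc - 1 holds exactly for sample-sd standardized columns.
    """
    if p_used <= 0:
        raise ValueError("p_used must be positive")
    X = np.asarray(X, dtype=float)
    K = X @ X.T / p_used
    return (K + K.T) / 2.0


def build_kinships(scores: ScorePair) -> KinshipPair:
    KA = kinship(scores.XA, scores.XA.shape[1])
    KD = kinship(scores.XD, scores.XD.shape[1])
    return KinshipPair(KA, KD)


def pc_reduce(
    XA: np.ndarray, XD: np.ndarray, threshold: float = 0.99
) -> PCScores:
    """Replace merged marker scores by principal-component scores.

    The merged matrix [XA, XD] is column-centered (already true for
    standardized scores) and decomposed by SVD; the smallest number of
    components whose cumulative explained variance exceeds ``threshold`` is
    retained.  Rows of ``Z`` are candidate scores; training-set rows for the
    ridge criterion are row subsets of the same basis.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    M = np.hstack([np.asarray(XA, float), np.asarray(XD, float)])
    M = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    var = s**2
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    cum = np.cumsum(var) / var.sum()
    above = np.flatnonzero(cum > threshold)
    m = int(above[0]) + 1 if above.size else rank
    m = max(1, min(m, rank))
    Z = U[:, :m] * s[:m]
    return PCScores(Z=Z, explained_cumvar=float(cum[m - 1]))


def dominance_variance_profile(KD: np.ndarray, sigmaD2: float) -> np.ndarray:
    """Per-genotype genomic variance attributable to dominance effects."""
    return sigmaD2 * np.diag(np.asarray(KD, float)).copy()


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------

def read_genotype_matrix(path) -> GenotypeTable:
    """Read a delimited genotype matrix (tab or comma, auto-detected).

    Layout: header row of marker ids, first column hybrid id, cells either
    AA/AB/BB strings or 0/1/2 integers (2 = major homozygote AA).
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)
    if df.isna().any().any():
        raise ValueError(f"missing genotype entries in {path}")
    raw = df.to_numpy(dtype=object)
    nc, p = raw.shape
    coded = np.empty((nc, p), dtype=np.int8)
    for i in range(nc):
        for j in range(p):
            c = str(raw[i, j]).strip()
            if c in CALL_TO_DOSAGE:
                coded[i, j] = CALL_TO_DOSAGE[c]
            elif c in {"0", "1", "2"}:
                coded[i, j] = int(c)
            else:
                raise ValueError(
                    f"unknown genotype call at hybrid {df.index[i]!r}, "
                    f"marker {df.columns[j]!r}: {c!r}"
                )
    return GenotypeTable(coded, [str(x) for x in df.index],
                         [str(x) for x in df.columns])


def write_genotype_matrix(g: GenotypeTable, path, sep: str = "\t") -> None:
    """Write calls as AA/AB/BB strings with ids."""
    strings = np.vectorize(DOSAGE_TO_CALL.get)(g.calls.astype(int))
    df = pd.DataFrame(strings, index=g.hybrid_ids, columns=g.marker_ids)
    df.to_csv(path, sep=sep)


def read_vcf(path) -> GenotypeTable:
    """Read biallelic SNP genotypes from a (plain-text) VCF, GT subfield only.

    REF is treated as the major allele: 0/0 -> AA, 0/1 or 1/0 -> AB,
    1/1 -> BB.  Multi-allelic records are skipped; their count is logged.
    Missing genotypes are an error — resolve missingness upstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    hybrid_ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    marker_ids: list[str] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = v.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        if np.any(gt == 2):
            raise ValueError(
                f"missing genotype in record {v.CHROM}:{v.POS}; "
                "impute or filter upstream"
            )
        dosage = np.where(gt == 0, 2, np.where(gt == 1, 1, 0)).astype(np.int8)
        rows.append(dosage)
        marker_ids.append(v.ID if v.ID and v.ID != "." else f"{v.CHROM}:{v.POS}")
    if n_multi:
        logger.warning("rejected %d multi-allelic VCF records", n_multi)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    calls = np.stack(rows, axis=1)
    return GenotypeTable(calls, hybrid_ids, marker_ids)
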