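"""Synthetic hybrid genotypes and the GBLUP phenotype simulator.

Hybrids are produced by crossing fully homozygous male and female inbred
parents: per locus a minor-allele frequency f ~ U(maf_low, maf_high) is
drawn, each parent carries the minor allele (homozygously) with probability
f, and a cross is AA/AB/BB according to whether zero, one or both parents
carry it.  The default design mirrors a wheat-type factorial — 15 male ×
120 female parents, 500 sampled crosses, markers with MAF above 0.1.

Phenotypes follow y = μ + gA + gD + e with gA ~ MVN(0, σ²A·KA),
gD ~ MVN(0, σ²D·KD), e ~ MVN(0, σ²e·I); the true breeding value is
tbv = μ + gA + gD.  The error variance is tied to broad-sense heritability
h² = (σ²A + σ²D)/(σ²A + σ²D + σ²e) and the dominance ratio γ = σ²D/σ²A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .genotypes import GenotypeTable, KinshipPair


@dataclass
class HybridDesign:
    """Parent counts, marker count and allele-frequency bounds for crosses."""

    n_male: int = 15
    n_female: int = 120
    p: int = 2000
    maf_low: float = 0.1
    maf_high: float = 0.5
    n_hybrids: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.n_hybrids > self.n_male * self.n_female:
            raise ValueError(
                f"n_hybrids={self.n_hybrids} exceeds the "
                f"{self.n_male}x{self.n_female} cross grid"
            )


@dataclass
class SimScenario:
    """One simulation setting; σ²D and σ²e are derived, never stored."""

    mu: float = 100.0
    sigmaA2: float = 20.0
    gamma: float = 1.0
    h2: float = 0.3
    n_reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigmaA2 <= 0 or self.gamma <= 0:
            raise ValueError("sigmaA2 and gamma must be > 0")
        if not (0 < self.h2 < 1):
            raise ValueError("h2 must be in (0, 1)")

    @property
    def sigmaD2(self) -> float:
        return self.gamma * self.sigmaA2

    @property
    def sigmaE2(self) -> float:
        return (1.0 - self.h2) / self.h2 * (self.sigmaA2 + self.sigmaD2)


@dataclass
class PhenoReplicate:
    """One simulated phenotype dataset; identities hold exactly."""

    gA: np.ndarray
    gD: np.ndarray
    g: np.ndarray
    tbv: np.ndarray
    e: np.ndarray
    y: np.ndarray
    rep: int


def simulate_hybrid_genotypes(design: HybridDesign) -> GenotypeTable:
    """Cross homozygous inbred parents into a hybrid candidate population.

    Loci monomorphic across the sampled hybrids are redrawn up to 10 times
    and dropped if still monomorphic.
    """
    rng = np.random.default_rng(design.seed)
    nm, nf, p = design.n_male, design.n_female, design.p
    # sample crosses uniformly without replacement from the full grid
    cross = rng.choice(nm * nf, size=design.n_hybrids, replace=False)
    males, females = np.divmod(cross, nf)

    def draw(n_loci: int) -> np.ndarray:
        f = rng.uniform(design.maf_low, design.maf_high, size=n_loci)
        male_carrier = rng.random((nm, n_loci)) < f
        female_carrier = rng.random((nf, n_loci)) < f
        minor_count = male_carrier[males].astype(np.int8) + female_carrier[
            females
        ].astype(np.int8)
        return 2 - minor_count  # major-allele dosage: AA=2, AB=1, BB=0

    calls = draw(p)
    for _ in range(10):
        mono = np.flatnonzero(np.all(calls == calls[0], axis=0))
        if mono.size == 0:
            break
        calls[:, mono] = draw(mono.size)
    poly = ~np.all(calls == calls[0], axis=0)
    calls = calls[:, poly]
    if calls.shape[1] == 0:
        raise ValueError("all simulated loci monomorphic; widen MAF bounds")
    hybrid_ids = [
        f"H{m + 1:02d}x{w + 1:03d}" for m, w in zip(males, females)
    ]
    marker_ids = [f"M{j + 1}" for j in range(calls.shape[1])]
    return GenotypeTable(calls, hybrid_ids, marker_ids)


def _mvn_factor(K: np.ndarray) -> np.ndarray:
    """Square root of a PSD kinship by symmetric eigendecomposition.

    Kinships built as X·Xᵀ/p are rank-deficient by construction, so a
    Cholesky factor need not exist; small negative eigenvalues are clipped
    to zero, and anything below −1e-6 means the matrix is corrupted.
    """
    K = np.asarray(K, dtype=float)
    vals, vecs = np.linalg.eigh((K + K.T) / 2.0)
    if vals.min() < -1e-6:
        raise ValueError(f"kinship has negative eigenvalue {vals.min():.3g}")
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def simulate_replicate(
    LA: np.ndarray, LD: np.ndarray, sc: SimScenario, rep: int
) -> PhenoReplicate:
    """One phenotype replicate from precomputed kinship factors.

    Replicate streams are addressed by (seed, rep), so replicate r is
    bit-identical whether drawn alone or within a batch.
    """
    rng = np.random.default_rng(np.random.SeedSequence(sc.seed, spawn_key=(rep,)))
    nc = LA.shape[0]
    gA = np.sqrt(sc.sigmaA2) * (LA @ rng.standard_normal(LA.shape[1]))
    gD = np.sqrt(sc.sigmaD2) * (LD @ rng.standard_normal(LD.shape[1]))
    e = np.sqrt(sc.sigmaE2) * rng.standard_normal(nc)
    g = gA + gD
    tbv = sc.mu + g
    return PhenoReplicate(gA=gA, gD=gD, g=g, tbv=tbv, e=e, y=tbv + e, rep=rep)


def simulate_replicates(
    kin: KinshipPair, sc: SimScenario
) -> Iterator[PhenoReplicate]:
    """Generate ``sc.n_reps`` independent phenotype replicates."""
    LA = _mvn_factor(kin.KA)
    LD = _mvn_factor(kin.KD)
    for rep in range(sc.n_reps):
        yield simulate_replicate(LA, LD, sc, rep)
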