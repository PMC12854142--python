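import numpy as np
import pytest

import hybridts as ht


@pytest.fixture(scope="session")
def small_population():
    """A 60-hybrid synthetic candidate population with scores and kinships."""
    g = ht.simulate_hybrid_genotypes(
        ht.HybridDesign(n_male=6, n_female=15, p=400, n_hybrids=60, seed=42)
    )
    scores = ht.build_scores(g)
    kin = ht.build_kinships(scores)
    return g, scores, kin


@pytest.fixture(scope="session")
def tiny_kinships():
    """Kinships for an 8-hybrid population, small enough for exhaustive search."""
    g = ht.simulate_hybrid_genotypes(
        ht.HybridDesign(n_male=4, n_female=4, p=100, n_hybrids=8, seed=7)
    )
    kin = ht.build_kinships(ht.build_scores(g))
    return kin


def random_psd_kernels(rng, nc, p=None):
    """Random centered-score kinship pair, the shape the model assumes."""
    p = p or 3 * nc
    XA, _, _ = ht.standardize(rng.normal(size=(nc, p)))
    XD, _, _ = ht.standardize(rng.normal(size=(nc, p)))
    return ht.KinshipPair(
        KA=ht.kinship(XA, XA.shape[1]), KD=ht.kinship(XD, XD.shape[1])
    )
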