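"""Training-set construction: top ranking, exchange search, random baseline."""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .criteria import TrainingSet


@dataclass
class ExchangeConfig:
    """Knobs for the steepest-ascent exchange search."""

    max_rounds: int = 50
    n_restarts: int = 1
    seed: int = 0
    direction: str = "maximize"

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.direction not in {"maximize", "minimize"}:
            raise ValueError("direction must be 'maximize' or 'minimize'")


def _check_nt(nt: int, nc: int) -> None:
    if not (1 <= nt <= nc):
        raise ValueError(f"nt must be in [1, {nc}], got {nt}")


def select_gv_average(scores: np.ndarray, nt: int) -> TrainingSet:
    """Top-nt candidates by genomic-variance score; ties to the smallest index.

    Deterministic and search-free: sorting the per-candidate scores solves
    the subset-trace maximization exactly.
    """
    scores = np.asarray(scores, dtype=float)
    nc = scores.size
    _check_nt(nt, nc)
    # lexsort: primary key -scores (descending), secondary key index ascending
    order = np.lexsort((np.arange(nc), -scores))
    idx = np.sort(order[:nt])
    return TrainingSet(
        indices=idx,
        method="gv_average",
        criterion_value=float(scores[idx].sum()),
    )


def select_random(nt: int, nc: int, seed: int) -> TrainingSet:
    """Uniform sample of nt candidates without replacement (baseline)."""
    _check_nt(nt, nc)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(nc, size=nt, replace=False))
    return TrainingSet(indices=idx, method="random", seed=seed)


def select_exchange(
    criterion: Callable[[np.ndarray], float],
    nt: int,
    nc: int,
    cfg: ExchangeConfig,
) -> TrainingSet:
    """Steepest-ascent exchange search over size-nt subsets.

    From a seeded uniform start, every round evaluates all nt x (nc - nt)
    single (in, out) swaps and applies the best strictly-improving one;
    the search stops when no swap improves or ``max_rounds`` is reached.
    The best result over ``n_restarts`` restarts is returned.  Criterion
    values along a run are strictly monotone in ``cfg.direction``.
    """
    _check_nt(nt, nc)
    sign = 1.0 if cfg.direction == "maximize" else -1.0
    cache: dict[tuple, float] = {}

    def ev(idx: np.ndarray) -> float:
        key = tuple(idx.tolist())
        if key not in cache:
            cache[key] = float(criterion(idx))
        return cache[key]

    if nt == nc:
        idx = np.arange(nc, dtype=np.intp)
        return TrainingSet(
            indices=idx,
            method="exchange",
            criterion_value=ev(idx),
            seed=cfg.seed,
            report={"rounds": 0, "swaps": 0, "restarts": 0},
        )

    t0 = time.perf_counter()
    best_idx: np.ndarray | None = None
    best_val = -np.inf
    best_report: dict = {}
    for restart in range(cfg.n_restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=(restart,))
        )
        current = np.sort(rng.choice(nc, size=nt, replace=False))
        cur_val = sign * ev(current)
        swaps = rounds = 0
        for _ in range(cfg.max_rounds):
            rounds += 1
            in_mask = np.zeros(nc, dtype=bool)
            in_mask[current] = True
            outside = np.flatnonzero(~in_mask)
            best_swap = None
            best_swap_val = cur_val
            for pos in range(nt):  # ascending member, ascending outsider
                cand = current.copy()
                for j in outside:
                    cand2 = cand.copy()
                    cand2[pos] = j
                    cand2.sort()
                    val = sign * ev(cand2)
                    if val > best_swap_val:
                        best_swap_val = val
                        best_swap = cand2
            if best_swap is None:
                break
            current = best_swap
            cur_val = best_swap_val
            swaps += 1
        if cur_val > best_val or best_idx is None:
            best_val = cur_val
            best_idx = current
            best_report = {"rounds": rounds, "swaps": swaps, "restarts": restart}
    best_report["wall_time_s"] = time.perf_counter() - t0
    best_report["evaluations"] = len(cache)
    return TrainingSet(
        indices=best_idx,
        method="exchange",
        criterion_value=sign * best_val,
        seed=cfg.seed,
        report=best_report,
    )
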