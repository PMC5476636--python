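"""Traveling-salesman tours over cluster means by arbitrary insertion.

The cycle assumption — adjacent cell-cycle phases have the most similar
transcriptomes — turns ordering into a Euclidean TSP on cluster means.
Arbitrary insertion is a randomized O(k^2) construction heuristic with a
2 ln(k) worst-case approximation guarantee; running it many times and
keeping the shortest tour is both the per-k step and the raw material for
the consensus order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TourCycle:
    """A Hamilton cycle over k nodes: circular node order plus total length."""

    node_order: np.ndarray  # permutation of 0..k-1, read circularly
    total_length: float
    k: int

    def __post_init__(self) -> None:
        self.node_order = np.asarray(self.node_order, dtype=int)
        if sorted(self.node_order.tolist()) != list(range(self.k)):
            raise ValueError("node_order is not a permutation of 0..k-1")


def tour_length(order: np.ndarray, D: np.ndarray) -> float:
    """Cycle length including the closing edge."""
    order = np.asarray(order, dtype=int)
    return float(D[order, np.roll(order, -1)].sum())


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0) or not np.allclose(np.diag(D), 0):
        raise ValueError("distances must be nonnegative with zero diagonal")
    return D


def arbitrary_insertion_tour(D: np.ndarray, seed: int = 0) -> TourCycle:
    """One arbitrary-insertion run: grow a sub-tour by inserting uniformly
    chosen nodes at the position of minimal length increase.

    The initial sub-tour is a random edge; insertion-cost ties break at the
    smallest insertion index.  Deterministic given ``seed``.
    """
    D = _check_distance_matrix(D)
    k = D.shape[0]
    rng = np.random.default_rng(seed)
    if k < 3:
        order = np.arange(k)
        return TourCycle(order, tour_length(order, D), k)
    start = rng.choice(k, size=2, replace=False)
    tour: list[int] = list(start)
    remaining = [i for i in range(k) if i not in tour]
    while remaining:
        node = remaining.pop(rng.integers(len(remaining)))
        m = len(tour)
        cur = np.array(tour)
        nxt = np.roll(cur, -1)
        # insertion of `node` between tour[i] and tour[i+1]
        costs = D[cur, node] + D[node, nxt] - D[cur, nxt]
        pos = int(np.argmin(costs))  # argmin takes the first (smallest index) on ties
        tour.insert(pos + 1, node)
    order = np.array(tour)
    return TourCycle(order, tour_length(order, D), k)


def best_tour(D: np.ndarray, k: int | None = None, n_fold: int = 2, seed: int = 0) -> TourCycle:
    """Shortest tour over ``n_fold * k`` seeded arbitrary-insertion runs."""
    D = _check_distance_matrix(D)
    if k is None:
        k = D.shape[0]
    if n_fold < 1:
        raise ValueError("n_fold must be >= 1")
    n_runs = max(1, n_fold * k)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs)]
    best: TourCycle | None = None
    for s in child_seeds:
        cand = arbitrary_insertion_tour(D, seed=s)
        if best is None or cand.total_length < best.total_length:
            best = cand
    assert best is not None
    return best


def exhaustive_tour(D: np.ndarray) -> TourCycle:
    """Exact optimum by enumerating all (k-1)!/2 distinct cycles.

    Only feasible for small k; used as an oracle for the heuristic.
    """
    from itertools import permutations

    D = _check_distance_matrix(D)
    k = D.shape[0]
    if k < 4:
        order = np.arange(k)
        return TourCycle(order, tour_length(order, D), k)
    best_order, best_len = None, np.inf
    for perm in permutations(range(1, k)):
        if perm[0] > perm[-1]:  # skip reversals
            continue
        order = np.array((0,) + perm)
        length = tour_length(order, D)
        if length < best_len:
            best_order, best_len = order, length
    return TourCycle(best_order, best_len, k)
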