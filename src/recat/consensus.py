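"""Consensus circular ordering of cells across cluster granularities.

A single tour at one k is brittle: clustering noise at that granularity
propagates directly into the order.  The consensus order instead computes a
shortest tour for every k in a sweep (k_min..k_max), turns each tour into a
per-cell circular position, aligns the position vectors to the k_min
reference (best rotation and reflection), and averages them on the circle.
When all tours agree the consensus reproduces the shared order; under noise
it averages out per-k mistakes.

The merge scheme (align-then-circular-mean) is this package's concrete
interpretation of consensus tour merging; it is order-preserving on
agreement and degrades gracefully, but other merge rules exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .circular import circular_mean, resultant_length, wrap_unit
from .cluster import GmmModel, cluster_distance_matrix, fit_gmm
from .matrix import ExpressionMatrix, ValidationError
from .tsp import TourCycle, best_tour


@dataclass
class ConsensusOrder:
    """Per-cell circular pseudotime positions and their linearization."""

    theta: np.ndarray             # (n,), positions in [0, 1)
    cell_ids: list[str]
    provenance: dict = field(default_factory=dict)  # per-k tour lengths, seeds, k list
    ref_labels: np.ndarray | None = None  # hard cluster labels at the reference k

    def __post_init__(self) -> None:
        self.theta = np.asarray(wrap_unit(np.asarray(self.theta, dtype=float)), dtype=float)
        if self.theta.shape != (len(self.cell_ids),):
            raise ValidationError("theta length must match cell_ids")

    @property
    def n_cells(self) -> int:
        return self.theta.size

    @property
    def linear_order(self) -> np.ndarray:
        """Permutation of cell indices: cut at theta=0, ascending theta."""
        return np.argsort(self.theta, kind="stable")

    def ranks(self) -> np.ndarray:
        """Per-cell 0-based rank along the linearized series."""
        ranks = np.empty(self.n_cells, dtype=int)
        ranks[self.linear_order] = np.arange(self.n_cells)
        return ranks

    def reversed(self) -> "ConsensusOrder":
        return ConsensusOrder(
            wrap_unit(-self.theta), list(self.cell_ids), dict(self.provenance),
            self.ref_labels,
        )


def positions_from_tour(model: GmmModel, tour: TourCycle) -> np.ndarray:
    """Per-cell circular positions induced by a cluster-level tour.

    Cluster j (the j-th node along the tour) owns the arc [j/k, (j+1)/k); its
    member cells are spread uniformly inside the arc, ordered by projection
    onto the direction from the previous to the next cluster mean so that the
    within-cluster order follows the local geometry of the cycle.
    """
    k = model.k
    members = model.members()
    theta = np.empty(model.responsibilities.shape[0], dtype=float)
    order = tour.node_order
    for pos_j, cluster in enumerate(order):
        cells = members[cluster]
        if cells.size == 0:
            continue
        prev_mean = model.means[order[(pos_j - 1) % k]]
        next_mean = model.means[order[(pos_j + 1) % k]]
        direction = next_mean - prev_mean
        cell_proj = _cell_projection(model, cells, direction)
        within = np.argsort(cell_proj, kind="stable")
        ranks = np.empty(cells.size, dtype=int)
        ranks[within] = np.arange(cells.size)
        theta[cells] = (pos_j + (ranks + 0.5) / cells.size) / k
    return theta


def _cell_projection(model: GmmModel, cells: np.ndarray, direction: np.ndarray) -> np.ndarray:
    # the fitted model does not retain cell coordinates; callers attach them
    # as `_cell_coords` (cells x genes) before requesting positions
    return model._cell_coords[cells] @ direction  # type: ignore[attr-defined]


def align_to_reference(theta: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Best rotation/reflection of ``theta`` onto ``reference``.

    For each orientation the optimal rotation is the circular mean of the
    per-cell offsets; the orientation with the larger mean resultant length
    (tighter agreement) wins.  Returns the aligned vector and its resultant.
    """
    best_aligned, best_r = None, -1.0
    for cand in (theta, wrap_unit(-theta)):
        offsets = wrap_unit(reference - cand)
        r = resultant_length(offsets)
        delta = circular_mean(offsets)
        aligned = wrap_unit(cand + delta)
        if r > best_r:
            best_aligned, best_r = aligned, r
    return best_aligned, best_r


def consensus_order(
    mat: ExpressionMatrix,
    k_min: int = 7,
    k_max: int | None = None,
    n_fold: int = 2,
    seed: int = 0,
    n_init: int = 10,
) -> ConsensusOrder:
    """Consensus circular pseudotime over the cluster-granularity sweep.

    For each k in [k_min, k_max]: fit a GMM, find the shortest tour over
    cluster means (best of n_fold*k arbitrary-insertion runs), and place each
    cell on the circle.  Position vectors are aligned to the k_min reference
    and averaged per cell on the circle.  Default k_max = min(n//10, 30) so
    clusters keep >= 10 cells on average.
    """
    n = mat.n_cells
    if k_max is None:
        k_max = max(k_min, min(n // 10, 30))
    if k_max > n:
        raise ValidationError("k_max exceeds the number of cells")
    if k_max < k_min:
        raise ValidationError("k_max must be >= k_min")
    ss = np.random.SeedSequence(seed)
    ks = list(range(k_min, k_max + 1))
    child = {k: s for k, s in zip(ks, ss.spawn(len(ks)))}
    per_k_theta: dict[int, np.ndarray] = {}
    provenance: dict = {"seed": seed, "n_fold": n_fold, "tours": {}}
    ref_labels = None
    for k in ks:
        gmm_seed, tour_seed = (int(s.generate_state(1)[0] % (2**31)) for s in child[k].spawn(2))
        try:
            model = fit_gmm(mat, k=k, seed=gmm_seed, n_init=n_init)
            model._cell_coords = mat.values.T  # used for within-cluster placement
            labels = model.hard_labels
            if len(np.unique(labels)) < max(3, k - k // 3):
                raise ValidationError(f"degenerate GMM at k={k}")
            D = cluster_distance_matrix(model)
            tour = best_tour(D, k=k, n_fold=n_fold, seed=tour_seed)
            per_k_theta[k] = positions_from_tour(model, tour)
            provenance["tours"][k] = {
                "length": tour.total_length,
                "node_order": tour.node_order.tolist(),
                "gmm_seed": gmm_seed,
                "tour_seed": tour_seed,
            }
            if k == k_min:
                ref_labels = labels
        except ValidationError as err:
            warnings.warn(f"skipping k={k}: {err}", stacklevel=2)
    if len(per_k_theta) < 2:
        raise ValidationError("fewer than 2 usable cluster granularities; cannot build consensus")
    ref_k = min(per_k_theta)
    reference = per_k_theta[ref_k]
    aligned = [reference]
    for k in sorted(per_k_theta):
        if k == ref_k:
            continue
        vec, _ = align_to_reference(per_k_theta[k], reference)
        aligned.append(vec)
    theta = circular_mean(np.vstack(aligned), axis=0)
    provenance["k_values"] = sorted(per_k_theta)
    return ConsensusOrder(theta, list(mat.cell_ids), provenance, ref_labels)


def single_k_order(
    mat: ExpressionMatrix, k: int = 8, n_fold: int = 2, seed: int = 0, n_init: int = 10
) -> ConsensusOrder:
    """Order from a single cluster granularity (the non-consensus baseline)."""
    ss = np.random.SeedSequence(seed)
    gmm_seed, tour_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    model = fit_gmm(mat, k=k, seed=gmm_seed, n_init=n_init)
    model._cell_coords = mat.values.T
    D = cluster_distance_matrix(model)
    tour = best_tour(D, k=k, n_fold=n_fold, seed=tour_seed)
    theta = positions_from_tour(model, tour)
    prov = {"seed": seed, "n_fold": n_fold, "tours": {k: {"length": tour.total_length}}}
    return ConsensusOrder(theta, list(mat.cell_ids), prov, model.hard_labels)
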