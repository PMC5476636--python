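"""Accuracy metrics for a recovered order against experimental stage labels.

Two metrics compare a circular order with per-cell labels (e.g. 1 = G0/G1,
2 = S, 3 = G2/M from Hoechst or FUCCI):

* **correlation-score** — a cycle of k clusters can be cut at any of its k
  edges and read in either direction, giving 2k linearizations; each assigns
  every cell the sequential index of its cluster.  The score is the maximum
  Pearson correlation between that index vector and the labels over all 2k
  linearizations.
* **change-index** — 1 - (s_c - 2)/(N - 3), where s_c counts adjacent label
  changes along the linearized series.  A perfect series changes labels
  exactly twice (G1->S, S->G2/M) and scores 1; a worst-case series with
  s_c = N - 1 scores 0.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .consensus import ConsensusOrder
from .matrix import ValidationError
from .tsp import TourCycle


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("correlation-score undefined for constant vectors")
    return float(np.corrcoef(a, b)[0, 1])


def correlation_score(
    cycle: Sequence[Sequence[int]] | ConsensusOrder,
    labels: np.ndarray,
    tour: TourCycle | None = None,
) -> float:
    """Maximum PCC between labels and predicted sequential indices over all
    2k linearizations of the cycle.

    ``cycle`` is either a list of per-cluster cell-index lists in cycle order
    (pass ``tour`` if they still need ordering), or a :class:`ConsensusOrder`,
    which is treated as the k = n limit: every cell its own cluster, cuts
    enumerated at all n cell boundaries.
    """
    labels = np.asarray(labels, dtype=float)
    if isinstance(cycle, ConsensusOrder):
        members = [[int(i)] for i in cycle.linear_order]
    else:
        members = [list(c) for c in cycle]
        if tour is not None:
            members = [members[j] for j in tour.node_order]
    n = labels.size
    if n < 3:
        raise ValidationError("need at least 3 cells")
    covered = sorted(i for c in members for i in c)
    if covered != list(range(n)):
        raise ValidationError("cycle clusters must partition the label vector indices")
    k = len(members)
    best = -np.inf
    for direction in (1, -1):
        ordered = members if direction == 1 else members[::-1]
        for cut in range(k):
            rotated = ordered[cut:] + ordered[:cut]
            pred = np.empty(n)
            for j, cluster in enumerate(rotated, start=1):
                for i in cluster:
                    pred[i] = j
            best = max(best, _pcc(labels, pred))
    return best


def change_index(ordered_labels: Sequence) -> float:
    """1 - (s_c - 2)/(N - 3) with s_c = number of adjacent label changes.

    Assumes the labels were read along a linearized series.  Degenerate
    series with fewer than 2 intrinsic changes are clamped at 1 with a
    warning (the formula presumes the two ideal stage transitions exist).
    """
    labels = list(ordered_labels)
    N = len(labels)
    if N < 4:
        raise ValidationError("change-index needs at least 4 cells (denominator N - 3)")
    s_c = sum(1 for a, b in zip(labels, labels[1:]) if a != b)
    value = 1.0 - (s_c - 2) / (N - 3)
    if s_c < 2:
        warnings.warn(
            f"only {s_c} label change(s); change-index clamped to 1", stacklevel=2
        )
        return 1.0
    return float(value)


def evaluate_order(order: ConsensusOrder, labels_by_cell: dict[str, int]) -> dict:
    """Both metrics for a consensus order against per-cell integer labels."""
    labels = np.array([labels_by_cell[c] for c in order.cell_ids], dtype=float)
    ordered = labels[order.linear_order]
    return {
        "correlation_score": correlation_score(order, labels),
        "change_index": change_index(ordered.tolist()),
        "n": int(labels.size),
        "k": int(labels.size),
    }
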