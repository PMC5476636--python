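"""Reconstruct a circular cell-cycle pseudotime from a synthetic experiment.

Simulates 300 unsynchronized cells with known phase, runs the consensus
traveling-salesman ordering over a sweep of Gaussian-mixture granularities,
and compares the recovered circular positions with the ground truth and with
a single fixed-granularity tour.
"""

import numpy as np

import recat
from recat.circular import circular_rank_correlation
from recat.preprocess import log_transform, normalize, subset_to_catalog

config = recat.CycleSimConfig(seed=1)  # 300 cells x 200 genes
mat, truth = recat.simulate_expression(config)
catalog = recat.make_catalog(truth)
log_mat = subset_to_catalog(log_transform(normalize(mat)), catalog)

consensus = recat.consensus_order(log_mat, seed=1)
single = recat.single_k_order(log_mat, k=8, seed=1)

c = abs(circular_rank_correlation(consensus.theta, truth.phi))
s = abs(circular_rank_correlation(single.theta, truth.phi))
print(f"cells: {log_mat.n_cells}, cycle genes: {log_mat.n_genes}")
print(f"granularities merged: k = {consensus.provenance['k_values']}")
print(f"circular rank correlation with true phase: consensus {c:.3f}, single k=8 {s:.3f}")

stage_to_int = {"G1": 1, "S": 2, "G2M": 3}
labels = {cell: stage_to_int[st] for cell, st in zip(truth.cell_ids, truth.stage)}
metrics = recat.evaluate_order(consensus, labels)
print(f"correlation-score vs stage labels: {metrics['correlation_score']:.3f}")
print(f"change-index of the linearized series: {metrics['change_index']:.3f}")
print("(1 = labels change only at the two ideal stage transitions; 0 = worst case)")
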