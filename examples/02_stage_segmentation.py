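"""Segment a recovered pseudotime into cell-cycle stages with the HMM.

Builds the 9-dimensional score track (3 gene-pair Bayes scores + 6 marker-set
mean scores) along the true circular order of a simulation, searches the
cycle start, and reports Viterbi stage calls against the ground truth.
"""

import numpy as np

import recat
from recat.preprocess import log_transform, normalize, subset_to_catalog

config = recat.CycleSimConfig(n_cells=150, n_genes=150, seed=2)
mat, truth = recat.simulate_expression(config)
catalog = recat.make_catalog(truth)
log_mat = subset_to_catalog(log_transform(normalize(mat)), catalog)

pair_model = recat.train_gene_pairs(log_mat, np.array(truth.stage), pairs_per_stage=50)
sets = recat.MeanScoreSets.from_catalog(catalog)
order = recat.ConsensusOrder(truth.phi, log_mat.cell_ids)  # true order, for clarity
track = recat.score_track(order, log_mat, pair_model, sets)

hmm, path = recat.segment_stages(track, include_g0=False, seed=2, refit=False)
print(f"chosen start: rotation {path.rotation}, orientation {path.orientation:+d}")
print("stage proportions:", {s: round(p, 3) for s, p in path.proportions().items()})

truth_by_cell = dict(zip(truth.cell_ids, truth.stage))
agree = np.mean([truth_by_cell[c] == st for c, st in zip(path.unit_ids, path.labels)])
print(f"agreement with true stage labels: {agree:.3f}")
print("(proportions reflect the 0.4/0.3/0.3 G1/S/G2M arcs of the generator)")
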