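# recat

Circular cell-cycle pseudotime from unsynchronized single-cell
transcriptomes — consensus traveling-salesman ordering, HMM stage
segmentation, Kalman smoothing, nonlinear cycle-gene discovery, and
single-cell methylome overlay.

## The problem

Unsynchronized single cells captured by scRNA-seq sit at unknown points of
the cell cycle. Single marker genes cannot place a cell (expression is too
stochastic), but the joint profile of a few hundred cycle-regulated genes
can: transcriptomes at adjacent cycle phases are more similar than
transcriptomes at distant phases, and the phases close into a cycle. `recat`
exploits exactly these two assumptions:

1. **Ordering.** Cells are clustered on log expression with a Gaussian
   mixture (log negative-binomial expression is approximately normal) for
   every cluster number k in a sweep (k = 7 … k_max). For each k, cluster
   means become nodes of a Euclidean TSP, solved heuristically by
   *arbitrary insertion* (O(k²), 2 ln k worst-case ratio), keeping the
   shortest of n_fold·k runs. Each per-k tour induces circular positions
   θ ∈ [0, 1) for all cells; the per-k position vectors are aligned (best
   rotation/reflection) and averaged on the circle into one **consensus
   order** that is far more robust than any single tour.
2. **Staging.** Each ordered cell gets a 9-dimensional score vector: three
   *Bayes-scores* (log₁₀ posterior of G1/S/G2M under a naive Bayes model on
   binary gene-pair comparisons e_a ≥ e_b) and six *mean-scores* (mean log₂
   expression of marker sets peaking at G1, G1/S, S, G2, G2/M, M). A
   left-to-right hidden Markov model with Gaussian emissions — transitions
   only to self or to the physiologically next stage — is fit by Baum-Welch;
   every rotation and orientation of the circular track is tried and the
   likelihood-maximizing start defines where the cycle begins. Viterbi then
   labels every cell G0/G1/S/G2M.
3. **Smoothing & gene discovery.** Per-gene series along the order follow a
   random-walk-plus-noise model (e_t = z_t + v, z_t = z_{t−1} + w); the
   latent level ẑ_t comes from a forward Kalman filter plus backward
   Rauch–Tung–Striebel pass. Association of ẑ with the time index is scored
   by distance correlation and Kraskov k-NN mutual information — both detect
   the non-monotone dependence the cycle produces — with permutation
   p-values, BH q-values, and standardized significance scores.
4. **Methylation overlay.** Per-cell CpG calls (binarized by majority of
   methylated vs unmethylated counts) give genome-wide or promoter-window
   (TSS ± 3 kb) methylation levels, projected on the order and smoothed with
   a 9-point moving average.

A synthetic-data module generates all inputs with known ground truth
(circular phase, stage arcs, two-wave gene peak structure, negative-binomial
noise, library-size variation, dropout, optional quiescent G0 arc), so every
claim above is testable end to end.

## Worked example

`examples/01_reconstruct_order.py` simulates 300 cells, reconstructs the
consensus order, and evaluates it against the known phase:

```
cells: 300, cycle genes: 176
granularities merged: k = [7, 8, ..., 30]
circular rank correlation with true phase: consensus 0.988, single k=8 0.953
correlation-score vs stage labels: 0.899
change-index of the linearized series: 0.963
```

The consensus order tracks the true phase almost perfectly and beats the
single fixed-granularity tour. The *correlation-score* is the maximum
Pearson correlation between stage labels and predicted order over all 2k
cut/reversal linearizations of the cycle; the *change-index*,
1 − (s_c − 2)/(N − 3) for s_c adjacent label changes, is 1 when labels
change only at the two ideal stage transitions and 0 for the worst case.

The other examples segment stages (`02`, typical stage agreement ≈ 1.0 on
clean simulations), rank cycle genes (`03` — the top of the table is
enriched for true cycling genes, ranked by the permutation-standardized
dCor significance `dcor_z`), and overlay methylation (`04` — the smoothed
track peaks inside the simulated elevation arc).

A command-line interface mirrors the workflow:

```bash
recat simulate --out bundle/ --cells 300 --genes 200 --seed 1
recat order --expr bundle/expression.tsv --catalog bundle/catalog.tsv \
      --unit counts --min-genes 10 --kmin 7 --nfold 2 --seed 1 --out order.tsv
recat eval  --order order.tsv --labels bundle/labels.tsv
recat run   --config run.yaml        # full pipeline with manifest
```

## Layout

- `src/recat/` — the library: `matrix`/`preprocess` (I/O, QC,
  median-of-ratios size factors), `cluster` (GMM), `tsp` + `consensus`
  (ordering), `scores` (Bayes- and mean-scores), `hmm` (segmentation),
  `kalman` + `association` (smoothing and gene ranking), `methylation`,
  `evaluation` (correlation-score, change-index), `synthetic` (generator),
  `pipeline` + `cli`.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details, and known limitations.
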