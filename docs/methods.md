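# Methods

## Model and assumptions

The package reconstructs a **circular pseudotime** for unsynchronized single
cells under two assumptions: (i) cell-cycle phases form a cycle, and (ii)
the transcriptome at a phase is closer (in Euclidean distance on log
expression of cycle genes) to its neighboring phases than to distant ones.
Under these assumptions the correct order of phase representatives is the
shortest Hamilton cycle over them, which motivates the TSP formulation.
Both assumptions fail when a non-cycle process dominates the variance
(differentiation, batch) — see Limitations.

### Preprocessing

For TPM/FPKM data, cells are eligible when strictly more than `min_genes`
(default 4000) genes exceed expression `min_expr` (default 2); both bounds
are strict. Genes with mean expression below `min_mean` (default 2,
boundary inclusive — equality is kept) are dropped. Count data carries no
universal eligibility rule; the thresholds are exposed and must be chosen
per protocol. Depth normalization uses median-of-ratios size factors with
the reference-gene convention (genes positive in every cell; no
pseudocounts), then log₂(x + 1). Analysis is restricted to a cycle-gene
catalog (a Cyclebase-style list of genes with annotated peak stage and
rank); matching is exact and case-sensitive with an opt-in case-insensitive
fallback, because silent case folding hides id-scheme mismatches.

### Clustering and ordering

Cells are clustered with a Gaussian mixture (EM, scikit-learn) on the log₂
layer. Covariances are **diagonal with a 1e-6 variance floor**: with a few
hundred genes and clusters of tens of cells, full covariances are singular.
Initialization is k-means++ with `n_init = 10` restarts; hard labels are
argmax responsibilities with ties to the lowest index, so downstream
ordering is deterministic given the seed.

Arbitrary insertion builds a tour from a random initial edge, repeatedly
inserting a uniformly chosen remaining node at the position of least length
increase (ties at the smallest insertion index). `best_tour` keeps the
shortest of `n_fold · k` seeded runs; the seed scheme spawns child seeds
from one master `SeedSequence`, so enlarging `n_fold` adds runs without
changing earlier ones (tour length is monotone in `n_fold`) and runs are
reproducible and parallelizable.

The **consensus order** sweeps k from `k_min = 7` to
`k_max = min(n/10, 30)` (each cluster keeps ≥ 10 cells on average). Each
per-k tour induces cell positions: cluster j along the tour owns the arc
[j/k, (j+1)/k), and member cells are spread uniformly inside it, ordered by
projection onto the direction from the previous to the next cluster mean.
Per-k position vectors are aligned to the k_min reference — for both
orientations, the optimal rotation is the circular mean of the per-cell
offsets, and the orientation with the larger mean resultant length wins —
then averaged per cell on the circle. This merge rule is one concrete
choice among several reasonable ones: it reproduces the common order when
all tours agree and degrades gracefully under noise, but it is an
interpretation, not the only possible consensus scheme. Degenerate fits at
some k (collapsed clusters) are skipped with a warning; at least two usable
granularities are required.

### Stage scores

*Bayes-scores* use binary gene-pair features x_i = [e_a ≥ e_b] (ties count
as 1, deterministically). Training computes, per ordered pair, the fraction
of each stage's cells with the feature set; pairs are ranked per stage by
the margin between that stage's fraction and the best other stage, the top
`pairs_per_stage = 100` per stage (positive margin only) are unified, and
per-stage probabilities are re-estimated with Laplace (+1/+2) smoothing so
they stay strictly inside (0, 1). The score for stage σ is
log₁₀ P(x | σ) + log₁₀ P(σ) with uniform priors 1/3 — always ≤ log₁₀(1/3).
Because only comparisons enter, the features are invariant to any monotone
per-cell transform of expression. A pre-trained model shipped in
`data/gene_pair_model_synthetic.json` was trained on the synthetic
generator (labels from true phase) and only applies to matrices with the
generator's gene naming; real data should retrain on any labeled matrix.

*Mean-scores* are the arithmetic means of log₂ expression over six marker
sets keyed by catalog peak stage (G1, G1/S, S, G2, G2/M, M); genes missing
from the matrix are skipped with a warning, an empty set is an error.

Both score families can be computed per cell or per cluster (cluster-mean
expression, clusters ordered by circular mean position); cell granularity
is the default.

### HMM segmentation

States are G1 → S → G2M, optionally with G0 prepended (G0 → G1 → S → G2M).
G0 biologically branches from G1; placing it first is the simplest chain
consistent with forward-only progression and with the start search, and is
an interpretation. Emissions are 9-dimensional Gaussians with diagonal
covariance (floor 1e-6). Transitions are allowed only to self or the next
stage; the chain is open (no wrap transition) because the start search
already handles circularity. Baum-Welch (hmmlearn) preserves the structural
zeros. Initialization anchors state identity to the score semantics: G1/S/
G2M emission means start from the top-quartile cells by the corresponding
Bayes-score, G0 from the bottom quartile by mean-score sum (quiescent cells
show globally depressed cycle-gene expression); degenerate anchors fall
back to contiguous quantile slices of the track. If a state never receives
posterior mass its transition row is made self-absorbing rather than
failing. The start search tries every rotation and both orientations,
refitting per rotation by default; `refit=False` (`--fast-start`) fits once
and only re-scores, n-fold cheaper, appropriate for long tracks.

### Kalman smoothing and gene ranking

Per-gene series along the order follow the scalar local level model
(random walk plus noise). The filter uses **exact diffuse initialization**
(the first observation initializes the level with variance σ_e²), so the
two boundary regimes are exact: σ_e = 0 reproduces the data, σ_z = 0
returns the sample mean. `fit_rwp` estimates (σ_e, σ_z) by bounded
maximum likelihood (L-BFGS-B on the diffuse-conditional likelihood from
several starts, bounds [0, ∞)); bounded MLE was chosen over EM because the
boundary solutions are first-class here and are reached exactly, whereas EM
approaches them only asymptotically. A method-of-moments alternative
(from the variance and lag-1 autocovariance of first differences) is
provided for very short series and for bulk refitting. Constant series are
flagged degenerate.

Association of the smoothed level ẑ with the ordinal index t = 1…T uses
distance correlation (double-centered V-statistic form, so dCor ∈ [0, 1]
and equals 1 under affine dependence) and the Kraskov type-1 k-NN mutual
information (k = 3, max-norm, marginals standardized — MI is invariant to
monotone marginal transforms and max-norm neighborhoods need comparable
scales — ties broken by seeded 1e-10 jitter; estimates can be slightly
negative near independence).

Two subtleties drive the ranking design. First, the permutation null must
rerun the *entire* fit-and-smooth pipeline on each permuted series —
reusing the observed fit breaks exchangeability — so the in-ranking fit
defaults to the O(T) moments estimator (thousands of refits per gene);
p-values are then exactly uniform under independence. Second, raw dCor on
smoothed series is not comparable across genes: a noise gene whose fitted
level wanders produces a smooth chance trend with dCor near 1. Genes are
therefore ranked by the permutation-standardized significance score
z = (observed − null mean)/null sd of dCor (ties by gene id); with
`n_perm = 0` the raw statistic is the only option and is used. When the
fitted state variance is zero the model calls the series white noise around
a constant — its smoothed level is flat and carries no signal — so the raw
series is scored instead (smoothing at near-zero signal-to-noise would
manufacture a global chance trend). Multiple testing uses Benjamini-
Hochberg across genes.

### Methylation overlay

CpG calls are binarized by majority: 1 if methylated reads exceed
unmethylated, 0 for the converse, missing on ties (including 0/0) — ties
carry no direction and assigning them either way would bias the level.
Genome-wide level = methylated calls / measured calls. Promoter windows
are TSS ± 3000 bp, strand-aware (start for +, end for −), clipped at the
chromosome start; BED input is 0-based half-open, CpG tables 1-based
(bismark-coverage dialect), converted in one place. Region-set levels are
site-pooled by default (one ratio over all measured CpGs in any window;
overlaps never double-count a site) because pooling is robust to windows
with a single CpG; an unweighted per-region average is available behind a
flag. Tracks along the order are smoothed with a 9-point centered moving
average whose edge windows truncate; NaN levels (cells with no measured
CpG in the region set) are ignored within windows.

### Evaluation metrics

The correlation-score of a k-cluster cycle against integer stage labels is
the maximum Pearson correlation over all 2k cut/reversal linearizations,
each assigning cells the sequential index of their cluster. Scoring a
cell-level consensus order takes the k = n limit (every cell its own
cluster). Note that even a perfectly sorted cell-level series scores
slightly below 1, because a staircase of labels is not linear in per-cell
rank; the score is exactly 1 when clusters coincide with label groups in
order. The change-index is 1 − (s_c − 2)/(N − 3); degenerate series with
fewer than two changes are clamped to 1 with a warning, and N < 4 is an
error. G0 labels merge into label 1 by default; the mapping is
configurable.

## The synthetic generator

The generator emulates what the method assumes and nothing more. Each cell
has a phase φ ~ U[0, 1); stages occupy arcs — an optional G0 arc of
configurable fraction, then G1/S/G2M at 0.4/0.3/0.3 of the cycling part
(typical mammalian proportions). Cycle genes (fraction 0.9 of 200 by
default) have mean baseline + amplitude · exp(κ(cos 2π(φ − peak) − 1)) — a
periodic, unimodal von-Mises-style bump (κ = 5) whose peak is well defined,
unlike a raw sinusoid. Peak phases are drawn from a two-component circular
mixture centered on the G1 and G2 arcs, reproducing the two observed waves
of cycle-gene expression; the six-way peak-stage annotation of the derived
catalog comes from a fixed partition of the cycling arc. Baselines are
log-normal (ln-mean 3.0 ≈ 20 counts, ln-sd 0.5), amplitude = 2 × baseline.
Counts are negative binomial (var = μ + 0.2 μ²) scaled by mean-one
log-normal library sizes (ln-sd 0.3), with dropout probability
0.1 · exp(−μ/5) — decaying with the mean, as in real protocols, which also
keeps reference genes available for median-of-ratios. G0 cells express
cycle genes at 0.4 × baseline with no cyclic component (quiescence switches
the program off). Defaults are 300 cells × 200 genes.

What the generator does **not** emulate: batch effects, doublets,
cell-size/phase-dependent library size, gene-gene correlation beyond the
shared phase, UMI structure, or any real dataset's moments. Passing tests
on this generator shows the machinery recovers structure it is designed
for; it does not certify performance on real data with those confounders.

The methylome generator elevates a cell's global methylation probability by
a constant inside a phase arc (default [0.35, 0.55), around G1/S), with
binomial counts at 1 + Poisson coverage over ~400 CpGs on one synthetic
chromosome, each cell measuring a random 60% of sites.

## Numerical choices

- Variance floors: 1e-6 for GMM and HMM diagonal covariances.
- Circular positions wrap through a guarded mod that never returns 1.0.
- Tie-breaks are all deterministic: lowest cluster index (GMM hard labels),
  smallest insertion index (TSP), smallest rotation / +1 orientation first
  (start search), gene id (rankings).
- Master seeds spawn child seeds via `numpy.random.SeedSequence` with a
  fixed counter scheme; all derived seeds stay below 2³¹.
- Problem sizes in tests and examples (e.g. 10 seeds × 300 cells for the
  consensus-vs-single comparison, n = 5000 for the Gaussian MI check) were
  chosen to make the statistical assertions stable at desk scale.

## Known limitations

- The consensus merge scheme is an interpretation (see above); published
  descriptions of consensus tour merging leave the algorithm open.
- Whether Bayes-scores feed the HMM per cell or per cluster is ambiguous in
  the field; both granularities are exposed, cell-level is default.
- Batch effects can masquerade as clean cycles: if cells with the same
  stage label were processed together, clustering recovers batches and
  scores look deceptively good. The package does not correct batches.
- The change-index presumes a series genuinely traversing three stages;
  degenerate label sets are clamped, not modeled.
- MIC (a third nonlinear statistic sometimes used for this task) is not
  implemented; dCor and KNN-MI cover the use cases here.
- The shipped gene-pair model is synthetic; treat it as a format example
  and retrain for real data.
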