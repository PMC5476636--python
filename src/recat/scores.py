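"""Stage-membership scores along the recovered order.

Two score families describe how strongly a cell (or cluster) looks like each
cell-cycle stage:

* **Bayes-scores** — a supervised naive Bayes model over binary gene-pair
  comparisons.  For each informative pair (a, b) the feature is whether
  e_a >= e_b; per stage the model stores the probability p_i of that outcome,
  and the score is log10 of the joint Bernoulli likelihood times a uniform
  prior over {G1, S, G2M}.  Rank-based features are robust to per-cell
  monotone distortions of expression.
* **mean-scores** — unsupervised means of log2 expression over six marker
  gene sets keyed by peak stage {G1, G1/S, S, G2, G2/M, M}.

Stacked (3 Bayes + 6 mean) they form the 9-dimensional emission vector the
stage-segmentation HMM consumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusOrder
from .matrix import ExpressionMatrix, GeneCatalog, ValidationError

BAYES_STAGES = ("G1", "S", "G2M")
SCORE_COLUMNS = (
    "bayes_G1", "bayes_S", "bayes_G2M",
    "mean_G1", "mean_G1S", "mean_S", "mean_G2", "mean_G2M", "mean_M",
)
_MEAN_SET_STAGES = ("G1", "G1/S", "S", "G2", "G2/M", "M")


@dataclass
class GenePairModel:
    """Trained gene-pair naive Bayes classifier for {G1, S, G2M}."""

    pairs: list[tuple[str, str]]                  # unified pair set, size N_p
    probs: dict[str, np.ndarray]                  # stage -> p_i per pair, in (0,1)
    priors: dict[str, float] = field(default_factory=lambda: {s: 1 / 3 for s in BAYES_STAGES})
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stage in BAYES_STAGES:
            p = np.asarray(self.probs[stage], dtype=float)
            if p.shape != (len(self.pairs),):
                raise ValidationError("probability vector length mismatch")
            if np.any(p <= 0) or np.any(p >= 1):
                raise ValidationError("pair probabilities must lie strictly in (0,1)")
            self.probs[stage] = p
        if not np.isclose(sum(self.priors.values()), 1.0):
            raise ValidationError("priors must sum to 1")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "pairs": [list(p) for p in self.pairs],
                "probs": {s: self.probs[s].tolist() for s in BAYES_STAGES},
                "priors": self.priors,
                "meta": self.meta,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GenePairModel":
        d = json.loads(text)
        return cls(
            pairs=[tuple(p) for p in d["pairs"]],
            probs={s: np.asarray(v, dtype=float) for s, v in d["probs"].items()},
            priors={s: float(v) for s, v in d["priors"].items()},
            meta=d.get("meta", {}),
        )


@dataclass
class MeanScoreSets:
    """Six marker gene sets keyed by peak stage."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for stage in _MEAN_SET_STAGES:
            if not self.sets.get(stage):
                raise ValidationError(f"empty marker set for stage {stage}")

    @classmethod
    def from_catalog(cls, catalog: GeneCatalog, n_per_stage: int | None = None) -> "MeanScoreSets":
        if n_per_stage is not None:
            catalog = catalog.top_ranked(n_per_stage)
        return cls({s: catalog.genes_for_stage(s) for s in _MEAN_SET_STAGES})


@dataclass
class ScoreTrack:
    """Per ordered unit (cell or cluster), the 9-dim score vector o_i."""

    scores: np.ndarray             # (T, 9): 3 Bayes then 6 mean scores
    unit_ids: list[str]
    granularity: str = "cell"      # or "cluster"
    cells_per_unit: list[list[str]] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 9:
            raise ValidationError("score track must be T x 9")
        if self.scores.shape[0] != len(self.unit_ids):
            raise ValidationError("track length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("non-finite scores")

    def __len__(self) -> int:
        return self.scores.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=list(SCORE_COLUMNS))
        df.insert(0, "rank", np.arange(len(self)))
        df.insert(0, "unit_id", self.unit_ids)
        return df

    def reversed(self) -> "ScoreTrack":
        cpu = self.cells_per_unit[::-1] if self.cells_per_unit is not None else None
        return ScoreTrack(self.scores[::-1].copy(), self.unit_ids[::-1], self.granularity, cpu)


def load_default_pair_model() -> GenePairModel:
    """The shipped gene-pair model (synthetic training data; see its meta).

    Trained on the synthetic generator with stage labels from the true phase;
    it applies to matrices using the generator's gene naming.  Real data sets
    should retrain with :func:`train_gene_pairs` on any labeled matrix.
    """
    from importlib import resources

    text = resources.files("recat").joinpath("data/gene_pair_model_synthetic.json").read_text()
    return GenePairModel.from_json(text)


# ---------------------------------------------------------------------------
# training and scoring
# ---------------------------------------------------------------------------

def _pair_fractions(values: np.ndarray) -> np.ndarray:
    """f[a, b] = fraction of columns (cells) with values[a] >= values[b]."""
    m = values.shape[0]
    out = np.empty((m, m), dtype=float)
    chunk = max(1, int(2e7 // max(1, values.shape[1] * m)))
    for start in range(0, m, chunk):
        stop = min(m, start + chunk)
        out[start:stop] = (values[start:stop, None, :] >= values[None, :, :]).mean(axis=2)
    return out


def train_gene_pairs(
    mat: ExpressionMatrix,
    labels: pd.Series | dict[str, str] | np.ndarray,
    pairs_per_stage: int = 100,
) -> GenePairModel:
    """Select informative gene pairs per stage and estimate their probabilities.

    For every ordered pair (a, b), f_stage is the fraction of that stage's
    cells with e_a >= e_b.  Pairs are ranked for stage s by the margin
    f_s - max_other f_other; the top ``pairs_per_stage`` per stage (with
    strictly positive margin) are kept, unified, and each stage's p_i is
    re-estimated on the unified set with Laplace (+1/+2) smoothing.
    """
    if mat.layer != "log2":
        raise ValidationError("train_gene_pairs expects the log2 layer")
    labels = _as_label_array(labels, mat.cell_ids)
    for stage in BAYES_STAGES:
        if (labels == stage).sum() < 2:
            raise ValidationError(f"need >= 2 training cells for stage {stage}")
    frac = {s: _pair_fractions(mat.values[:, labels == s]) for s in BAYES_STAGES}
    m = mat.n_genes
    off_diag = ~np.eye(m, dtype=bool)
    selected: set[tuple[int, int]] = set()
    for stage in BAYES_STAGES:
        others = np.maximum.reduce([frac[s] for s in BAYES_STAGES if s != stage])
        margin = np.where(off_diag, frac[stage] - others, -np.inf)
        flat = np.argsort(margin, axis=None, kind="stable")[::-1]
        picked = 0
        for idx in flat:
            if picked >= pairs_per_stage:
                break
            a, b = divmod(int(idx), m)
            if margin[a, b] <= 0:
                break
            selected.add((a, b))
            picked += 1
        if picked < pairs_per_stage:
            warnings.warn(
                f"only {picked} informative pairs for stage {stage} "
                f"(requested {pairs_per_stage})",
                stacklevel=2,
            )
    if not selected:
        raise ValidationError("no informative gene pairs found")
    pair_idx = sorted(selected)
    genes = mat.gene_ids
    pairs = [(genes[a], genes[b]) for a, b in pair_idx]
    probs: dict[str, np.ndarray] = {}
    for stage in BAYES_STAGES:
        cells = mat.values[:, labels == stage]
        n_stage = cells.shape[1]
        ones = np.array([(cells[a] >= cells[b]).sum() for a, b in pair_idx], dtype=float)
        probs[stage] = (ones + 1.0) / (n_stage + 2.0)
    return GenePairModel(pairs=pairs, probs=probs, meta={"n_pairs": len(pairs)})


def _as_label_array(labels, cell_ids: list[str]) -> np.ndarray:
    if isinstance(labels, pd.Series):
        return labels.reindex(cell_ids).to_numpy(dtype=object).astype(str)
    if isinstance(labels, dict):
        return np.array([labels[c] for c in cell_ids], dtype=str)
    arr = np.asarray(labels).astype(str)
    if arr.shape != (len(cell_ids),):
        raise ValidationError("label vector length mismatch")
    return arr


def bayes_scores(model: GenePairModel, expr: pd.Series) -> np.ndarray:
    """log10(P(x|stage) * P(stage)) for {G1, S, G2M} on one expression vector.

    The binary feature is x_i = 1 if e_a >= e_b (ties count as 1,
    deterministically) else 0.
    """
    if not isinstance(expr, pd.Series):
        raise ValidationError("expr must be a pandas Series indexed by gene id")
    for a, b in model.pairs:
        if a not in expr.index:
            raise ValidationError(f"gene {a!r} required by the pair model is missing")
        if b not in expr.index:
            raise ValidationError(f"gene {b!r} required by the pair model is missing")
    x = np.array([1.0 if expr[a] >= expr[b] else 0.0 for a, b in model.pairs])
    out = np.empty(3)
    for j, stage in enumerate(BAYES_STAGES):
        p = model.probs[stage]
        out[j] = np.log10(model.priors[stage]) + np.sum(
            x * np.log10(p) + (1 - x) * np.log10(1 - p)
        )
    return out


def mean_scores(expr: pd.Series, sets: MeanScoreSets) -> np.ndarray:
    """Mean log2 expression of each stage's marker set, in the order
    (G1, G1/S, S, G2, G2/M, M).  Genes absent from ``expr`` are skipped."""
    out = np.empty(6)
    for j, stage in enumerate(_MEAN_SET_STAGES):
        genes = sets.sets[stage]
        present = [g for g in genes if g in expr.index]
        if not present:
            raise ValidationError(f"no marker genes of stage {stage} present in expression")
        if len(present) < len(genes):
            warnings.warn(
                f"{len(genes) - len(present)} marker genes of {stage} absent; skipped",
                stacklevel=2,
            )
        out[j] = float(expr[present].mean())
    return out


def score_track(
    order: ConsensusOrder,
    mat: ExpressionMatrix,
    model: GenePairModel,
    sets: MeanScoreSets,
    granularity: str = "cell",
) -> ScoreTrack:
    """9-dim score vectors along the recovered order (Bayes scores first).

    At ``cluster`` granularity the reference clustering stored on the order is
    used: scores are computed on cluster-mean log expression, clusters sorted
    by the circular mean position of their members.
    """
    if set(order.cell_ids) != set(mat.cell_ids):
        raise ValidationError("order and matrix cover different cells")
    df = mat.to_frame()
    if granularity == "cell":
        ordered = [order.cell_ids[i] for i in order.linear_order]
        scores = np.vstack(
            [np.concatenate([bayes_scores(model, df[c]), mean_scores(df[c], sets)])
             for c in ordered]
        )
        return ScoreTrack(scores, ordered, "cell", [[c] for c in ordered])
    if granularity == "cluster":
        if order.ref_labels is None:
            raise ValidationError("order carries no reference clustering")
        from .circular import circular_mean

        labels = np.asarray(order.ref_labels)
        clusters = sorted(
            np.unique(labels), key=lambda c: circular_mean(order.theta[labels == c])
        )
        rows, ids, cpu = [], [], []
        for c in clusters:
            members = [order.cell_ids[i] for i in np.flatnonzero(labels == c)]
            mean_expr = df[members].mean(axis=1)
            rows.append(np.concatenate([bayes_scores(model, mean_expr), mean_scores(mean_expr, sets)]))
            ids.append(f"cluster_{c}")
            cpu.append(members)
        return ScoreTrack(np.vstack(rows), ids, "cluster", cpu)
    raise ValidationError("granularity must be 'cell' or 'cluster'")
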