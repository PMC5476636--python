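"""Nonlinear association statistics and cycle-gene ranking.

Expression along the cycle is non-monotone, so Pearson/Spearman correlation
with the time index cannot detect it.  Two statistics that can are:

* distance correlation (dCor): zero iff independent, computed from
  doubly-centered pairwise distance matrices;
* Kraskov-type k-nearest-neighbor mutual information (KSG type 1, max-norm).

``rank_cycle_genes`` smooths every gene with the random-walk-plus-noise
smoother, scores the smoothed series against the time index, attaches
permutation p-values (the raw series is permuted and the whole fit-and-
smooth pipeline rerun per draw, so smoothing-induced autocorrelation is part
of the null), Benjamini-Hochberg q-values and standardized significance
scores, and ranks genes by significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .consensus import ConsensusOrder
from .kalman import RwpModel, fit_rwp, rts_smooth
from .matrix import ExpressionMatrix, ValidationError


def _double_center(x: np.ndarray) -> np.ndarray:
    a = np.abs(x[:, None] - x[None, :])
    return a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()


def _dcor_centered(A: np.ndarray, B: np.ndarray) -> float:
    dcov2 = (A * B).mean()
    denom = np.sqrt((A * A).mean() * (B * B).mean())
    if denom <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def dcor(x: np.ndarray, y: np.ndarray) -> float:
    """Distance correlation in [0, 1] from doubly-centered distance matrices.

    Constant input has no defined value; it is reported as 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("dcor expects two equal-length 1-D series")
    if x.size < 2:
        raise ValidationError("dcor needs at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input to dcor; returning 0", stacklevel=2)
        return 0.0
    return _dcor_centered(_double_center(x), _double_center(y))


def knn_mi(x: np.ndarray, y: np.ndarray, k_neighbors: int = 3, seed: int = 0) -> float:
    """KSG type-1 mutual information estimate in nats (max-norm neighborhoods).

    Both marginals are standardized first (MI is invariant under monotone
    marginal transforms, and max-norm neighborhoods need comparable scales);
    ties are broken by seeded jitter of 1e-10 relative scale.  The estimator
    is consistent but can be slightly negative near independence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("knn_mi expects two equal-length 1-D series")
    n = x.size
    if n <= k_neighbors:
        raise ValidationError(f"need more than k={k_neighbors} observations, got {n}")
    rng = np.random.default_rng(seed)
    x = (x - x.mean()) / (x.std() or 1.0)
    y = (y - y.mean()) / (y.std() or 1.0)
    x = x + rng.normal(0, 1e-10, n)
    y = y + rng.normal(0, 1e-10, n)
    xy = np.column_stack([x, y])
    tree_xy = cKDTree(xy)
    # distance to the k-th neighbor in max-norm (exclude the point itself)
    dist, _ = tree_xy.query(xy, k=k_neighbors + 1, p=np.inf)
    eps = dist[:, -1]
    tree_x = cKDTree(x[:, None])
    tree_y = cKDTree(y[:, None])
    # strict inequality: count neighbors at distance < eps_i (shrink by a hair)
    radius = eps * (1 - 1e-12)
    nx = tree_x.query_ball_point(x[:, None], radius, p=np.inf, return_length=True) - 1
    ny = tree_y.query_ball_point(y[:, None], radius, p=np.inf, return_length=True) - 1
    return float(
        digamma(k_neighbors) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    )


@dataclass
class AssociationResult:
    gene: str
    dcor: float
    mi: float
    dcor_p: float | None = None
    mi_p: float | None = None
    dcor_q: float | None = None
    mi_q: float | None = None
    dcor_z: float | None = None   # permutation-standardized significance score
    mi_z: float | None = None
    rank: int | None = None


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def _smoothed(e: np.ndarray, estimator: str) -> np.ndarray:
    """Denoised series for association scoring.

    When the fitted state variance is zero the model calls the series white
    noise around a constant; its smoothed level is flat and carries no
    association signal, so the raw series is scored instead.  (Smoothing with
    a near-zero signal-to-noise ratio would instead manufacture a global
    chance trend with spuriously high dCor.)
    """
    if np.ptp(e) == 0:
        return e
    model = fit_rwp(e, method=estimator)
    if model.sigma_z == 0 or model.degenerate:
        return e
    return rts_smooth(model, e).z_hat


def rank_cycle_genes(
    mat: ExpressionMatrix,
    order: ConsensusOrder,
    n_perm: int = 200,
    seed: int = 0,
    k_neighbors: int = 3,
    smooth: bool = True,
    estimator: str = "moments",
) -> list[AssociationResult]:
    """Score every gene's association with the recovered pseudotime.

    Per gene: reorder the series along the linearization, RWP-smooth it
    (``smooth=False`` scores the raw series), then compute dCor and KNN-MI
    against the ordinal time index 1..T.  The permutation null shuffles the
    raw series and reruns the identical fit-and-smooth pipeline, so observed
    and null statistics are exchangeable under independence; p-values, BH
    q-values and standardized significance scores (z = (obs - null mean) /
    null sd) follow.  ``estimator`` selects the per-series noise-scale fit
    ("moments" by default: the permutation null needs thousands of refits).

    Smoothing makes raw statistic values incomparable across genes (a noise
    gene smoothed into a chance trend can reach dCor near 1), so genes are
    ranked by the dCor significance score when permutations are run, by the
    raw statistic otherwise; ties break by gene id.
    """
    if set(order.cell_ids) != set(mat.cell_ids):
        raise ValidationError("order and matrix cover different cells")
    col = {c: i for i, c in enumerate(mat.cell_ids)}
    cols = [col[order.cell_ids[i]] for i in order.linear_order]
    series_matrix = mat.values[:, cols]
    T = series_matrix.shape[1]
    t_index = np.arange(1, T + 1, dtype=float)
    B_t = _double_center(t_index)  # constant across genes and permutations
    rng = np.random.default_rng(seed)

    def _dcor_vs_t(z: np.ndarray) -> float:
        if np.ptp(z) == 0:
            return 0.0
        return _dcor_centered(_double_center(z), B_t)

    results: list[AssociationResult] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g, gene in enumerate(mat.gene_ids):
            e = series_matrix[g]
            z = _smoothed(e, estimator) if smooth else e
            d_obs = _dcor_vs_t(z)
            mi_obs = knn_mi(z, t_index, k_neighbors=k_neighbors, seed=seed)
            res = AssociationResult(gene, d_obs, mi_obs)
            if n_perm > 0:
                # fresh draws per gene keep p-values independent across genes
                perms = [rng.permutation(T) for _ in range(n_perm)]
                d_null = np.empty(n_perm)
                mi_null = np.empty(n_perm)
                for j, perm in enumerate(perms):
                    ep = e[perm]
                    zp = _smoothed(ep, estimator) if smooth else ep
                    d_null[j] = _dcor_vs_t(zp)
                    mi_null[j] = knn_mi(zp, t_index, k_neighbors=k_neighbors, seed=seed)
                res.dcor_p = float((1 + np.sum(d_null >= d_obs)) / (n_perm + 1))
                res.mi_p = float((1 + np.sum(mi_null >= mi_obs)) / (n_perm + 1))
                res.dcor_z = _zscore(d_obs, d_null)
                res.mi_z = _zscore(mi_obs, mi_null)
            results.append(res)

    if n_perm > 0:
        dq = _bh_qvalues(np.array([r.dcor_p for r in results]))
        mq = _bh_qvalues(np.array([r.mi_p for r in results]))
        for r, a, b in zip(results, dq, mq):
            r.dcor_q, r.mi_q = float(a), float(b)
        results.sort(key=lambda r: (-r.dcor_z, r.gene))
    else:
        results.sort(key=lambda r: (-r.dcor, r.gene))
    for i, r in enumerate(results):
        r.rank = i + 1
    return results


def _zscore(obs: float, null: np.ndarray) -> float:
    sd = float(null.std())
    if sd == 0:
        return 0.0
    return float((obs - null.mean()) / sd)


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "dcor": [r.dcor for r in results],
            "dcor_p": [r.dcor_p for r in results],
            "dcor_q": [r.dcor_q for r in results],
            "dcor_z": [r.dcor_z for r in results],
            "mi": [r.mi for r in results],
            "mi_p": [r.mi_p for r in results],
            "mi_q": [r.mi_q for r in results],
            "mi_z": [r.mi_z for r in results],
            "rank": [r.rank for r in results],
        }
    )
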