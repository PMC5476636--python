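"""Gaussian-mixture clustering of single cells on log expression.

Log-transformed negative-binomial expression is approximately Gaussian, so
cells are grouped into k mixture components fit by EM; the component means
act as cell-cycle phase representatives and their pairwise Euclidean
distances feed the traveling-salesman ordering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .matrix import ExpressionMatrix, ValidationError

COV_TYPES = {"diagonal": "diag", "full": "full", "spherical": "spherical"}
VARIANCE_FLOOR = 1e-6


@dataclass
class GmmModel:
    """Fitted Gaussian mixture over cells (observations = cells, dims = genes)."""

    k: int
    weights: np.ndarray          # (k,), simplex
    means: np.ndarray            # (k, n_genes)
    covariances: np.ndarray      # diagonal: (k, n_genes)
    responsibilities: np.ndarray  # (n_cells, k), rows sum to 1
    log_likelihood: float
    cov_type: str = "diagonal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValidationError("mixture weights must sum to 1")
        if not np.allclose(self.responsibilities.sum(axis=1), 1.0):
            raise ValidationError("responsibility rows must sum to 1")

    @property
    def hard_labels(self) -> np.ndarray:
        """Argmax responsibility per cell; ties go to the lowest cluster index."""
        return np.argmax(self.responsibilities, axis=1)

    def members(self) -> list[np.ndarray]:
        labels = self.hard_labels
        return [np.flatnonzero(labels == r) for r in range(self.k)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "cov_type": self.cov_type,
                "seed": self.seed,
                "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist(),
                "log_likelihood": self.log_likelihood,
            }
        )


def fit_gmm(
    mat: ExpressionMatrix,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    cov_type: str = "diagonal",
) -> GmmModel:
    """Fit a k-component Gaussian mixture to cells by EM (best of ``n_init`` restarts).

    Expects the log2 layer.  Covariances default to diagonal with a 1e-6
    variance floor: with a few hundred genes and clusters of tens of cells,
    full covariances are singular.
    """
    if mat.layer != "log2":
        raise ValidationError("fit_gmm expects the log2 layer")
    n = mat.n_cells
    if k > n:
        raise ValidationError(f"k={k} exceeds number of cells ({n})")
    if cov_type not in COV_TYPES:
        raise ValidationError(f"cov_type must be one of {sorted(COV_TYPES)}")
    x = mat.values.T  # observations are cells
    gm = GaussianMixture(
        n_components=k,
        covariance_type=COV_TYPES[cov_type],
        reg_covar=VARIANCE_FLOOR,
        n_init=n_init,
        init_params="k-means++",
        random_state=seed,
        max_iter=300,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on degenerate k
        gm.fit(x)
    resp = gm.predict_proba(x)
    if cov_type == "diagonal":
        cov = gm.covariances_
    elif cov_type == "spherical":
        cov = np.repeat(gm.covariances_[:, None], x.shape[1], axis=1)
    else:
        cov = np.array([np.diag(c) for c in gm.covariances_])  # diagonal summary
    return GmmModel(
        k=k,
        weights=gm.weights_,
        means=gm.means_,
        covariances=cov,
        responsibilities=resp,
        log_likelihood=float(gm.score(x) * n),
        cov_type=cov_type,
        seed=seed,
    )


def cluster_distance_matrix(model: GmmModel) -> np.ndarray:
    """Pairwise Euclidean distances between cluster means (symmetric, zero diagonal)."""
    diff = model.means[:, None, :] - model.means[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))
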