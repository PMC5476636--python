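"""Stage segmentation of the ordered score track with a left-to-right HMM.

Hidden states are the cell-cycle stages (optionally including G0), emissions
are the 9-dimensional score vectors modeled as multivariate Gaussians with
diagonal covariance.  Transitions are constrained to self or the
physiologically subsequent stage, so along the linearized series the stage
sequence is non-decreasing.  Because the series is circular, the start point
and orientation are unknown; they are found by trying every rotation (and
both orientations) and keeping the configuration with the highest
likelihood.

Baum-Welch / forward / Viterbi are provided by hmmlearn's GaussianHMM;
structural zeros in the transition matrix are preserved by its EM updates,
which is what enforces the left-to-right chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import logging

from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM

# hmmlearn logs per-iteration convergence chatter and dead-state notices at
# WARNING level; the conditions are handled explicitly below
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

from .matrix import ValidationError
from .scores import ScoreTrack

STAGE_ORDER_G0 = ("G0", "G1", "S", "G2M")
STAGE_ORDER = ("G1", "S", "G2M")
COVAR_FLOOR = 1e-6


class _FullHistoryMonitor(ConvergenceMonitor):
    """hmmlearn's monitor keeps only the last two log-likelihoods; EM
    monotonicity checks need the whole trace."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob: float) -> None:
        self.full_history.append(float(log_prob))
        super().report(log_prob)


def _left_to_right_transmat(n_states: int) -> np.ndarray:
    """Initial transition matrix: mass only on self and successor; the last
    state is absorbing (the chain is open — circularity is handled by the
    start search, not by a wrap transition)."""
    A = np.zeros((n_states, n_states))
    for i in range(n_states - 1):
        A[i, i] = 0.5
        A[i, i + 1] = 0.5
    A[-1, -1] = 1.0
    return A


@dataclass
class CycleHmm:
    """Left-to-right Gaussian HMM over stage-score emissions."""

    states: tuple[str, ...]
    transmat: np.ndarray            # (S, S), rows sum to 1, left-to-right zeros
    means: np.ndarray               # (S, 9)
    covars: np.ndarray              # (S, 9) diagonal variances
    startprob: np.ndarray | None = None
    log_likelihood: float = np.nan
    converged: bool = True
    ll_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        S = len(self.states)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covars = np.maximum(np.asarray(self.covars, dtype=float), COVAR_FLOOR)
        if self.startprob is None:
            self.startprob = np.eye(S)[0]
        self.startprob = np.asarray(self.startprob, dtype=float)
        if self.transmat.shape != (S, S):
            raise ValidationError("transition matrix shape mismatch")
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValidationError("transition rows must sum to 1")
        allowed = np.zeros((S, S), dtype=bool)
        for i in range(S):
            allowed[i, i] = True
            if i + 1 < S:
                allowed[i, i + 1] = True
        if np.any(self.transmat[~allowed] > 1e-12):
            raise ValidationError("transition mass outside {self, successor}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def _to_hmmlearn(self) -> GaussianHMM:
        model = GaussianHMM(
            n_components=self.n_states,
            covariance_type="diag",
            min_covar=COVAR_FLOOR,
            init_params="",
            params="",
        )
        model.n_features = self.means.shape[1]
        model.startprob_ = self.startprob
        model.transmat_ = self.transmat
        model.means_ = self.means
        model.covars_ = self.covars
        return model

    def score(self, X: np.ndarray) -> float:
        """Forward (total) log-likelihood of an observation sequence."""
        return float(self._to_hmmlearn().score(np.asarray(X, dtype=float)))

    def viterbi(self, X: np.ndarray) -> tuple[float, np.ndarray]:
        """Most likely state path and its joint log-likelihood."""
        logprob, path = self._to_hmmlearn().decode(np.asarray(X, dtype=float), algorithm="viterbi")
        return float(logprob), path

    def path_log_likelihood(self, X: np.ndarray, path: np.ndarray) -> float:
        """Joint log-likelihood of observations and one specific state path."""
        from scipy.stats import norm

        X = np.asarray(X, dtype=float)
        path = np.asarray(path, dtype=int)
        ll = np.log(self.startprob[path[0]]) if self.startprob[path[0]] > 0 else -np.inf
        for t in range(1, len(path)):
            a = self.transmat[path[t - 1], path[t]]
            ll += np.log(a) if a > 0 else -np.inf
        for t, s in enumerate(path):
            ll += norm.logpdf(X[t], self.means[s], np.sqrt(self.covars[s])).sum()
        return float(ll)


def _score_heuristic_init(
    X: np.ndarray, states: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray] | None:
    """Anchor state identities to the score semantics of the 9-dim track.

    The G1/S/G2M states are initialized from the cells with the highest
    corresponding Bayes-score (columns 0-2); G0 from the cells with the
    lowest mean-score sum (columns 3-8), the depressed signature of
    quiescence.  Returns None when the track is not 9-dimensional.
    """
    if X.ndim != 2 or X.shape[1] != 9:
        return None
    n = X.shape[0]
    q = max(2, n // 4)
    bayes_col = {"G1": 0, "S": 1, "G2M": 2}
    means, covars = [], []
    for state in states:
        if state == "G0":
            idx = np.argsort(X[:, 3:].sum(axis=1), kind="stable")[:q]
        else:
            idx = np.argsort(X[:, bayes_col[state]], kind="stable")[-q:]
        block = X[idx]
        means.append(block.mean(axis=0))
        covars.append(np.maximum(block.var(axis=0), COVAR_FLOOR))
    means = np.asarray(means)
    if np.any(~np.isfinite(means)) or len({tuple(m) for m in np.round(means, 12)}) < len(states):
        return None  # degenerate anchors; caller falls back to quantile slicing
    return means, np.asarray(covars)


def _quantile_slice_init(X: np.ndarray, n_states: int) -> tuple[np.ndarray, np.ndarray]:
    """Initial emission parameters from contiguous blocks of the series.

    The left-to-right chain visits stages in order along the series, so
    slicing the track into S contiguous quantile blocks gives a deterministic,
    order-consistent starting point for Baum-Welch.
    """
    T = X.shape[0]
    bounds = np.linspace(0, T, n_states + 1).astype(int)
    means, covars = [], []
    for i in range(n_states):
        block = X[bounds[i]:max(bounds[i] + 1, bounds[i + 1])]
        means.append(block.mean(axis=0))
        covars.append(np.maximum(block.var(axis=0), COVAR_FLOOR))
    return np.asarray(means), np.asarray(covars)


def fit_hmm(
    track: ScoreTrack | np.ndarray,
    include_g0: bool = False,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> CycleHmm:
    """Baum-Welch fit of the left-to-right stage HMM to an ordered track.

    ``include_g0`` adds a G0 state before G1 (used when the mean-scores show
    the globally depressed signature of quiescent cells); otherwise the
    states are G1 -> S -> G2M.
    """
    X = track.scores if isinstance(track, ScoreTrack) else np.asarray(track, dtype=float)
    states = STAGE_ORDER_G0 if include_g0 else STAGE_ORDER
    S = len(states)
    if X.shape[0] < 2 * S:
        raise ValidationError(f"track of length {X.shape[0]} too short for {S} states")
    model = GaussianHMM(
        n_components=S,
        covariance_type="diag",
        min_covar=COVAR_FLOOR,
        n_iter=max_iter,
        tol=tol,
        random_state=seed,
        init_params="",
        params="tmc",  # startprob stays fixed at state 0
    )
    heuristic = _score_heuristic_init(X, states)
    inits = ([heuristic] if heuristic is not None else []) + [_quantile_slice_init(X, S)]
    fitted = False
    for means, covars in inits:
        model.monitor_ = _FullHistoryMonitor(tol, max_iter)
        model.startprob_ = np.eye(S)[0]
        model.transmat_ = _left_to_right_transmat(S)
        model.means_ = means
        model.covars_ = covars
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X)
            fitted = True
            break
        except ValueError:
            # a state received no posterior mass (zero transition row), which
            # happens when the series does not start near the first stage;
            # retry from the positional initialization
            continue
    if not fitted:
        # keep the initialization parameters as a degenerate "fit"
        warnings.warn("Baum-Welch collapsed for every initialization", stacklevel=2)
        model.startprob_ = np.eye(S)[0]
        model.transmat_ = _left_to_right_transmat(S)
        model.means_, model.covars_ = inits[-1]
    converged = fitted and bool(model.monitor_.converged)
    # a state the posterior never left ends up with an all-zero transition
    # row; make it self-absorbing (still within the left-to-right structure)
    A = np.asarray(model.transmat_)
    dead = ~np.isfinite(A.sum(axis=1)) | (np.nan_to_num(A, nan=0.0).sum(axis=1) < 1e-12)
    if dead.any():
        A = np.nan_to_num(A, nan=0.0)
        A[dead] = np.eye(S)[dead]
        model.transmat_ = A / A.sum(axis=1, keepdims=True)
    if not converged:
        warnings.warn(f"Baum-Welch did not converge in {max_iter} iterations", stacklevel=2)
    covars_fit = np.array([np.diag(c) for c in model.covars_])
    return CycleHmm(
        states=states,
        transmat=model.transmat_,
        means=model.means_,
        covars=covars_fit,
        startprob=model.startprob_,
        log_likelihood=float(model.score(X)),
        converged=converged,
        ll_history=list(model.monitor_.full_history),
    )


def _orient_and_rotate(X: np.ndarray, rotation: int, orientation: int) -> np.ndarray:
    oriented = X if orientation == 1 else X[::-1]
    return np.roll(oriented, -rotation, axis=0)


def _original_indices(T: int, rotation: int, orientation: int) -> np.ndarray:
    """Original track index of each position of the oriented+rotated series."""
    idx = (np.arange(T) + rotation) % T
    if orientation == -1:
        idx = T - 1 - idx
    return idx


def find_start(
    track: ScoreTrack | np.ndarray,
    include_g0: bool = False,
    seed: int = 0,
    refit: bool = True,
    max_iter: int = 100,
) -> tuple[int, int, float]:
    """Search the cycle start: try every rotation of the circular track (both
    orientations) and return the (rotation, orientation, log-likelihood)
    maximizing the HMM likelihood.

    ``refit=True`` re-runs Baum-Welch per rotation; ``refit=False`` fits once
    on the unrotated series and only re-evaluates likelihoods (n-fold
    cheaper).  Ties break at the smallest rotation, +1 orientation first.
    """
    X = track.scores if isinstance(track, ScoreTrack) else np.asarray(track, dtype=float)
    T = X.shape[0]
    base = None if refit else fit_hmm(X, include_g0=include_g0, seed=seed, max_iter=max_iter)
    best = (-np.inf, 0, 1)
    for orientation in (1, -1):
        for rotation in range(T):
            Xr = _orient_and_rotate(X, rotation, orientation)
            if refit:
                hmm = fit_hmm(Xr, include_g0=include_g0, seed=seed, max_iter=max_iter)
                ll = hmm.log_likelihood
            else:
                ll = base.score(Xr)
            if ll > best[0] + 1e-12:
                best = (ll, rotation, orientation)
    ll, rotation, orientation = best
    return rotation, orientation, ll


@dataclass
class StagePath:
    """Hard stage labels along the original track order, plus the chosen
    start configuration and per-stage tallies."""

    labels: list[str]             # aligned with the track's original unit order
    unit_ids: list[str]
    rotation: int
    orientation: int
    log_likelihood: float
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.unit_ids):
            raise ValidationError("label/unit length mismatch")
        unknown = set(self.labels) - set(self.states)
        if unknown:
            raise ValidationError(f"labels outside the state set: {sorted(unknown)}")

    def counts(self) -> dict[str, int]:
        return {s: self.labels.count(s) for s in self.states}

    def proportions(self) -> dict[str, float]:
        n = len(self.labels)
        return {s: c / n for s, c in self.counts().items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_id": self.unit_ids, "rank": np.arange(len(self.labels)), "stage": self.labels}
        )


def viterbi_stages(
    hmm: CycleHmm,
    track: ScoreTrack | np.ndarray,
    rotation: int = 0,
    orientation: int = 1,
) -> StagePath:
    """Most likely stage assignment under the left-to-right chain, mapped back
    to the track's original unit order."""
    X = track.scores if isinstance(track, ScoreTrack) else np.asarray(track, dtype=float)
    T = X.shape[0]
    Xr = _orient_and_rotate(X, rotation, orientation)
    logprob, path = hmm.viterbi(Xr)
    orig = _original_indices(T, rotation, orientation)
    labels = [""] * T
    for pos, oi in enumerate(orig):
        labels[oi] = hmm.states[path[pos]]
    unit_ids = track.unit_ids if isinstance(track, ScoreTrack) else [str(i) for i in range(T)]
    return StagePath(labels, list(unit_ids), rotation, orientation, logprob, hmm.states)


def segment_stages(
    track: ScoreTrack,
    include_g0: bool = False,
    seed: int = 0,
    refit: bool = True,
    max_iter: int = 100,
) -> tuple[CycleHmm, StagePath]:
    """Full segmentation: start/orientation search, fit, Viterbi."""
    rotation, orientation, _ = find_start(
        track, include_g0=include_g0, seed=seed, refit=refit, max_iter=max_iter
    )
    Xr = _orient_and_rotate(track.scores, rotation, orientation)
    hmm = fit_hmm(Xr, include_g0=include_g0, seed=seed, max_iter=max_iter)
    path = viterbi_stages(hmm, track, rotation, orientation)
    return hmm, path


def stage_proportions(
    path: StagePath, groups: list[str] | np.ndarray | None = None
) -> pd.DataFrame:
    """Per-group stage fractions (rows: groups, columns: stages; rows sum to 1)."""
    labels = np.asarray(path.labels)
    if groups is None:
        groups = np.array(["all"] * labels.size)
    groups = np.asarray(groups)
    if groups.shape != labels.shape:
        raise ValidationError("group vector length mismatch")
    rows = {}
    for g in pd.unique(groups):
        sub = labels[groups == g]
        rows[g] = {s: float((sub == s).mean()) for s in path.states}
    return pd.DataFrame.from_dict(rows, orient="index")[list(path.states)]
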