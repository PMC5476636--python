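"""Random-walk-plus-noise smoothing of per-gene series along the pseudotime.

Log expression along the recovered order is modeled as a local level (random
walk plus noise) state space:

    e_t = z_t + v,   v ~ N(0, sigma_e^2)      (observation)
    z_t = z_{t-1} + w,   w ~ N(0, sigma_z^2)  (latent level)

The latent level z_t is the denoised expression; it is estimated by a
forward Kalman filter followed by the backward Rauch-Tung-Striebel (RTS)
pass.  The two noise scales are estimated by maximum likelihood on the
diffuse-conditional likelihood (the first observation initializes the state
exactly, so boundary cases sigma_e = 0 or sigma_z = 0 are admissible and the
corresponding limits — interpolation of the raw series, or a constant level
at the sample mean — are exact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize


@dataclass
class RwpModel:
    """Fitted random-walk-plus-noise model (scalar local level)."""

    sigma_e: float   # observation noise standard deviation
    sigma_z: float   # state (level) noise standard deviation
    log_likelihood: float = np.nan
    degenerate: bool = False  # constant input series

    def __post_init__(self) -> None:
        if self.sigma_e < 0 or self.sigma_z < 0:
            raise ValueError("noise scales must be nonnegative")
        if self.sigma_e == 0 and self.sigma_z == 0 and not self.degenerate:
            raise ValueError("sigma_e and sigma_z cannot both be zero")


@dataclass
class SmoothedSeries:
    """RTS-smoothed latent level and its smoothing variances."""

    z_hat: np.ndarray
    variance: np.ndarray
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.z_hat = np.asarray(self.z_hat, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if np.any(self.variance < -1e-12):
            raise ValueError("negative smoothing variance")
        self.variance = np.maximum(self.variance, 0.0)


def _filter(e: np.ndarray, var_e: float, var_z: float):
    """Forward Kalman filter with exact diffuse initialization (z_1 | e_1).

    Returns filtered means/variances, one-step predicted variances, and the
    log-likelihood of e_2..e_T given e_1.
    """
    T = e.size
    m = np.empty(T)
    P = np.empty(T)
    P_pred = np.empty(T)  # P_pred[t] = Var(z_t | e_1..e_{t-1}), t >= 1
    m[0], P[0] = e[0], var_e  # diffuse limit after the first observation
    ll = 0.0
    for t in range(1, T):
        mp = m[t - 1]
        Pp = P[t - 1] + var_z
        P_pred[t] = Pp
        F = Pp + var_e
        if F <= 0:  # both noise scales zero: degenerate, level sticks to data
            m[t], P[t] = e[t], 0.0
            ll = -np.inf if e[t] != mp else ll
            continue
        K = Pp / F
        m[t] = mp + K * (e[t] - mp)
        P[t] = (1.0 - K) * Pp
        ll += -0.5 * (np.log(2 * np.pi * F) + (e[t] - mp) ** 2 / F)
    return m, P, P_pred, ll


def rwp_log_likelihood(e: np.ndarray, sigma_e: float, sigma_z: float) -> float:
    """Diffuse-conditional log-likelihood of the series under (sigma_e, sigma_z)."""
    e = np.asarray(e, dtype=float)
    return _filter(e, sigma_e**2, sigma_z**2)[3]


def fit_rwp_moments(e: np.ndarray) -> RwpModel:
    """Method-of-moments noise scales for the random-walk-plus-noise model.

    For first differences d_t = e_t - e_{t-1}: Var(d) = 2 sigma_e^2 +
    sigma_z^2 and Cov(d_t, d_{t-1}) = -sigma_e^2; both estimates are clipped
    at zero.  O(T), no optimization — the estimator of choice for very short
    series and for permutation nulls where thousands of refits are needed.
    """
    e = np.asarray(e, dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 observations to fit the RWP model")
    if np.ptp(e) == 0:
        return RwpModel(0.0, 0.0, log_likelihood=np.inf, degenerate=True)
    d = np.diff(e)
    gamma0 = float(np.var(d))
    gamma1 = float(np.mean((d[1:] - d.mean()) * (d[:-1] - d.mean())))
    var_e = max(-gamma1, 0.0)
    var_z = max(gamma0 - 2 * var_e, 0.0)
    if var_e == 0 and var_z == 0:
        var_z = gamma0
    return RwpModel(
        float(np.sqrt(var_e)), float(np.sqrt(var_z)),
        log_likelihood=_filter(e, var_e, var_z)[3],
    )


def fit_rwp(e: np.ndarray, method: str = "mle") -> RwpModel:
    """Noise scales for the random-walk-plus-noise model.

    ``method="mle"`` (default) optimizes the diffuse-conditional likelihood
    over (sigma_e^2, sigma_z^2) with bounds [0, inf) from several starts, so
    boundary solutions (pure random walk, pure white noise) are reached
    exactly.  ``method="moments"`` uses the O(T) difference-autocovariance
    estimator instead.  A constant series is flagged degenerate with both
    scales zero.
    """
    if method == "moments":
        return fit_rwp_moments(e)
    if method != "mle":
        raise ValueError("method must be 'mle' or 'moments'")
    e = np.asarray(e, dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 observations to fit the RWP model")
    if np.ptp(e) == 0:
        return RwpModel(0.0, 0.0, log_likelihood=np.inf, degenerate=True)
    total_var = float(np.var(e))
    diff_var = float(np.var(np.diff(e)))

    def neg_ll(params):
        ve, vz = params
        return -_filter(e, max(ve, 0.0), max(vz, 0.0))[3]

    starts = [
        (diff_var / 2, diff_var / 2),
        (total_var, 1e-3 * total_var),
        (1e-3 * total_var, diff_var),
        (1e-8 * total_var, diff_var),
        (diff_var, 1e-8 * total_var),
    ]
    best = None
    ub = 100 * total_var
    for s in starts:
        res = minimize(
            neg_ll, x0=np.asarray(s), method="L-BFGS-B",
            bounds=[(0.0, ub), (0.0, ub)],
        )
        if best is None or res.fun < best.fun:
            best = res
    ve, vz = np.maximum(best.x, 0.0)
    # snap near-boundary variances so the exact limits apply
    for i, v in enumerate((ve, vz)):
        if v < 1e-12 * total_var:
            cand = [ve, vz]
            cand[i] = 0.0
            if neg_ll(cand) <= best.fun + 1e-9:
                ve, vz = cand
    if ve == 0 and vz == 0:
        vz = diff_var  # pathological optimizer corner; fall back to moments
    return RwpModel(float(np.sqrt(ve)), float(np.sqrt(vz)), log_likelihood=-float(best.fun))


def rts_smooth(model: RwpModel, e: np.ndarray, gene_id: str | None = None) -> SmoothedSeries:
    """Forward Kalman filter + backward RTS pass for the latent level.

    Limits: sigma_e = 0 returns the observations exactly; sigma_z = 0 returns
    the constant level (the sample mean, under the diffuse start).
    """
    e = np.asarray(e, dtype=float)
    T = e.size
    if model.degenerate or (model.sigma_e == 0 and model.sigma_z == 0):
        return SmoothedSeries(e.copy(), np.zeros(T), gene_id)
    var_e, var_z = model.sigma_e**2, model.sigma_z**2
    m, P, P_pred, _ = _filter(e, var_e, var_z)
    z = np.empty(T)
    V = np.empty(T)
    z[-1], V[-1] = m[-1], P[-1]
    for t in range(T - 2, -1, -1):
        Pp = P_pred[t + 1]
        C = P[t] / Pp if Pp > 0 else 0.0
        z[t] = m[t] + C * (z[t + 1] - m[t] - 0.0)  # state transition is identity
        V[t] = P[t] + C**2 * (V[t + 1] - Pp)
    return SmoothedSeries(z, V, gene_id)


def smooth_series(e: np.ndarray, gene_id: str | None = None) -> SmoothedSeries:
    """Convenience: fit the RWP model and smooth in one call."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rts_smooth(fit_rwp(e), e, gene_id)
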