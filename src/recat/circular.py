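"""Small helpers for circular quantities on [0, 1)."""

from __future__ import annotations

import numpy as np


def wrap_unit(theta):
    """Wrap onto [0, 1); guards against np.mod returning exactly 1.0 for tiny
    negative inputs."""
    out = np.mod(theta, 1.0)
    return np.where(out >= 1.0, 0.0, out) if np.ndim(out) else (0.0 if out >= 1.0 else float(out))


def circular_mean(theta: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """Circular mean of positions on [0, 1) via unit-vector averaging."""
    ang = 2 * np.pi * np.asarray(theta, dtype=float)
    mean = np.arctan2(np.sin(ang).mean(axis=axis), np.cos(ang).mean(axis=axis))
    return wrap_unit(mean / (2 * np.pi))


def resultant_length(theta: np.ndarray) -> float:
    """Mean resultant length R in [0, 1]; 1 means perfectly concentrated."""
    ang = 2 * np.pi * np.asarray(theta, dtype=float)
    return float(np.hypot(np.sin(ang).mean(), np.cos(ang).mean()))


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee circular correlation between two position vectors on [0, 1).

    Lies in [-1, 1]; sign flips when one argument reverses orientation, so
    comparisons of recovered vs true phase use the absolute value.
    """
    x = 2 * np.pi * np.asarray(a, dtype=float)
    y = 2 * np.pi * np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    num = 0.0
    # O(n^2) pairwise form; fine for the sizes used here
    sin_dx = np.sin(x[:, None] - x[None, :])
    sin_dy = np.sin(y[:, None] - y[None, :])
    num = (sin_dx * sin_dy).sum()
    den = np.sqrt((sin_dx**2).sum() * (sin_dy**2).sum())
    if den == 0:
        return 0.0
    return float(num / den)


def circular_rank(theta: np.ndarray) -> np.ndarray:
    """Uniform ranks on the circle: rank/n in [0, 1)."""
    theta = np.asarray(theta, dtype=float)
    order = np.argsort(theta, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(theta.size)
    return ranks / theta.size


def circular_rank_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Circular correlation of the circular ranks of two position vectors."""
    return circular_correlation(circular_rank(a), circular_rank(b))
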