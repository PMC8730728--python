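"""First-order (delta-method) and Monte-Carlo error propagation helpers."""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["central_gradient", "delta_method_se", "monte_carlo_se", "ratio_se"]


def central_gradient(
    f: Callable[[np.ndarray], float], x: Sequence[float], rel_step: float = 1e-6
) -> np.ndarray:
    """Central-difference gradient of scalar ``f`` at ``x``.

    Step is relative to each coordinate's magnitude (absolute ``rel_step``
    for coordinates at zero).
    """
    x = np.asarray(x, dtype=float)
    grad = np.empty_like(x)
    for i in range(x.size):
        h = rel_step * max(abs(x[i]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        grad[i] = (f(xp) - f(xm)) / (2 * h)
    return grad


def delta_method_se(
    f: Callable[[np.ndarray], float],
    x: Sequence[float],
    sds: Sequence[float],
    rel_step: float = 1e-6,
) -> float:
    """SE of f(x) treating inputs as independent with given SDs (first order)."""
    grad = central_gradient(f, x, rel_step)
    return float(np.sqrt(np.sum((grad * np.asarray(sds, dtype=float)) ** 2)))


def monte_carlo_se(
    f: Callable[[np.ndarray], float],
    x: Sequence[float],
    sds: Sequence[float],
    n_draws: int = 10_000,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Monte-Carlo SE of f(x) under independent Gaussian input errors.

    Seeded by default so the delta-method cross-check is reproducible.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    sds = np.asarray(sds, dtype=float)
    draws = rng.normal(loc=x, scale=sds, size=(n_draws, x.size))
    vals = np.array([f(d) for d in draws])
    return float(np.std(vals, ddof=1))


def ratio_se(a: float, se_a: float, b: float, se_b: float) -> float:
    """SE of a/b with relative errors combined in quadrature."""
    return abs(a / b) * float(np.sqrt((se_a / a) ** 2 + (se_b / b) ** 2))
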