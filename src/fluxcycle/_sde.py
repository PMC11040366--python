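"""Euler-Maruyama integration with reflecting boundaries.

Shared by the synthetic-data generator and the landscape estimator so that
"cell scatter" in synthetic samples and steady-state ensembles come from the
same stochastic integrator.
"""
from __future__ import annotations

from typing import Callable

import numpy as np

from .grids import Rect

__all__ = ["reflect_into", "em_step", "integrate_em", "deterministic_orbit"]


def reflect_into(points: np.ndarray, rect: Rect) -> np.ndarray:
    """Reflect points into `rect` (mirror at each boundary, then clip).

    A single mirror per side is exact for steps smaller than the domain size;
    the final clip guards pathological large excursions.
    """
    p = np.array(points, float)
    for axis, (lo, hi) in enumerate(((rect.x_min, rect.x_max), (rect.y_min, rect.y_max))):
        v = p[..., axis]
        v = np.where(v < lo, 2 * lo - v, v)
        v = np.where(v > hi, 2 * hi - v, v)
        p[..., axis] = np.clip(v, lo, hi)
    return p


def em_step(
    drift: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    dt: float,
    D: float,
    rng: np.ndarray | None,
    rect: Rect | None,
) -> np.ndarray:
    """One Euler-Maruyama update x += F(x) dt + sqrt(2 D dt) eta."""
    f = np.asarray(drift(x), float)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("drift returned non-finite values during integration")
    x_new = x + f * dt
    if D > 0:
        x_new = x_new + np.sqrt(2.0 * D * dt) * rng.standard_normal(x.shape)
    if rect is not None:
        x_new = reflect_into(x_new, rect)
    return x_new


def integrate_em(
    drift: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    dt: float,
    n_steps: int,
    D: float,
    rng,
    rect: Rect | None = None,
    record_every: int = 1,
) -> np.ndarray:
    """Integrate an ensemble; returns (n_traj, n_recorded, 2) including x0."""
    x = np.array(x0, float)
    if x.ndim == 1:
        x = x[None, :]
    n_rec = n_steps // record_every + 1
    out = np.empty((x.shape[0], n_rec, 2))
    out[:, 0] = x
    k = 1
    for step in range(1, n_steps + 1):
        x = em_step(drift, x, dt, D, rng, rect)
        if step % record_every == 0:
            out[:, k] = x
            k += 1
    return out[:, :k]


def deterministic_orbit(
    drift: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    dt: float,
    n_steps: int,
    rect: Rect | None = None,
) -> np.ndarray:
    """RK4 trajectory (n_steps+1, 2) of the noiseless dynamics."""
    x = np.asarray(x0, float)[None, :].copy()
    out = np.empty((n_steps + 1, 2))
    out[0] = x[0]
    for k in range(1, n_steps + 1):
        k1 = np.asarray(drift(x))
        k2 = np.asarray(drift(x + 0.5 * dt * k1))
        k3 = np.asarray(drift(x + 0.5 * dt * k2))
        k4 = np.asarray(drift(x + dt * k3))
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if rect is not None:
            x = reflect_into(x, rect)
        out[k] = x[0]
    return out
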