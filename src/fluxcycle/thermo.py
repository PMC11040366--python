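"""Nonequilibrium thermodynamics of the steady state.

With the temperature scale identified with the diffusion coefficient
(k_B = 1, k_B T -> D, matching the additive-noise convention
<zeta zeta'> = 2 D delta), the steady-state quantities are

    S   = -sum Pss ln Pss dA              (Gibbs entropy of the density)
    EPR = sum |J|^2 / (D Pss) dA          (entropy production rate)
    HDR = sum (F . J) / D dA              (heat dissipation rate)

evaluated over masked grid cells (density above the histogram floor).
At a nonequilibrium steady state EPR = HDR >= 0; for an equilibrium
(detailed-balance) system J = 0 and both vanish. The loop flux is the line
integral of J along a closed path divided by the path length -- the scalar
strength of the rotational driving along the oscillation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from ._sde import deterministic_orbit
from .grids import StateGrid
from .landscape import FluxDecomposition, LandscapeResult

__all__ = [
    "ThermoSummary",
    "LoopPath",
    "entropy",
    "epr",
    "epr_cross",
    "hdr",
    "flux_loop",
    "energy_per_period",
    "mean_limit_cycle",
    "thermo_summary",
]


@dataclass
class LoopPath:
    """Closed polyline (first point = last point) with its arc length."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 4:
            raise ValueError("loop needs at least 4 (x, y) points")
        if not np.allclose(self.points[0], self.points[-1]):
            raise ValueError("loop must be closed (first point == last point)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("loop contains non-finite points")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def reversed(self) -> "LoopPath":
        return LoopPath(self.points[::-1].copy())


@dataclass
class ThermoSummary:
    entropy_S: float
    EPR: float
    HDR: float
    flux_loop: float | None
    period_T: float | None
    energy_per_period: float | None
    D: float

    def to_dict(self) -> dict:
        return {k: (None if v is None else float(v)) for k, v in self.__dict__.items()}


def entropy(land: LandscapeResult) -> float:
    """Gibbs entropy S = -sum pss ln(pss) dA over masked cells (k_B = 1)."""
    pss = land.pss
    total = float(pss.sum() * land.grid.cell_area)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"pss integrates to {total}, expected 1")
    mask = pss > land.floor_eps
    p = pss[mask]
    return float(-(p * np.log(p)).sum() * land.grid.cell_area)


def epr(decomp: FluxDecomposition, land: LandscapeResult) -> float:
    """Entropy production rate sum |J|^2 / (D pss) dA on masked cells."""
    if decomp.D <= 0:
        raise ValueError("EPR requires D > 0")
    if decomp.grid != land.grid or not np.isclose(decomp.D, land.D):
        raise ValueError("decomposition and landscape disagree on grid or D")
    mask = decomp.mask
    j2 = (decomp.J[..., 0] ** 2 + decomp.J[..., 1] ** 2)[mask]
    p = land.pss[mask]
    return float((j2 / (decomp.D * p)).sum() * land.grid.cell_area)


def epr_cross(decomps, lands) -> float:
    """Split-ensemble entropy production rate, robust to histogram noise.

    The plain estimator sums |J|^2 and therefore inherits a positive bias
    from Monte-Carlo noise in the density gradient. With two independent
    half-ensembles the noises are uncorrelated, so the cross product
    J1 . J2 / (D pbar) is first-order unbiased: an equilibrium system's
    EPR correctly averages to ~0. Use this when comparing systems whose
    true EPR may be orders of magnitude apart.
    """
    (d1, d2), (l1, l2) = decomps, lands
    if d1.grid != d2.grid or not np.isclose(d1.D, d2.D):
        raise ValueError("half-ensembles disagree on grid or D")
    pbar = 0.5 * (l1.pss + l2.pss)
    mask = d1.mask & d2.mask
    jj = (d1.J * d2.J).sum(-1)
    return float((jj[mask] / (d1.D * pbar[mask])).sum() * l1.grid.cell_area)


def hdr(model_or_system, decomp: FluxDecomposition) -> float:
    """Heat dissipation rate sum (F . J) / D dA on masked cells."""
    grid = decomp.grid
    drift = getattr(model_or_system, "drift", model_or_system)
    F = np.asarray(drift(grid.centers_flat()), float).reshape(grid.ny, grid.nx, 2)
    fj = (F * decomp.J).sum(-1)[decomp.mask]
    return float(fj.sum() * grid.cell_area / decomp.D)


def _bilinear(grid: StateGrid, field: np.ndarray):
    return RegularGridInterpolator(
        (grid.y_centers, grid.x_centers), field,
        bounds_error=False, fill_value=0.0,
    )


def flux_loop(decomp: FluxDecomposition, loop: LoopPath, warn_outside: bool = True) -> float:
    """Line-averaged flux along a closed loop: (oint J . dl) / (oint dl).

    J is interpolated bilinearly onto segment midpoints; the sign follows the
    loop orientation (counterclockwise positive for a counterclockwise J).
    """
    L = loop.length
    if L <= 0:
        raise ValueError("degenerate loop of zero length")
    mids = 0.5 * (loop.points[:-1] + loop.points[1:])
    if warn_outside:
        mask_itp = _bilinear(decomp.grid, decomp.mask.astype(float))
        if np.any(mask_itp(mids[:, ::-1]) < 0.5):
            import warnings

            warnings.warn("loop leaves the masked (well-sampled) region", stacklevel=2)
    Jx = _bilinear(decomp.grid, np.nan_to_num(decomp.J[..., 0]))
    Jy = _bilinear(decomp.grid, np.nan_to_num(decomp.J[..., 1]))
    seg = np.diff(loop.points, axis=0)
    Jm = np.column_stack([Jx(mids[:, ::-1]), Jy(mids[:, ::-1])])
    return float((Jm * seg).sum() / L)


def energy_per_period(epr_value: float, period: float) -> float:
    """Dissipated energy over one oscillation period: EPR x T."""
    if period <= 0:
        raise ValueError("period must be positive")
    return epr_value * period


def mean_limit_cycle(
    model_or_system,
    x0=None,
    dt: float = 0.005,
    t_relax: float = 300.0,
    n_points: int = 200,
) -> LoopPath:
    """Deterministic limit-cycle orbit resampled to equal arc length.

    Integrates the noiseless dynamics until it settles on the attractor,
    extracts one period via the closest-return point, and resamples the orbit
    to ``n_points`` equally spaced (by arc length) vertices.
    """
    drift = getattr(model_or_system, "drift", model_or_system)
    domain = getattr(model_or_system, "domain", None)
    if x0 is None:
        kf = getattr(model_or_system, "known_features", {}) or {}
        if "unstable_focus" in kf:
            x0 = np.asarray(kf["unstable_focus"], float) + 0.2
        elif domain is not None:
            x0 = np.array([domain.x_min + 0.6 * domain.width,
                           domain.y_min + 0.6 * domain.height])
        else:
            x0 = np.array([1.0, 1.0])
    relax = deterministic_orbit(drift, np.asarray(x0, float),
                                dt=dt, n_steps=int(t_relax / dt), rect=domain)
    start = relax[-1]
    # follow the orbit until it returns close to the start
    orbit = deterministic_orbit(drift, start, dt=dt, n_steps=int(t_relax / dt), rect=domain)
    d = np.linalg.norm(orbit - start, axis=1)
    # ignore the initial departure, then find the first close return
    away = np.argmax(d > 0.05 * d.max()) if d.max() > 0 else 1
    ret = None
    for k in range(away + 1, len(d)):
        if d[k] < 1e-3 * max(1.0, d.max()):
            ret = k
            break
    if ret is None:
        ret = int(np.argmin(d[away:]) + away)
    cycle = orbit[: ret + 1]
    period = ret * dt
    closed = np.vstack([cycle, cycle[:1]])
    # resample by arc length
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    s_new = np.linspace(0.0, s[-1], n_points + 1)
    pts = np.column_stack([
        np.interp(s_new, s, closed[:, 0]),
        np.interp(s_new, s, closed[:, 1]),
    ])
    pts[-1] = pts[0]
    loop = LoopPath(pts)
    loop.period = period  # type: ignore[attr-defined]
    return loop


def thermo_summary(
    model_or_system,
    land: LandscapeResult,
    decomp: FluxDecomposition,
    loop: LoopPath | None = None,
    period: float | None = None,
) -> ThermoSummary:
    """Bundle S, EPR, HDR, loop flux and energy per period for one condition."""
    S = entropy(land)
    e = epr(decomp, land)
    h = hdr(model_or_system, decomp)
    fl = flux_loop(decomp, loop, warn_outside=False) if loop is not None else None
    if period is None and loop is not None:
        period = getattr(loop, "period", None)
    e_per = energy_per_period(e, period) if period else None
    return ThermoSummary(entropy_S=S, EPR=e, HDR=h, flux_loop=fl,
                         period_T=period, energy_per_period=e_per, D=land.D)
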