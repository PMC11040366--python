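"""Transition paths and passage times between attractors.

The most probable (least-action) path between two states under weak noise
minimizes the Freidlin-Wentzell-type functional

    S_T[x] = (1/2) int_0^T |dx/dt - F(x)|^2 / D dt

over both the path shape and the traversal time T. Downhill segments (where
the deterministic flow does the work) cost nothing; uphill segments against
the flow accumulate action. For a pure gradient system F = -grad V the
uphill action has the closed form 2 (V(saddle) - V(start)) / D, the oracle
used by the tests. Transition rates follow R = C exp(-S) and MFPT = 1/R; an
independent simulation-based first-passage estimator provides the empirical
cross-check.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import pearsonr, spearmanr

from ._sde import em_step
from .grids import Rect

__all__ = [
    "ActionPath",
    "RateModel",
    "BasinSpec",
    "FirstPassageResult",
    "least_action_path",
    "path_action",
    "mfpt_from_action",
    "mfpt_simulated",
    "transition_summary",
]


@dataclass
class ActionPath:
    waypoints: np.ndarray        # (p, 2)
    times: np.ndarray            # (p,)
    action_S: float
    D: float
    converged: bool
    endpoints: tuple = ("source", "target")

    @property
    def traversal_time(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class RateModel:
    """Rate R = C exp(-S) and MFPT = 1/R."""

    prefactor_C: float
    action_S: float

    def __post_init__(self) -> None:
        if self.prefactor_C <= 0:
            raise ValueError("prefactor must be positive")

    @property
    def rate_R(self) -> float:
        return self.prefactor_C * np.exp(-self.action_S)

    @property
    def mfpt(self) -> float:
        return 1.0 / self.rate_R


@dataclass
class BasinSpec:
    center: np.ndarray
    radius: float
    label: str = ""

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        if self.radius <= 0:
            raise ValueError("basin radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.norm(points - self.center, axis=-1) <= self.radius


@dataclass
class FirstPassageResult:
    mean: float | None
    sd: float | None
    n_events: int
    n_censored: int
    t_max: float
    seed: int


def path_action(waypoints: np.ndarray, T: float, drift, D: float) -> float:
    """Discretized action of a path traversed in time T with equal steps."""
    w = np.asarray(waypoints, float)
    p = len(w)
    dt = T / (p - 1)
    mid = 0.5 * (w[:-1] + w[1:])
    v = (w[1:] - w[:-1]) / dt
    F = np.asarray(drift(mid), float)
    return float(0.5 * ((v - F) ** 2).sum() / D * dt)


def _action_and_grad(x_int, source, target, T, drift, jac, D):
    p = len(x_int) // 2 + 2
    w = np.vstack([source, x_int.reshape(-1, 2), target])
    dt = T / (p - 1)
    mid = 0.5 * (w[:-1] + w[1:])
    v = (w[1:] - w[:-1]) / dt
    F = np.asarray(drift(mid), float)
    r = v - F                                  # (p-1, 2)
    S = 0.5 * (r**2).sum() / D * dt
    if jac is None:
        return S, None
    J = np.asarray(jac(mid), float)            # (p-1, 2, 2)
    # dS/dw_k = (dt/D) [ r_{k-1} (I/dt - J_{k-1}/2) + r_k (-I/dt - J_k/2) ]
    rJ = np.einsum("sa,sab->sb", r, J)
    g = np.zeros_like(w)
    g[1:] += (dt / D) * (r / dt - 0.5 * rJ)
    g[:-1] += (dt / D) * (-r / dt - 0.5 * rJ)
    return S, g[1:-1].ravel()


def least_action_path(
    model_or_system,
    source,
    target,
    D: float,
    p: int = 48,
    T_init: float | None = None,
    n_T: int = 7,
    T_span: tuple[float, float] = (0.1, 10.0),
    maxiter: int = 400,
) -> ActionPath:
    """Least-action path between two states, optimizing shape and time.

    Interior waypoints are optimized by L-BFGS (with the analytic action
    gradient when the model provides a Jacobian) from a straight-line
    initialization; an outer search over the traversal time T spans
    ``T_span`` times a characteristic flow time, and the best (lowest-action)
    restart wins.
    """
    if p < 8:
        raise ValueError("need at least 8 waypoints")
    if D <= 0:
        raise ValueError("D must be positive")
    drift = getattr(model_or_system, "drift", model_or_system)
    jac = getattr(model_or_system, "jacobian", None)
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    dist = np.linalg.norm(target - source)
    mid_speed = np.linalg.norm(drift(0.5 * (source + target)[None, :])) + 1e-9
    T_char = T_init if T_init is not None else max(dist / mid_speed, 1.0)
    T_values = np.geomspace(T_span[0] * T_char, T_span[1] * T_char, n_T)

    line = np.linspace(source, target, p)
    best = None
    for T in T_values:
        x0 = line[1:-1].ravel()
        res = minimize(
            _action_and_grad, x0,
            args=(source, target, T, drift, jac, D),
            jac=True if jac is not None else None,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x, T, res.success)
    S, x_int, T, success = best
    w = np.vstack([source, x_int.reshape(-1, 2), target])
    return ActionPath(
        waypoints=w,
        times=np.linspace(0.0, T, p),
        action_S=float(max(S, 0.0)),
        D=D,
        converged=bool(success),
    )


def mfpt_from_action(action_S: float, prefactor_C: float = 1.0) -> RateModel:
    """Kramers-type rate model from a path action."""
    return RateModel(prefactor_C=prefactor_C, action_S=action_S)


def mfpt_simulated(
    model_or_system,
    D: float,
    source: BasinSpec,
    target: BasinSpec,
    n: int = 200,
    t_max: float = 2000.0,
    dt: float = 0.01,
    seed: int = 0,
    domain: Rect | None = None,
) -> FirstPassageResult:
    """Empirical mean first-passage time from Langevin simulation.

    ``n`` trajectories start at the source center; the first entry time into
    the target disk is recorded, and runs that never arrive by ``t_max`` are
    counted as censored.
    """
    if np.linalg.norm(source.center - target.center) <= source.radius + target.radius:
        raise ValueError("source and target basins must be disjoint")
    drift = getattr(model_or_system, "drift", model_or_system)
    domain = domain or getattr(model_or_system, "domain", None)
    rng = np.random.default_rng(seed)
    x = np.repeat(source.center[None, :], n, axis=0)
    alive = np.ones(n, bool)
    hit_time = np.full(n, np.nan)
    n_steps = int(round(t_max / dt))
    for step in range(1, n_steps + 1):
        x[alive] = em_step(drift, x[alive], dt, D, rng, domain)
        arrived = np.zeros(n, bool)
        arrived[alive] = target.contains(x[alive])
        if arrived.any():
            hit_time[arrived] = step * dt
            alive &= ~arrived
        if not alive.any():
            break
    events = hit_time[~np.isnan(hit_time)]
    n_events = len(events)
    return FirstPassageResult(
        mean=float(events.mean()) if n_events else None,
        sd=float(events.std(ddof=1)) if n_events > 1 else None,
        n_events=n_events,
        n_censored=int(n - n_events),
        t_max=t_max,
        seed=seed,
    )


def transition_summary(rows: list[dict]) -> dict:
    """Rank/linear correlations among per-condition transition quantities.

    ``rows`` is a list of dicts with keys among {'D', 'action', 'ln_mfpt',
    'barrier', 'flux', 'epr'}; returns the table plus Pearson and Spearman
    correlations of ln MFPT with barrier, ln|flux| and ln EPR.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 conditions to correlate")
    get = lambda k: np.array([r[k] for r in rows], float)
    ln_mfpt = get("ln_mfpt")
    out = {"rows": rows, "correlations": {}}
    pairs = {
        "barrier": get("barrier") if "barrier" in rows[0] else None,
        "ln_flux": np.log(np.abs(get("flux"))) if "flux" in rows[0] else None,
        "ln_epr": np.log(get("epr")) if "epr" in rows[0] else None,
        "action": get("action") if "action" in rows[0] else None,
    }
    for name, v in pairs.items():
        if v is None:
            continue
        out["correlations"][f"ln_mfpt_vs_{name}"] = {
            "pearson": float(pearsonr(ln_mfpt, v)[0]),
            "spearman": float(spearmanr(ln_mfpt, v)[0]),
        }
    return out
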