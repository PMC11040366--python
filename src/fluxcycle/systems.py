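"""Ground-truth dynamical systems and synthetic velocity samples.

These systems emulate the kind of data the pipeline consumes in practice: a
2-D embedding of cell states together with per-cell velocity vectors (the
reduced-space representation of RNA velocity). Each system exposes an
analytic drift F(x) and its Jacobian so that every downstream stage can be
tested against a known ground truth.

The flagship system is a two-gene Hill-kinetics relaxation oscillator in
which gene x (a G2-M-like regulator) self-activates and activates gene y (a
G1-S-like regulator), while y represses x's basal production:

    dx/dt = A1 x^n1/(K1 + x^n1) + A2 K2/(K2 + y^n2) - g1 x
    dy/dt = A3 y^n3/(K3 + y^n3) + A4 x^n4/(K4 + x^n4) - g2 y

The coupled positive (self-activation) and negative (x -> y -| x) feedback
loops produce a stable limit cycle mimicking cell-cycle progression.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Literal

import numpy as np

from ._sde import deterministic_orbit, integrate_em
from .grids import Rect

__all__ = [
    "HillOscillatorParams",
    "SyntheticSystem",
    "VelocitySampleSet",
    "make_hill_oscillator",
    "make_double_well",
    "make_hopf_rotator",
    "make_linear",
    "default_hill_oscillator",
    "arrest_hill_oscillator",
    "sample_velocities",
    "DEFAULT_HILL_PARAMS",
    "ARREST_HILL_PARAMS",
]

SystemKind = Literal["hill_oscillator", "double_well", "hopf_rotator", "linear"]

#: Diffusion used when scattering sample positions along trajectories, so the
#: synthetic "cells" spread around the attractor the way real cells scatter
#: around the mean cycle.
TRAJECTORY_SAMPLING_D = 0.01


@dataclass(frozen=True)
class HillOscillatorParams:
    """Kinetic parameters of the two-gene Hill oscillator.

    Amplitudes ``A_i`` are production rates (concentration/time), thresholds
    ``K_i`` carry units of concentration**n_i, Hill coefficients ``n_i`` are
    dimensionless (>= 1), and ``g1``/``g2`` are first-order degradation rates.
    """

    A1: float
    K1: float
    n1: float
    A2: float
    K2: float
    n2: float
    A3: float
    K3: float
    n3: float
    A4: float
    K4: float
    n4: float
    g1: float
    g2: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name} must be strictly positive, got {value!r}")
        for name in ("n1", "n2", "n3", "n4"):
            if getattr(self, name) < 1:
                raise ValueError(f"Hill coefficient {name} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HillOscillatorParams":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "HillOscillatorParams":
        return cls.from_dict(json.loads(s))


#: Default oscillator: a relaxation limit cycle (period ~24.6 in natural time
#: units) verified by the Poincare-return oracle in the test suite. The values
#: are package configuration chosen for a robust cycle with O(1) concentrations.
DEFAULT_HILL_PARAMS = HillOscillatorParams(
    A1=1.6, K1=1.0, n1=4, A2=0.8, K2=1.0, n2=4,
    A3=0.2, K3=4.0, n3=4, A4=0.6, K4=3.0, n4=4,
    g1=1.0, g2=0.15,
)

#: Variant with a strong, high-threshold self-activation of y: the limit cycle
#: coexists with a quiescent arrest state (stable node near (0, 5.5), saddle
#: near (0, 3.0)) -- the "G0 basin next to the cycle" topology.
ARREST_HILL_PARAMS = HillOscillatorParams(
    A1=1.6, K1=1.0, n1=4, A2=0.8, K2=1.0, n2=4,
    A3=0.9, K3=81.0, n3=4, A4=0.6, K4=3.0, n4=4,
    g1=1.0, g2=0.15,
)


@dataclass
class SyntheticSystem:
    """A 2-D dynamical system with analytic drift and Jacobian.

    ``drift`` maps (n, 2) states to (n, 2) velocities; ``jacobian`` maps
    (n, 2) states to (n, 2, 2) matrices J[i, a, b] = dF_a/dx_b.
    """

    kind: SystemKind
    drift: Callable[[np.ndarray], np.ndarray]
    jacobian: Callable[[np.ndarray], np.ndarray]
    domain: Rect
    params: dict | HillOscillatorParams = field(default_factory=dict)
    known_features: dict = field(default_factory=dict)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.drift(np.atleast_2d(np.asarray(points, float)))


def _hill_act(u: np.ndarray, A: float, K: float, n: float) -> np.ndarray:
    un = u**n
    return A * un / (K + un)


def _hill_act_deriv(u: np.ndarray, A: float, K: float, n: float) -> np.ndarray:
    un = u**n
    with np.errstate(divide="ignore", invalid="ignore"):
        d = A * K * n * u ** (n - 1) / (K + un) ** 2
    return np.where(u > 0, d, 0.0 if n > 1 else A * n / K)


def make_hill_oscillator(
    params: HillOscillatorParams = DEFAULT_HILL_PARAMS,
    domain: Rect | None = None,
) -> SyntheticSystem:
    """Build the two-gene Hill oscillator.

    Concentrations are clamped at zero before evaluating the Hill terms, so
    the drift stays finite (and pushes inward) for slightly negative states
    that can occur transiently under noise before boundary reflection.
    """
    p = params

    def drift(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        x = np.maximum(pts[..., 0], 0.0)
        y = np.maximum(pts[..., 1], 0.0)
        fx = _hill_act(x, p.A1, p.K1, p.n1) + p.A2 * p.K2 / (p.K2 + y**p.n2) - p.g1 * pts[..., 0]
        fy = _hill_act(y, p.A3, p.K3, p.n3) + _hill_act(x, p.A4, p.K4, p.n4) - p.g2 * pts[..., 1]
        return np.stack([fx, fy], axis=-1)

    def jacobian(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        x = np.maximum(pts[..., 0], 0.0)
        y = np.maximum(pts[..., 1], 0.0)
        J = np.empty(pts.shape[:-1] + (2, 2))
        J[..., 0, 0] = _hill_act_deriv(x, p.A1, p.K1, p.n1) - p.g1
        J[..., 0, 1] = -_hill_act_deriv(y, p.A2, p.K2, p.n2)
        J[..., 1, 0] = _hill_act_deriv(x, p.A4, p.K4, p.n4)
        J[..., 1, 1] = _hill_act_deriv(y, p.A3, p.K3, p.n3) - p.g2
        return J

    if domain is None:
        domain = _attractor_domain(drift, starts=[(0.2, 0.2), (1.5, 0.5), (0.5, 3.0)])
        # concentrations are nonnegative
        domain = Rect(max(domain.x_min, 0.0), domain.x_max, max(domain.y_min, 0.0), domain.y_max)
    return SyntheticSystem(
        kind="hill_oscillator", drift=drift, jacobian=jacobian,
        domain=domain, params=p,
    )


def default_hill_oscillator() -> SyntheticSystem:
    """The shipped default oscillator with its verified features attached."""
    sys_ = make_hill_oscillator(DEFAULT_HILL_PARAMS)
    sys_.known_features = {
        "period": 24.6,
        "unstable_focus": (0.910, 1.202),
        "cycle_bbox": (0.08, 1.63, 0.73, 2.39),
    }
    return sys_


def arrest_hill_oscillator() -> SyntheticSystem:
    """Oscillator coexisting with a quiescent (G0-like) arrest basin."""
    sys_ = make_hill_oscillator(ARREST_HILL_PARAMS)
    sys_.known_features = {
        "period": 26.6,
        "unstable_focus": (1.039, 1.368),
        "arrest_point": (0.001, 5.518),
        "saddle": (0.010, 3.000),
    }
    return sys_


def make_double_well(barrier: float, well_separation: float) -> SyntheticSystem:
    """Gradient system F = -grad V, V = barrier ((x/a)^2 - 1)^2 + y^2, a = sep/2.

    An equilibrium (detailed-balance) oracle: minima at (+-a, 0), saddle at
    the origin with depth `barrier`.
    """
    if not (barrier > 0 and well_separation > 0):
        raise ValueError("barrier and well_separation must be positive")
    a = well_separation / 2.0

    def potential(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        return barrier * ((pts[..., 0] / a) ** 2 - 1) ** 2 + pts[..., 1] ** 2

    def drift(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        x, y = pts[..., 0], pts[..., 1]
        fx = -4 * barrier * x * ((x / a) ** 2 - 1) / a**2
        fy = -2 * y
        return np.stack([fx, fy], axis=-1)

    def jacobian(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        x = pts[..., 0]
        J = np.zeros(pts.shape[:-1] + (2, 2))
        J[..., 0, 0] = -4 * barrier * (3 * x**2 / a**2 - 1) / a**2
        J[..., 1, 1] = -2.0
        return J

    domain = Rect(-1.6 * a, 1.6 * a, -0.8 * a, 0.8 * a)
    return SyntheticSystem(
        kind="double_well", drift=drift, jacobian=jacobian, domain=domain,
        params={"barrier": barrier, "well_separation": well_separation, "a": a},
        known_features={
            "minima": [(-a, 0.0), (a, 0.0)],
            "saddle": (0.0, 0.0),
            "delta_V": barrier,
            "potential": potential,
        },
    )


def make_hopf_rotator(omega: float, radius: float, relaxation: float) -> SyntheticSystem:
    """Rotationally symmetric limit cycle: dr/dt = relaxation r (radius^2 - r^2),
    dtheta/dt = omega. Period and orbit are known in closed form."""
    if omega == 0:
        raise ValueError("omega must be nonzero")
    if not (radius > 0 and relaxation > 0):
        raise ValueError("radius and relaxation must be positive")
    lam, R = relaxation, radius

    def drift(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        x, y = pts[..., 0], pts[..., 1]
        r2 = x**2 + y**2
        g = lam * (R**2 - r2)
        return np.stack([g * x - omega * y, g * y + omega * x], axis=-1)

    def jacobian(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        x, y = pts[..., 0], pts[..., 1]
        r2 = x**2 + y**2
        g = lam * (R**2 - r2)
        J = np.empty(pts.shape[:-1] + (2, 2))
        J[..., 0, 0] = g - 2 * lam * x**2
        J[..., 0, 1] = -omega - 2 * lam * x * y
        J[..., 1, 0] = omega - 2 * lam * x * y
        J[..., 1, 1] = g - 2 * lam * y**2
        return J

    m = 1.4 * R
    return SyntheticSystem(
        kind="hopf_rotator", drift=drift, jacobian=jacobian,
        domain=Rect(-m, m, -m, m),
        params={"omega": omega, "radius": radius, "relaxation": relaxation},
        known_features={"period": 2 * np.pi / abs(omega), "orbit_radius": R},
    )


def make_linear(A: np.ndarray, domain: Rect | None = None) -> SyntheticSystem:
    """Linear field F(x) = A x (constant Jacobian A)."""
    A = np.asarray(A, float).reshape(2, 2)

    def drift(pts: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(pts, float)) @ A.T

    def jacobian(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        return np.broadcast_to(A, pts.shape[:-1] + (2, 2)).copy()

    return SyntheticSystem(
        kind="linear", drift=drift, jacobian=jacobian,
        domain=domain or Rect(-2, 2, -2, 2),
        params={"A": A.tolist()},
        known_features={"fixed_points": [(0.0, 0.0)]},
    )


def _attractor_domain(drift, starts, margin: float = 0.2) -> Rect:
    """Bounding rectangle of the attractor(s), with a fractional margin."""
    pts = []
    for x0 in starts:
        orbit = deterministic_orbit(drift, np.asarray(x0, float), dt=0.02, n_steps=15000)
        pts.append(orbit[len(orbit) // 3:])
    pts = np.concatenate(pts)
    rect = Rect(pts[:, 0].min() - 1e-6, pts[:, 0].max() + 1e-6,
                pts[:, 1].min() - 1e-6, pts[:, 1].max() + 1e-6)
    return rect.expand(margin)


@dataclass
class VelocitySampleSet:
    """Sparse per-cell (position, velocity) samples in embedding space."""

    positions: np.ndarray
    velocities: np.ndarray
    noise_sd: float = 0.0
    seed: int | None = None
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.velocities = np.asarray(self.velocities, float)
        if self.positions.shape != self.velocities.shape or self.positions.ndim != 2:
            raise ValueError("positions and velocities must both be (n, 2)")
        if self.positions.shape[1] != 2:
            raise ValueError("samples live in a 2-D embedding")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.velocities))):
            raise ValueError("samples contain non-finite values")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def bounding_rect(self, margin: float = 0.1) -> Rect:
        p = self.positions
        return Rect(p[:, 0].min(), p[:, 0].max() + 1e-12,
                    p[:, 1].min(), p[:, 1].max() + 1e-12).expand(margin)


def sample_velocities(
    system: SyntheticSystem,
    n: int,
    sampling: str = "trajectory",
    noise_sd: float = 0.05,
    seed: int = 0,
    burn_in: float = 50.0,
    dt: float = 0.01,
) -> VelocitySampleSet:
    """Draw n noisy velocity measurements from a ground-truth system.

    ``trajectory`` sampling scatters positions along stochastic trajectories
    (small diffusion, burn-in discarded) so they concentrate near the
    attractor like real cells; ``uniform`` covers the declared domain.
    Velocities are drift(position) plus iid Gaussian noise per component.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if sampling == "uniform":
        d = system.domain
        pos = np.column_stack([
            rng.uniform(d.x_min, d.x_max, n),
            rng.uniform(d.y_min, d.y_max, n),
        ])
    elif sampling == "trajectory":
        d = system.domain
        n_traj = min(max(n // 50, 1), 50)
        x0 = np.column_stack([
            rng.uniform(d.x_min, d.x_max, n_traj),
            rng.uniform(d.y_min, d.y_max, n_traj),
        ])
        burn_steps = int(round(burn_in / dt))
        n_keep = int(np.ceil(n / n_traj))
        states = integrate_em(
            system.drift, x0, dt=dt, n_steps=burn_steps + n_keep * 10,
            D=TRAJECTORY_SAMPLING_D, rng=rng, rect=d,
        )
        pool = states[:, burn_steps:].reshape(-1, 2)
        idx = rng.choice(pool.shape[0], size=n, replace=False)
        pos = pool[idx]
    else:
        raise ValueError(f"unknown sampling mode {sampling!r}")
    vel = system.drift(pos)
    if noise_sd > 0:
        vel = vel + rng.normal(0.0, noise_sd, size=vel.shape)
    return VelocitySampleSet(pos, vel, noise_sd=noise_sd, seed=seed, source=system.kind)
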