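"""Steady-state landscape U = -ln Pss and flux decomposition.

The stochastic cell-state dynamics dx/dt = F(x) + zeta, with white noise of
covariance <zeta zeta'> = 2 D delta, is simulated by Euler-Maruyama from many
random initial conditions. The long-run state histogram on a grid estimates
the steady-state probability Pss, the generalized potential is U = -ln Pss,
and the probability flux J = F Pss - D grad Pss splits the driving force into
a gradient part -D grad U and a rotational (curl-flux) part Jss/Pss:

    F = -D grad U + Jss/Pss

For equilibrium (gradient) systems Jss = 0 and the landscape alone governs
the dynamics; a nonzero rotational component is the signature of a
nonequilibrium steady state such as the cell cycle.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._sde import em_step, integrate_em
from .grids import Rect, StateGrid
from .vector_field import FixedPoint

__all__ = [
    "SDEConfig",
    "EnsembleTrajectories",
    "LandscapeResult",
    "FluxDecomposition",
    "BarrierReport",
    "simulate_langevin",
    "estimate_pss",
    "steady_state_landscape",
    "steady_state_landscape_multi",
    "compute_flux",
    "barrier_heights",
    "ring_break_level",
    "ring_coverage",
]


@dataclass
class SDEConfig:
    """Settings for the Langevin ensemble simulation.

    ``D`` is the diffusion coefficient (embedding units^2 / time); times are
    in the natural time unit of the drift. ``record_every`` thins the stored
    trajectory (the integration step is always ``dt``).
    """

    D: float
    dt: float = 0.01
    t_total: float = 500.0
    burn_in: float = 50.0
    n_traj: int = 500
    seed: int = 0
    init: Literal["uniform_random", "fixed_point_vicinity", "supplied"] = "uniform_random"
    init_states: np.ndarray | None = None
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.burn_in < self.t_total:
            raise ValueError("burn_in must be smaller than t_total")
        if self.n_traj < 1:
            raise ValueError("need at least one trajectory")
        if self.init == "supplied" and self.init_states is None:
            raise ValueError("init='supplied' requires init_states")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))

    @property
    def burn_in_steps(self) -> int:
        return int(round(self.burn_in / self.dt))


@dataclass
class EnsembleTrajectories:
    """Recorded ensemble states, shape (n_traj, n_recorded, 2)."""

    states: np.ndarray
    dt: float                      # time between recorded frames
    D: float
    seed: int
    burn_in_steps: int             # in recorded frames

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.states.shape[1]) * self.dt

    def post_burn_in(self) -> np.ndarray:
        return self.states[:, self.burn_in_steps:]


def _initial_states(drift, cfg: SDEConfig, domain: Rect, rng) -> np.ndarray:
    if cfg.init == "supplied":
        x0 = np.atleast_2d(np.asarray(cfg.init_states, float))
        if x0.shape[0] == 1:
            x0 = np.repeat(x0, cfg.n_traj, axis=0)
        return x0
    if cfg.init == "uniform_random":
        return np.column_stack([
            rng.uniform(domain.x_min, domain.x_max, cfg.n_traj),
            rng.uniform(domain.y_min, domain.y_max, cfg.n_traj),
        ])
    if cfg.init == "fixed_point_vicinity":
        center = np.array([(domain.x_min + domain.x_max) / 2,
                           (domain.y_min + domain.y_max) / 2])
        scale = 0.02 * max(domain.width, domain.height)
        return center + scale * rng.standard_normal((cfg.n_traj, 2))
    raise ValueError(f"unknown init mode {cfg.init!r}")


def simulate_langevin(model_or_system, cfg: SDEConfig, domain: Rect | None = None) -> EnsembleTrajectories:
    """Euler-Maruyama ensemble with reflecting domain boundaries."""
    drift = getattr(model_or_system, "drift", model_or_system)
    domain = domain or getattr(model_or_system, "domain", None)
    rng = np.random.default_rng(cfg.seed)
    x0 = _initial_states(drift, cfg, domain, rng)
    states = integrate_em(
        drift, x0, dt=cfg.dt, n_steps=cfg.n_steps, D=cfg.D, rng=rng,
        rect=domain, record_every=cfg.record_every,
    )
    return EnsembleTrajectories(
        states=states,
        dt=cfg.dt * cfg.record_every,
        D=cfg.D,
        seed=cfg.seed,
        burn_in_steps=cfg.burn_in_steps // cfg.record_every,
    )


@dataclass
class LandscapeResult:
    """Gridded steady-state probability density and potential U = -ln Pss.

    ``pss`` integrates to 1 over the grid (sum pss * cell_area = 1); ``U`` is
    -ln of the floored density, shifted so that min U = 0 when
    ``shift_min_to_zero`` is set (the default).
    """

    grid: StateGrid
    pss: np.ndarray
    U: np.ndarray
    D: float
    floor_eps: float
    n_samples: int
    shift_min_to_zero: bool = True


def _finalize_landscape(counts, grid, D, floor_eps, n_samples, shift) -> LandscapeResult:
    if n_samples == 0:
        raise ValueError("no samples fell inside the grid")
    pss = counts / (n_samples * grid.cell_area)
    if floor_eps is None:
        floor_eps = 0.1 / (n_samples * grid.cell_area)
    U = -np.log(np.maximum(pss, floor_eps))
    if shift:
        U = U - U.min()
    return LandscapeResult(grid=grid, pss=pss, U=U, D=D,
                           floor_eps=floor_eps, n_samples=n_samples,
                           shift_min_to_zero=shift)


def estimate_pss(
    traj: EnsembleTrajectories,
    grid: StateGrid,
    floor_eps: float | None = None,
    shift_min_to_zero: bool = True,
) -> LandscapeResult:
    """Histogram the post-burn-in ensemble into a normalized density."""
    pts = traj.post_burn_in().reshape(-1, 2)
    counts, _, _ = np.histogram2d(
        pts[:, 1], pts[:, 0], bins=[grid.y_edges, grid.x_edges]
    )
    n_in = int(counts.sum())
    if n_in == 0:
        raise ValueError("all samples fell outside the grid")
    return _finalize_landscape(counts, grid, traj.D, floor_eps, n_in, shift_min_to_zero)


def steady_state_landscape(
    model_or_system,
    cfg: SDEConfig,
    grid: StateGrid | None = None,
    nx: int = 100,
    floor_eps: float | None = None,
) -> LandscapeResult:
    """Simulate and histogram in one streaming pass (memory-light).

    Equivalent to ``estimate_pss(simulate_langevin(...), grid)`` but the
    ensemble states are binned chunk-by-chunk instead of being stored, which
    allows the long runs needed for well-resolved landscapes.
    """
    if grid is None:
        domain = getattr(model_or_system, "domain")
        grid = StateGrid.from_rect(domain, nx)
    return steady_state_landscape_multi(model_or_system, cfg, [grid],
                                        floor_eps=floor_eps)[0]


def steady_state_landscape_multi(
    model_or_system,
    cfg: SDEConfig,
    grids: list[StateGrid],
    floor_eps: float | None = None,
) -> list[LandscapeResult]:
    """One simulation pass histogrammed onto several grids at once."""
    drift = getattr(model_or_system, "drift", model_or_system)
    domain = getattr(model_or_system, "domain")
    rng = np.random.default_rng(cfg.seed)
    x = _initial_states(drift, cfg, domain, rng)
    counts = [np.zeros((g.ny, g.nx)) for g in grids]
    n_samples = [0] * len(grids)
    burn = cfg.burn_in_steps
    chunk: list[np.ndarray] = []

    def flush():
        nonlocal chunk
        pts = np.concatenate(chunk).reshape(-1, 2)
        for i, g in enumerate(grids):
            c, _, _ = np.histogram2d(pts[:, 1], pts[:, 0],
                                     bins=[g.y_edges, g.x_edges])
            counts[i] += c
            n_samples[i] += int(c.sum())
        chunk = []

    for step in range(1, cfg.n_steps + 1):
        x = em_step(drift, x, cfg.dt, cfg.D, rng, domain)
        if step > burn and step % cfg.record_every == 0:
            chunk.append(x.copy())
            if len(chunk) >= 256:
                flush()
    if chunk:
        flush()
    return [
        _finalize_landscape(counts[i], grids[i], cfg.D, floor_eps, n_samples[i], True)
        for i in range(len(grids))
    ]


@dataclass
class FluxDecomposition:
    """Gridded probability flux and force decomposition.

    On masked cells (density above the floor), ``residual`` is the
    discretization error of F = -D grad U + J/Pss; outside the mask the
    decomposition fields are NaN.
    """

    grid: StateGrid
    J: np.ndarray                # (ny, nx, 2)
    grad_force: np.ndarray       # -D grad U
    curl_component: np.ndarray   # J / pss
    residual: np.ndarray         # scalar field
    div_J: np.ndarray
    mask: np.ndarray
    D: float


def _grad(field: np.ndarray, grid: StateGrid) -> np.ndarray:
    """Central differences (one-sided at edges); returns (ny, nx, 2) = (d/dx, d/dy)."""
    gy, gx = np.gradient(field, grid.dy, grid.dx)
    return np.stack([gx, gy], axis=-1)


def compute_flux(model_or_system, land: LandscapeResult, D: float | None = None) -> FluxDecomposition:
    """Probability flux J = F Pss - D grad Pss and its decomposition."""
    if D is not None and not np.isclose(D, land.D):
        raise ValueError(f"landscape was estimated at D={land.D}, got D={D}")
    D = land.D
    grid = land.grid
    drift = getattr(model_or_system, "drift", model_or_system)
    F = np.asarray(drift(grid.centers_flat()), float).reshape(grid.ny, grid.nx, 2)
    pss = land.pss
    grad_p = _grad(pss, grid)
    J = F * pss[..., None] - D * grad_p
    U = -np.log(np.maximum(pss, land.floor_eps))
    grad_force = -D * _grad(U, grid)
    mask = pss > land.floor_eps
    with np.errstate(divide="ignore", invalid="ignore"):
        curl_component = J / pss[..., None]
    curl_component[~mask] = np.nan
    recon = grad_force + curl_component
    residual = np.linalg.norm(F - recon, axis=-1)
    residual[~mask] = np.nan
    dJx = np.gradient(J[..., 0], grid.dx, axis=1)
    dJy = np.gradient(J[..., 1], grid.dy, axis=0)
    return FluxDecomposition(
        grid=grid, J=J, grad_force=grad_force, curl_component=curl_component,
        residual=residual, div_J=dJx + dJy, mask=mask, D=D,
    )


@dataclass
class BarrierReport:
    """Barrier heights read off the potential landscape.

    ``barrier_to_saddle`` maps a basin label to U(saddle) - U(basin minimum)
    for the lowest (minimax) path connecting it to the other basin;
    ``barrier_center`` is the height of the hump inside the ring valley above
    the landscape minimum (the oscillation-center barrier).
    """

    basin_minima: list  # (label, location, U)
    saddle: tuple | None
    barrier_to_saddle: dict
    barrier_center: float | None
    labels: dict = field(default_factory=dict)


def _descend(U: np.ndarray, iy: int, ix: int) -> tuple[int, int]:
    """Greedy 8-neighbour descent from a cell to its local minimum."""
    ny, nx = U.shape
    while True:
        best = U[iy, ix]
        b = (iy, ix)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                jy, jx = iy + dy, ix + dx
                if 0 <= jy < ny and 0 <= jx < nx and U[jy, jx] < best:
                    best = U[jy, jx]
                    b = (jy, jx)
        if b == (iy, ix):
            return b
        iy, ix = b


def _minimax_level(U: np.ndarray, a: tuple[int, int], b: tuple[int, int]):
    """Lowest level at which cells a and b join in the sublevel-set filtration
    of U (8-connected); this is the saddle height of the bottleneck path.
    Returns (level, cell) of the connecting threshold."""
    ny, nx = U.shape
    order = np.argsort(U, axis=None, kind="stable")
    parent = np.full(ny * nx, -1, dtype=np.int64)

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    ia = a[0] * nx + a[1]
    ib = b[0] * nx + b[1]
    active = np.zeros(ny * nx, bool)
    for flat in order:
        parent[flat] = flat
        active[flat] = True
        iy, ix = divmod(int(flat), nx)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                jy, jx = iy + dy, ix + dx
                if 0 <= jy < ny and 0 <= jx < nx:
                    j = jy * nx + jx
                    if active[j]:
                        ra, rb = find(flat), find(j)
                        if ra != rb:
                            parent[ra] = rb
        if active[ia] and active[ib] and find(ia) == find(ib):
            return float(U[iy, ix]), (iy, ix)
    return None, None


def _cell_of(grid: StateGrid, point) -> tuple[int, int]:
    ix = int(np.clip((point[0] - grid.x_min) / grid.dx, 0, grid.nx - 1))
    iy = int(np.clip((point[1] - grid.y_min) / grid.dy, 0, grid.ny - 1))
    return iy, ix


def barrier_heights(
    land: LandscapeResult,
    fixed_points: list[FixedPoint],
    labels: dict | None = None,
) -> BarrierReport:
    """Basin minima, connecting saddle, and the oscillation-center barrier.

    Stable fixed points seed the basins (each is slid downhill to its local
    minimum of U); the saddle between two basins is found by minimax
    (bottleneck) search on the 8-connected grid graph. The ring-valley basin
    is seeded at the global minimum of U when an interior unstable focus
    signals a limit cycle.
    """
    U = land.U
    grid = land.grid
    labels = labels or {}
    stable = [fp for fp in fixed_points if fp.is_stable]
    unstable_focus = [fp for fp in fixed_points if fp.kind == "unstable_focus"]

    seeds: list[tuple[str, tuple[int, int]]] = []
    for i, fp in enumerate(stable):
        lab = labels.get(i, f"basin_{i}")
        seeds.append((lab, _descend(U, *_cell_of(grid, fp.location))))
    barrier_center = None
    if unstable_focus:
        # ring-valley seed: slide downhill from the central hump into the
        # surrounding valley (robust even when a coexisting basin holds the
        # global minimum of U)
        center = unstable_focus[0].location
        cy, cx = _cell_of(grid, center)
        ring_seed = _descend(U, cy, cx)
        if all(c != ring_seed for _, c in seeds):
            seeds.append(("cycle", ring_seed))
        # hump height: local max of U in a small disk around the focus
        r_cells = max(2, int(0.1 * min(grid.nx, grid.ny)))
        y0, y1 = max(0, cy - r_cells), min(grid.ny, cy + r_cells + 1)
        x0, x1 = max(0, cx - r_cells), min(grid.nx, cx + r_cells + 1)
        barrier_center = float(np.max(U[y0:y1, x0:x1]) - U.min())

    basin_minima = []
    for lab, (iy, ix) in seeds:
        loc = (float(grid.x_centers[ix]), float(grid.y_centers[iy]))
        basin_minima.append((lab, loc, float(U[iy, ix])))

    saddle = None
    barrier_to_saddle: dict = {}
    if len(seeds) >= 2:
        (lab_a, ca), (lab_b, cb) = seeds[0], seeds[1]
        level, cell = _minimax_level(U, ca, cb)
        if level is not None:
            loc = (float(grid.x_centers[cell[1]]), float(grid.y_centers[cell[0]]))
            saddle = (loc, level)
            barrier_to_saddle[lab_a] = float(level - U[ca])
            barrier_to_saddle[lab_b] = float(level - U[cb])
    return BarrierReport(
        basin_minima=basin_minima, saddle=saddle,
        barrier_to_saddle=barrier_to_saddle,
        barrier_center=barrier_center, labels=labels,
    )


def ring_break_level(land: LandscapeResult, center) -> float:
    """Lowest potential level (above min U) at which a closed valley loop
    encircles ``center``.

    Computed as the maximin (bottleneck) path value from the center cell to
    the domain boundary: a closed loop of cells with U <= level exists around
    the center exactly when every path from the center to the boundary dips
    to or below that level. A ring valley is intact when this break level
    lies well below the central hump (cells can circulate without climbing);
    when it approaches the hump height the valley has fragmented into
    discrete basins separated by comparable barriers.
    """
    U = land.U
    grid = land.grid
    ny, nx = U.shape
    cy, cx = _cell_of(grid, center)
    order = np.argsort(U, axis=None, kind="stable")[::-1]   # descending U
    parent = np.full(ny * nx + 1, -1, dtype=np.int64)       # extra boundary node
    BND = ny * nx
    parent[BND] = BND

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    ic = cy * nx + cx
    for flat in order:
        flat = int(flat)
        parent[flat] = flat
        iy, ix = divmod(flat, nx)
        if iy in (0, ny - 1) or ix in (0, nx - 1):
            parent[find(flat)] = BND
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                jy, jx = iy + dy, ix + dx
                if 0 <= jy < ny and 0 <= jx < nx:
                    j = jy * nx + jx
                    if parent[j] != -1:
                        ra, rb = find(flat), find(j)
                        if ra != rb:
                            parent[ra] = rb
        if parent[ic] != -1 and find(ic) == find(BND):
            return float(U[iy, ix] - U.min())
    return 0.0


def ring_coverage(
    land: LandscapeResult,
    center,
    u_band: float = 1.5,
    n_sectors: int = 72,
    r_min_frac: float = 0.15,
) -> float:
    """Angular coverage of the ring valley around ``center``.

    Fraction of angular sectors containing at least one cell with
    U <= min(U) + u_band at radius beyond ``r_min_frac`` of the domain
    half-size. Coverage 1.0 means an intact closed valley; values below 1
    flag a fragmented (broken) ring.
    """
    grid = land.grid
    xx, yy = grid.meshgrid()
    dx = xx - center[0]
    dy = yy - center[1]
    r = np.hypot(dx, dy)
    r_min = r_min_frac * 0.5 * min(grid.rect.width, grid.rect.height)
    low = (land.U <= land.U.min() + u_band) & (r > r_min)
    if not low.any():
        return 0.0
    ang = np.arctan2(dy[low], dx[low])
    sectors = np.unique(((ang + np.pi) / (2 * np.pi) * n_sectors).astype(int) % n_sectors)
    return len(sectors) / n_sectors
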