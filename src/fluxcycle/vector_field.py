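"""Continuous vector-field reconstruction from sparse velocity samples.

A smooth drift F(x) is learned from per-cell (position, velocity) pairs by
Gaussian kernel ridge regression with a constant offset:

    F(x) = b + sum_j w_j exp(-|x - c_j|^2 / (2 h^2))

with basis centers c_j placed by k-means on the sample positions. The
expansion is differentiable in closed form, which gives an analytic Jacobian
everywhere -- the object that downstream perturbation and gene-regulatory
analyses rely on. This is a deliberately transparent smoother standing in the
same role as sparse vector-field learners used on real RNA-velocity data.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field


import numpy as np
from sklearn.cluster import KMeans

from .grids import Rect, StateGrid

__all__ = [
    "VectorFieldModel",
    "GeometryFields",
    "FixedPoint",
    "fit_vector_field",
    "differential_geometry",
    "find_fixed_points",
]


@dataclass
class VectorFieldModel:
    """Gaussian kernel expansion of a 2-D vector field."""

    centers: np.ndarray          # (m, 2)
    coefficients: np.ndarray     # (m, 2)
    bandwidth: float
    ridge: float
    domain: Rect
    bias: np.ndarray = field(default_factory=lambda: np.zeros(2))
    heldout_rmse: float | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, float)
        self.coefficients = np.asarray(self.coefficients, float)
        self.bias = np.asarray(self.bias, float)
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    # -- evaluation ---------------------------------------------------------
    def _kernel(self, points: np.ndarray) -> np.ndarray:
        d2 = ((points[:, None, :] - self.centers[None, :, :]) ** 2).sum(-1)
        return np.exp(-0.5 * d2 / self.bandwidth**2)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.evaluate(points)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Velocities F at (k, 2) points (a single point is accepted too)."""
        pts = np.atleast_2d(np.asarray(points, float))
        out = self._kernel(pts) @ self.coefficients + self.bias
        return out if np.asarray(points).ndim == 2 else out[0]

    @property
    def drift(self):
        return self.evaluate

    def jacobian(self, points: np.ndarray) -> np.ndarray:
        """Closed-form Jacobian dF_a/dx_b, shape (k, 2, 2) (or (2, 2))."""
        pts = np.atleast_2d(np.asarray(points, float))
        diff = pts[:, None, :] - self.centers[None, :, :]          # (k, m, 2)
        k = np.exp(-0.5 * (diff**2).sum(-1) / self.bandwidth**2)   # (k, m)
        # dF_a/dx_b = sum_j w_ja * k_j * (-(x - c_j)_b / h^2)
        grad_k = -k[:, :, None] * diff / self.bandwidth**2         # (k, m, 2)
        J = np.einsum("kmb,ma->kab", grad_k, self.coefficients)
        return J if np.asarray(points).ndim == 2 else J[0]

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "coefficients": self.coefficients.tolist(),
            "bias": self.bias.tolist(),
            "bandwidth": self.bandwidth,
            "ridge": self.ridge,
            "domain": [self.domain.x_min, self.domain.x_max,
                       self.domain.y_min, self.domain.y_max],
            "heldout_rmse": self.heldout_rmse,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "VectorFieldModel":
        return cls(
            centers=np.asarray(d["centers"], float),
            coefficients=np.asarray(d["coefficients"], float),
            bias=np.asarray(d.get("bias", [0.0, 0.0]), float),
            bandwidth=float(d["bandwidth"]),
            ridge=float(d["ridge"]),
            domain=Rect(*d["domain"]),
            heldout_rmse=d.get("heldout_rmse"),
        )

    @classmethod
    def from_json(cls, s_or_path) -> "VectorFieldModel":
        try:
            d = json.loads(s_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(s_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


def _pick_centers(positions: np.ndarray, n_centers: int, seed: int) -> np.ndarray:
    uniq = np.unique(positions, axis=0)
    if len(uniq) <= n_centers:
        return uniq
    km = KMeans(n_clusters=n_centers, n_init=1, random_state=seed)
    km.fit(positions)
    return km.cluster_centers_


def fit_vector_field(
    samples,
    bandwidth: float | None = None,
    ridge: float = 1e-4,
    n_centers: int = 200,
    seed: int = 0,
    holdout_frac: float = 0.1,
) -> VectorFieldModel:
    """Fit the kernel expansion to a :class:`VelocitySampleSet`.

    The default bandwidth is half the median pairwise distance between
    centers, and the ridge penalty applies to the kernel weights only (the
    constant offset is unpenalized, so a constant field is reproduced
    exactly).
    A random ``holdout_frac`` of the samples is scored before the final fit
    on all samples; the RMSE is stored on the model.
    """
    pos = np.asarray(samples.positions, float)
    vel = np.asarray(samples.velocities, float)
    if len(pos) < 10:
        raise ValueError("need at least 10 samples to fit a field")
    centers = _pick_centers(pos, min(n_centers, len(pos)), seed)
    if bandwidth is None:
        # half the median pairwise center distance: wide enough for smooth
        # interpolation between centers, narrow enough to track the sharp
        # switching fronts of relaxation-type dynamics
        d = np.sqrt(((centers[:, None] - centers[None, :]) ** 2).sum(-1))
        bandwidth = 0.5 * float(np.median(d[np.triu_indices(len(centers), k=1)]))
        if bandwidth <= 0:
            raise ValueError("degenerate positions: cannot infer bandwidth")

    rng = np.random.default_rng(seed)
    heldout_rmse = None
    if holdout_frac > 0 and len(pos) >= 20:
        n_hold = max(1, int(holdout_frac * len(pos)))
        perm = rng.permutation(len(pos))
        hold, train = perm[:n_hold], perm[n_hold:]
        m = _solve(centers, pos[train], vel[train], bandwidth, ridge, samples)
        pred = m.evaluate(pos[hold])
        heldout_rmse = float(np.sqrt(np.mean((pred - vel[hold]) ** 2)))
    model = _solve(centers, pos, vel, bandwidth, ridge, samples)
    model.heldout_rmse = heldout_rmse
    return model


def _solve(centers, pos, vel, bandwidth, ridge, samples) -> VectorFieldModel:
    m = len(centers)
    d2 = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    phi = np.exp(-0.5 * d2 / bandwidth**2)
    X = np.column_stack([np.ones(len(pos)), phi])
    pen = np.diag(np.r_[0.0, np.full(m, ridge)])
    gram = X.T @ X + pen
    try:
        W = np.linalg.solve(gram, X.T @ vel)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular kernel system (duplicate positions with ridge=0?); "
            "raise the ridge parameter"
        ) from exc
    if hasattr(samples, "bounding_rect"):
        domain = samples.bounding_rect(0.1)
    else:
        domain = Rect(pos[:, 0].min(), pos[:, 0].max() + 1e-12,
                      pos[:, 1].min(), pos[:, 1].max() + 1e-12).expand(0.1)
    return VectorFieldModel(
        centers=centers, coefficients=W[1:], bias=W[0],
        bandwidth=bandwidth, ridge=ridge, domain=domain,
    )


# -- differential geometry ---------------------------------------------------

@dataclass
class GeometryFields:
    """Differential-geometry scalar/vector fields sampled on a grid.

    speed = |F|; divergence = tr J; curl = dFy/dx - dFx/dy (counterclockwise
    positive); acceleration a = J F; curvature = (a - (a.vhat) vhat)/|v|^2,
    NaN-flagged where the speed is below ``speed_tol``.
    """

    grid: StateGrid
    speed: np.ndarray
    divergence: np.ndarray
    curl: np.ndarray
    acceleration: np.ndarray   # (ny, nx, 2)
    curvature: np.ndarray      # (ny, nx, 2), NaN where undefined
    speed_tol: float = 1e-8


def differential_geometry(model, grid: StateGrid, speed_tol: float = 1e-8) -> GeometryFields:
    """Speed, divergence, curl, acceleration and curvature of a field on a grid.

    Works for any object exposing ``evaluate``/``drift`` and ``jacobian``
    (fitted models and synthetic systems alike).
    """
    pts = grid.centers_flat()
    drift = getattr(model, "drift", model)
    v = np.asarray(drift(pts), float)
    J = np.asarray(model.jacobian(pts), float)
    speed = np.linalg.norm(v, axis=1)
    div = np.trace(J, axis1=1, axis2=2)
    curl = J[:, 1, 0] - J[:, 0, 1]
    acc = np.einsum("kab,kb->ka", J, v)
    with np.errstate(divide="ignore", invalid="ignore"):
        vhat = v / speed[:, None]
        tang = (acc * vhat).sum(1)[:, None] * vhat
        curv = (acc - tang) / (speed**2)[:, None]
    curv[speed < speed_tol] = np.nan
    shape = (grid.ny, grid.nx)
    return GeometryFields(
        grid=grid,
        speed=speed.reshape(shape),
        divergence=div.reshape(shape),
        curl=curl.reshape(shape),
        acceleration=acc.reshape(shape + (2,)),
        curvature=curv.reshape(shape + (2,)),
        speed_tol=speed_tol,
    )


# -- fixed points ------------------------------------------------------------

@dataclass
class FixedPoint:
    location: np.ndarray
    eigenvalues: np.ndarray
    kind: str
    residual: float
    confidence: float

    @property
    def is_stable(self) -> bool:
        return self.kind in ("stable_node", "stable_focus")


def _classify(eig: np.ndarray) -> str:
    re = np.real(eig)
    if np.iscomplex(eig).any():
        return "stable_focus" if re.max() < 0 else "unstable_focus"
    if re.max() < 0:
        return "stable_node"
    if re.min() > 0:
        return "unstable_node"
    return "saddle"


def find_fixed_points(
    model,
    n_starts: int = 64,
    tol: float = 1e-6,
    seed: int = 0,
    domain: Rect | None = None,
    max_iter: int = 80,
) -> list[FixedPoint]:
    """Newton search for roots of F from seeded random starts.

    Converged roots inside the domain are deduplicated (distance < 10 tol up
    to a floor of 1e-4 in embedding units), classified by the eigenvalues of
    the analytic Jacobian and sorted by residual. An empty list (with a
    warning) is returned when no start converges.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    domain = domain or model.domain
    rng = np.random.default_rng(seed)
    starts = np.column_stack([
        rng.uniform(domain.x_min, domain.x_max, n_starts),
        rng.uniform(domain.y_min, domain.y_max, n_starts),
    ])
    drift = getattr(model, "drift", model)
    roots: list[np.ndarray] = []
    dedupe = max(10 * tol, 1e-4)
    for x0 in starts:
        x = x0.copy()
        ok = False
        for _ in range(max_iter):
            f = np.asarray(drift(x[None, :]))[0]
            if not np.all(np.isfinite(f)):
                break
            if np.linalg.norm(f) < tol:
                ok = True
                break
            J = np.asarray(model.jacobian(x[None, :]))[0]
            try:
                step = np.linalg.solve(J, -f)
            except np.linalg.LinAlgError:
                break
            nrm = np.linalg.norm(step)
            if nrm > 0.5 * max(domain.width, domain.height):
                step *= 0.5 * max(domain.width, domain.height) / nrm
            x = x + step
        if not ok or not domain.contains(x):
            continue
        if any(np.linalg.norm(x - r) < dedupe for r in roots):
            continue
        roots.append(x)
    if not roots:
        warnings.warn("no fixed point converged from any start", stacklevel=2)
        return []
    out = []
    for r in roots:
        f = np.asarray(drift(r[None, :]))[0]
        res = float(np.linalg.norm(f))
        eig = np.linalg.eigvals(np.asarray(model.jacobian(r[None, :]))[0])
        out.append(FixedPoint(
            location=r, eigenvalues=eig, kind=_classify(eig),
            residual=res, confidence=1.0 / (1.0 + res / tol),
        ))
    out.sort(key=lambda fp: fp.residual)
    return out
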