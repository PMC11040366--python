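"""In silico perturbation and Jacobian-based regulatory inference.

A small shift Delta x of gene expression propagates to the velocity field
through the Jacobian of the reconstructed drift, Delta f = J (c Delta x),
with c an amplification constant. Refitting a field to the perturbed
velocities yields a "mutant" dynamical system whose landscape, flux and
dissipation can be compared with the wild type.

Reading the Jacobian across sampled cell states also gives a signed
gene-gene interaction network (positive entries = activation, negative =
inhibition), and binning a Jacobian element against the regulator's
expression produces a response curve that can be fitted with the derivative
of a Hill function to recover kinetic parameters (A, K, n, and the
degradation rate g for self-interactions):

    activating   x -> y:  d/dx [A x^n / (K + x^n)] = A K n x^(n-1) / (K + x^n)^2
    inhibitory   x -| y:  the negative of the same derivative
    self (diagonal):      the activating derivative minus g
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .systems import VelocitySampleSet
from .vector_field import VectorFieldModel, fit_vector_field

__all__ = [
    "PerturbationSpec",
    "PerturbedVelocities",
    "GRNEdge",
    "ResponseCurve",
    "HillFit",
    "perturb_velocities",
    "refit_perturbed_field",
    "infer_grn",
    "response_curve",
    "fit_hill",
    "hill_derivative",
    "simulate_hill_kinetics",
    "auto_amplification",
]


@dataclass
class PerturbationSpec:
    """Signed expression shift per dimension, with amplification c."""

    deltas: np.ndarray
    amplification_c: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, float)
        if self.deltas.shape != (2,):
            raise ValueError("deltas must be a 2-vector")
        if not np.any(self.deltas):
            raise ValueError("at least one delta must be nonzero")
        if self.amplification_c <= 0:
            raise ValueError("amplification must be positive")


@dataclass
class PerturbedVelocities:
    positions: np.ndarray
    velocities_prime: np.ndarray
    spec: PerturbationSpec
    parent_source: str = ""

    def as_sample_set(self) -> VelocitySampleSet:
        return VelocitySampleSet(
            self.positions, self.velocities_prime,
            source=f"perturbed:{self.spec.label or 'unnamed'}",
        )


def auto_amplification(model: VectorFieldModel, samples: VelocitySampleSet,
                       deltas: np.ndarray, target_frac: float = 0.5) -> float:
    """Amplification c such that max |Delta f| is ``target_frac`` of the
    median sample speed."""
    J = np.asarray(model.jacobian(samples.positions))
    df = np.einsum("kab,b->ka", J, np.asarray(deltas, float))
    peak = np.abs(df).max()
    med_speed = np.median(np.linalg.norm(samples.velocities, axis=1))
    if peak == 0:
        return 1.0
    return float(target_frac * med_speed / peak)


def perturb_velocities(
    model: VectorFieldModel,
    samples: VelocitySampleSet,
    spec: PerturbationSpec,
) -> PerturbedVelocities:
    """Velocity response Delta f = J(x) (c Delta x) added at each sample."""
    J = np.asarray(model.jacobian(samples.positions))
    df = np.einsum("kab,b->ka", J, spec.amplification_c * spec.deltas)
    return PerturbedVelocities(
        positions=samples.positions.copy(),
        velocities_prime=samples.velocities + df,
        spec=spec,
        parent_source=samples.source,
    )


def refit_perturbed_field(perturbed: PerturbedVelocities, **fit_options) -> VectorFieldModel:
    """Reconstruct the perturbed vector field from the perturbed velocities."""
    return fit_vector_field(perturbed.as_sample_set(), **fit_options)


@dataclass
class GRNEdge:
    source: str
    target: str
    sign: int
    mean_jacobian: float
    support: float
    n_states: int


def infer_grn(
    model,
    states: np.ndarray,
    labels: tuple[str, str] = ("gene_x", "gene_y"),
    threshold: float | None = None,
    threshold_frac: float = 0.1,
) -> list[GRNEdge]:
    """Signed interactions from the state-averaged Jacobian.

    The Jacobian is evaluated at every supplied state; for each ordered pair
    (target, source) the mean entry and the fraction of states agreeing with
    its sign are reported. Edges below the threshold (default: 10% of the
    largest off-diagonal |mean|) get sign 0.
    """
    states = np.atleast_2d(np.asarray(states, float))
    J = np.asarray(model.jacobian(states))          # (k, 2, 2)
    means = J.mean(axis=0)
    if threshold is None:
        off = np.abs(np.array([means[0, 1], means[1, 0]]))
        threshold = threshold_frac * max(off.max(), 1e-300)
    edges = []
    for tgt in range(2):
        for src in range(2):
            m = float(means[tgt, src])
            sign = int(np.sign(m)) if abs(m) > threshold else 0
            vals = J[:, tgt, src]
            support = float((np.sign(vals) == np.sign(m)).mean()) if m != 0 else 0.0
            edges.append(GRNEdge(
                source=labels[src], target=labels[tgt],
                sign=sign, mean_jacobian=m, support=support,
                n_states=len(states),
            ))
    return edges


def grn_to_graph(edges: list[GRNEdge]):
    """Signed directed graph (networkx) of the non-null edges."""
    import networkx as nx

    g = nx.DiGraph()
    for e in edges:
        if e.sign != 0:
            g.add_edge(e.source, e.target, sign=e.sign,
                       weight=e.mean_jacobian, support=e.support)
    return g


@dataclass
class ResponseCurve:
    """Occupancy-weighted mean of one Jacobian element vs source expression."""

    bin_centers: np.ndarray
    weighted_mean_jacobian: np.ndarray
    weights: np.ndarray
    element: tuple[int, int]      # (target, source)

    def valid(self) -> np.ndarray:
        return self.weights > 0


def response_curve(
    model,
    states: np.ndarray,
    element: tuple[int, int],
    n_bins: int = 20,
) -> ResponseCurve:
    """Bin states by the source gene's expression; average the Jacobian element."""
    if n_bins < 4:
        raise ValueError("need at least 4 bins")
    states = np.atleast_2d(np.asarray(states, float))
    tgt, src = element
    x = states[:, src]
    J = np.asarray(model.jacobian(states))[:, tgt, src]
    edges = np.linspace(x.min(), x.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    weights = np.zeros(n_bins)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            means[b] = J[sel].mean()
            weights[b] = sel.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ResponseCurve(centers, means, weights, element)


def hill_derivative(x: np.ndarray, A: float, K: float, n: float) -> np.ndarray:
    """d/dx of the activating Hill function A x^n / (K + x^n)."""
    x = np.asarray(x, float)
    xn = np.where(x > 0, x, 0.0) ** n
    with np.errstate(divide="ignore", invalid="ignore"):
        d = A * K * n * np.where(x > 0, x, 1.0) ** (n - 1) / (K + xn) ** 2
    return np.where(x > 0, d, 0.0)


@dataclass
class HillFit:
    interaction_type: str     # activating | inhibitory | self_activating
    A: float | None
    K: float | None
    n: float | None
    g: float | None
    rss: float | None
    converged: bool
    element: tuple[int, int] | None = None


def fit_hill(
    curve: ResponseCurve,
    interaction_type: str,
    n_starts: int = 8,
    seed: int = 0,
) -> HillFit:
    """Weighted least-squares fit of a Hill derivative to a response curve.

    ``activating`` fits +dHill/dx, ``inhibitory`` fits -dHill/dx, and
    ``self_activating`` (diagonal elements) fits dHill/dx - g with a
    degradation offset. Positivity of (A, K, n, g) is enforced by log
    parameterization and the best of ``n_starts`` seeded restarts wins.
    """
    if interaction_type not in ("activating", "inhibitory", "self_activating"):
        raise ValueError(f"unknown interaction type {interaction_type!r}")
    ok = curve.valid() & np.isfinite(curve.weighted_mean_jacobian)
    if ok.sum() < 4:
        raise ValueError("need at least 4 non-missing bins")
    x = curve.bin_centers[ok]
    y = curve.weighted_mean_jacobian[ok]
    w = np.sqrt(curve.weights[ok] / curve.weights[ok].sum())
    if np.allclose(y, 0.0):
        return HillFit(interaction_type, None, None, None, None, None,
                       converged=False, element=curve.element)
    sign = -1.0 if interaction_type == "inhibitory" else 1.0
    with_g = interaction_type == "self_activating"

    def resid(theta):
        # clip the log-parameters so wild optimizer steps cannot overflow
        A = np.exp(np.clip(theta[0], -25.0, 25.0))
        K = np.exp(np.clip(theta[1], -25.0, 25.0))
        n = np.exp(np.clip(theta[2], 0.0, 3.0))     # Hill coefficient <= ~20
        pred = sign * hill_derivative(x, A, K, n)
        if with_g:
            pred = pred - np.exp(np.clip(theta[3], -25.0, 25.0))
        return w * (pred - y)

    scale = max(np.abs(y).max(), 1e-12)
    x_scale = max(np.median(x), 1e-6)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        n0 = [1.0, 2.0, 4.0, 6.0][s % 4] * np.exp(0.2 * rng.standard_normal())
        K0 = (x_scale * np.exp(rng.standard_normal())) ** n0
        A0 = scale * x_scale * np.exp(rng.standard_normal())
        theta0 = np.log([A0, K0, n0])
        if with_g:
            theta0 = np.r_[theta0, np.log(max(scale, 1e-6))]
        try:
            res = least_squares(resid, theta0, method="lm", max_nfev=4000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return HillFit(interaction_type, None, None, None, None, None,
                       converged=False, element=curve.element)
    A = np.exp(np.clip(best.x[0], -25.0, 25.0))
    K = np.exp(np.clip(best.x[1], -25.0, 25.0))
    n = np.exp(np.clip(best.x[2], 0.0, 3.0))
    g = float(np.exp(np.clip(best.x[3], -25.0, 25.0))) if with_g else None
    return HillFit(
        interaction_type, float(A), float(K), float(n), g,
        rss=float(2 * best.cost), converged=bool(best.success),
        element=curve.element,
    )


def simulate_hill_kinetics(
    fit_or_params,
    x_range: np.ndarray,
    interaction_type: str | None = None,
) -> np.ndarray:
    """Velocity contribution of the fitted Hill term over an expression range.

    Activating: A x^n/(K + x^n); inhibitory: A K/(K + x^n); self terms also
    subtract g x. Accepts a HillFit or a dict with keys A, K, n (and g).
    """
    if isinstance(fit_or_params, HillFit):
        A, K, n, g = fit_or_params.A, fit_or_params.K, fit_or_params.n, fit_or_params.g
        kind = interaction_type or fit_or_params.interaction_type
    else:
        d = dict(fit_or_params)
        A, K, n, g = d["A"], d["K"], d["n"], d.get("g")
        kind = interaction_type or d.get("interaction_type", "activating")
    x = np.asarray(x_range, float)
    xn = np.where(x > 0, x, 0.0) ** n
    if kind == "inhibitory":
        v = A * K / (K + xn)
    else:
        v = A * xn / (K + xn)
    if kind == "self_activating" and g is not None:
        v = v - g * x
    return v
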