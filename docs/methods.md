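# Methods

`fluxcycle` quantifies the nonequilibrium dynamics and thermodynamics of
oscillatory cell-state systems from a 2-D embedding with per-cell velocity
vectors — the reduced-space form in which RNA-velocity analyses of the cell
cycle operate. This note records the model, the estimators, the numerical
conventions, and the design choices made where the problem left them open.

## Dynamical model

Cell-state dynamics are modeled by the overdamped Langevin equation

    dx/dt = F(x) + zeta,   <zeta(t)> = 0,  <zeta(t) zeta(t')> = 2 D delta(t-t') I,

in dimensionless natural units (k_B = 1; the temperature scale is absorbed
into the diffusion coefficient D, in embedding-units²/time). F is either an
analytic synthetic drift or a field reconstructed from data. All machinery is
2-D: that is the space in which the downstream statistics (landscape,
flux, coherence) are defined, and where velocity embeddings live.

## Synthetic study systems

The generator provides ground-truth systems with analytic drift and Jacobian
so that every estimator can be validated against a known answer:

- **Two-gene Hill oscillator** (the flagship system):
  `fx = A1 x^n1/(K1+x^n1) + A2 K2/(K2+y^n2) − g1 x`,
  `fy = A3 y^n3/(K3+y^n3) + A4 x^n4/(K4+x^n4) − g2 y`.
  Gene x (G2-M-like) self-activates and activates gene y (G1-S-like); y
  represses x's basal production. The coupled positive + negative feedback
  produces a relaxation limit cycle. The default parameters
  (A1=1.6, K1=1, n1=4; A2=0.8, K2=1, n2=4; A3=0.2, K3=4, n3=4; A4=0.6,
  K4=3, n4=4; g1=1, g2=0.15) are package configuration: they were selected,
  once, by scanning the production/degradation balance for a robust cycle
  with O(1) concentrations and then frozen after passing a Poincaré-return
  oracle (a 50-period integration must return to its section crossing
  within 1% of the attractor size). Period ≈ 24.6 time units; an unstable
  focus sits at (0.91, 1.20).
- **Arrest variant**: raising y's self-activation (A3=0.9) with a threshold
  above the cycle's y-range (K3=81, threshold y=3) adds a quiescent stable
  state near (0, 5.5) behind a saddle near (0, 3) — a G0-like basin
  coexisting with the cycle, used for transition experiments.
- **Double well** `V = barrier((x/a)²−1)² + y²`: the equilibrium
  (detailed-balance) control with closed-form minima, saddle, barrier,
  Kramers passage time and uphill action.
- **Hopf rotator** (`ṙ = λ r (R²−r²)`, `θ̇ = ω`): an oscillator with exactly
  known period, orbit and speed for peak/coherence oracles.
- **Linear fields** `F = A x` for constant-Jacobian identities.

Velocity samples mimic real data: positions are scattered along stochastic
trajectories (the same Euler–Maruyama integrator as the landscape module,
small D = 0.01, burn-in discarded) or drawn uniformly; velocities are
`drift(position) + N(0, noise_sd²)` per component, with noise_sd = 0.05 the
default measurement noise (about 15% of the typical on-cycle speed). What
the generator does **not** emulate: high-dimensional gene space, embedding
distortion, velocity-estimation bias, and cell-density gradients unrelated
to dynamics — tests passing on these systems show the estimators are
correct, not that a particular biological dataset satisfies their
assumptions.

## Vector-field reconstruction

The drift is fitted with Gaussian kernel ridge regression plus an
unpenalized constant offset,

    F(x) = b + Σ_j w_j exp(−|x − c_j|²/(2 h²)),

with centers c_j a k-means subsample (default min(n, 200)) of the sample
positions. The expansion is differentiable in closed form, giving the
analytic Jacobian that perturbation and interaction inference consume. The
default bandwidth is **0.5×** the median pairwise distance between centers:
the unscaled median of a 2-D cloud is about half the domain size, which
oversmooths the sharp switching fronts of relaxation dynamics; halving it
recovers held-out errors at the measurement-noise floor while keeping the
field smooth between centers (both verified against the generating drift in
the test suite). Ridge default 1e-4 applies to kernel weights only, so a
constant field is reproduced exactly. A random 10% holdout is scored before
the final fit and the RMSE stored on the model.

Fixed points come from Newton iteration (analytic Jacobian) from seeded
random starts, deduplicated at max(10·tol, 1e-4), classified by eigenvalues,
and sorted by residual. Differential geometry (speed, divergence, curl as
∂vy/∂x − ∂vx/∂y with counterclockwise positive, acceleration a = J·F,
curvature (a − (a·v̂)v̂)/|v|²) is evaluated from the analytic Jacobian on
cell-centered grids; curvature is NaN-flagged where |v| < 1e-8.

## Landscape and flux

The steady-state density Pss is the long-run histogram of an
Euler–Maruyama ensemble (default 500 trajectories from uniform random
initial states, reflecting boundaries on the declared domain, dt chosen so
|F| dt ≪ cell size). U = −ln Pss, min-shifted to zero. Empty cells are
floored at 0.1/(total samples × cell area) so −ln stays finite and floored
cells are excluded (masked) from all thermodynamic sums. The flux is
J = F Pss − D ∇Pss with central differences (one-sided at edges), and the
decomposition F = −D∇U + J/Pss closes on masked cells up to discretization
error — refining the grid in the truncation-dominated regime reduces the
residual quadratically, until Monte-Carlo noise in the histogram takes over
(the grids used in the checks sit in the truncation-dominated regime).

Barriers: basin seeds (stable fixed points slid downhill; the ring valley
seeded by descending from the interior unstable focus) are joined by
minimax (bottleneck) search on the 8-connected grid graph — the joining
level is the saddle. The oscillation-center barrier is the local maximum of
U in a disk (10% of the grid) around the interior focus, minus min U. Ring
integrity is summarized by the **ring break level**: the maximin path value
from the cycle center to the domain boundary, i.e. the worst along-valley
barrier a state must cross to circulate. A break level well below the
center hump means an intact closed valley; when it approaches the hump the
valley has fragmented into discrete basins (the arrested-phases regime at
high noise).

## Thermodynamics

With k_B T ≡ D (the identification that makes the steady-state entropy
balance close under the 2D-noise convention):

    S   = −Σ Pss ln Pss ΔA       (masked cells)
    EPR = Σ |J|²/(D Pss) ΔA
    HDR = Σ (F·J)/D ΔA

EPR ≥ 0 by construction and equals HDR at stationarity; the equality (to a
few percent) is used as the convergence check of the ensemble. Because the
plain EPR sums |J|², Monte-Carlo noise in ∇Pss gives it a positive bias
that can swamp a near-equilibrium system's tiny true value; for
cross-system comparisons the package provides a split-ensemble estimator
(`epr_cross`) that multiplies the fluxes of two independent half-ensembles,
whose noises are uncorrelated, making the estimate first-order unbiased.
Relatedly, Euler–Maruyama sampling carries an O(dt) distortion of the
stationary density that shows up as spurious flux in steep gradient
systems; halving dt halves it, and near-equilibrium comparisons use a
smaller step. The loop
flux is ∮J·dl / ∮dl along the **mean limit cycle** — the deterministic
orbit of the drift, resampled to 200 equal-arc-length vertices — with J
interpolated bilinearly to segment midpoints; its sign follows loop
orientation (exactly antisymmetric under reversal). Energy per period is
EPR × T.

## Transitions

The least-action path minimizes the discretized functional
`S = ½ Σ |Δx/Δt − F(midpoint)|²/D Δt` (the printed ½/D normalization; note
this is twice the ¼/D convention sometimes used for noise covariance 2D —
all internal oracles use the same convention, under which the uphill action
in a gradient system is exactly 2ΔV/D). Interior waypoints are optimized by
L-BFGS with the analytic action gradient; an outer search over the
traversal time T spans 0.1–10× the deterministic travel-time scale
(geometric grid, best restart wins), since the action keeps decreasing
toward the quasi-static limit and the search makes the optimum explicit.
Rates follow R = C exp(−S) with C defaulting to 1 (all cross-condition
comparisons use ln-MFPT differences, so C cancels); MFPT = 1/R. The
simulation-based estimator releases trajectories at a source basin center
and records first entry to the target disk (default radius 10% of the
inter-attractor distance); censored runs are counted, not imputed.

## Oscillation statistics

Peaks are local maxima of a centered moving-average-smoothed coordinate
(default: first embedding coordinate) with prominence ≥ 10% of signal range;
the smoothing window should be a modest fraction of the period (the sweep
analyses use ≈ T/4 with prominence 0.3, which suppresses noise-split double
peaks at high D). From a common-start ensemble, var(t_i) grows linearly with
mean(t_i); the slope (first 10% of peak indices excluded) is the peak-time
diffusion constant D_peak, and D_phi = D_peak (2π)²/(2T) — the conversion is
a declared linear convention, and D_peak is always reported so any
rescaling is recoverable. The autocorrelation is fitted with
exp(−t/τ_c)cos(2πt/T); fits at the τ cap are flagged as lower bounds. The
PSD is the Welch segment-averaged periodogram (Hann window, density
normalization over angular frequency, so ∫S dω = variance); with a boxcar
window and a single full-length segment it reduces to the plain
periodogram, the exact Fourier pair of the biased autocorrelation
(Wiener–Khinchin, cross-checked in the tests). Ensemble averaging of
spectra/autocorrelations is used wherever a stable peak width or τ_c is
needed. Phase coherence uses the signed angle φ(t) between N(t) and
N(t+τ) about the cycle center (default: interior unstable focus), with
ξ = 2Σθ(φ)|φ|/Σ|φ| − 1 — the normalization chosen so ξ is exactly +1/−1/≈0
in the coherent/reversed/diffusive limits; τ should lie between the fast
fluctuation scale and the period (T/8 in the analyses).

## Perturbation and interaction inference

A genetic perturbation Δx maps to a velocity response Δf = J(x)·(cΔx) at
every cell; the default amplification c scales max|Δf| to 50% of the median
speed, and "strong" (oscillation-breaking) perturbations use 3× that scale —
strength is a modeling choice, and both are exposed. The perturbed field is
re-fitted from the shifted velocities (the compositional alternative
J-shifted field is available but refit is the default), and all downstream
modules consume it unchanged. Signed interactions are state-averaged
Jacobian entries with a threshold of 10% of the largest off-diagonal mean;
support is the fraction of states agreeing with the mean's sign. Response
curves bin a Jacobian element by the regulator's expression (equal-width
bins, occupancy weights) and are fitted with the derivative of the Hill
function, A K n x^(n−1)/(K+x^n)² (negated for inhibition; minus a constant
g for self-interactions), by weighted least squares with log-parameterized
positivity and ≥8 seeded multistarts. K carries units of concentration^n,
as in the kinetic model.

## Pipeline, I/O, preprocessing

Velocity tables are TSV (cell_id, x, y, vx, vy) with a JSON sidecar (seed,
noise, provenance); models serialize to JSON; grid fields export in long
TSV. The expression-matrix filter removes cells with fewer than a cutoff of
detected (strictly positive) genes first, then genes detected in fewer than
a cutoff of the remaining cells — the order matters and is fixed. The
pipeline driver validates configs against known keys (unknown keys are
errors), seeds every stochastic stage, and writes a manifest with
parameters and file checksums sufficient to re-execute any stage.

## Problem sizes and determinism

The analyses use ensembles of 250–500 trajectories over 800–1650 time units
(tens of periods) at dt = 0.005 with thinned recording, 80–100×100 grids,
and 150–500 first-passage trajectories per condition; these sizes put the
decomposition residual in the truncation-dominated regime and EPR/HDR
agreement at the few-percent level while keeping a full analysis on one CPU
in minutes. Every stochastic routine takes an explicit seed and is
bit-reproducible given it.

## Known limitations

- 2-D only, isotropic constant D; no state-dependent or anisotropic noise.
- Histogram landscapes, not a Fokker–Planck solve: accuracy is Monte-Carlo
  limited in low-density regions (hence the floor/mask machinery).
- The direction of the period and amplitude response to noise is
  system-dependent: the shipped relaxation oscillator's period is nearly
  noise-independent (±1%) and its smoothed peak-trough amplitude shrinks
  with noise (noise lets trajectories cut the slow corners), whereas softer
  reconstructed fields can show noise-widened cycles and longer periods.
  The monotone trends the package does reproduce robustly across noise are:
  barriers and spectral peak down; spectral width, phase diffusion up;
  coherence time and phase coherence down.
- In two-attractor landscapes the EPR trend across a noise sweep depends on
  which attractor holds the probability mass: when the quiescent basin
  dominates and mass shifts toward the cycle as noise rises, EPR rises with
  noise even as barriers and passage times fall.
- Kernel-ridge reconstruction has no outlier model; grossly corrupted
  velocity measurements should be filtered upstream.
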