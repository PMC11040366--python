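# fluxcycle

Nonequilibrium landscape–flux analysis of oscillatory cell-state dynamics —
the cell cycle being the motivating case — from a 2-D embedding of cell
states with per-cell velocity vectors (the reduced-space representation of
RNA velocity).

Single-cell velocity measurements are sparse and noisy, but they sample a
continuous drift field F(x). `fluxcycle` reconstructs that field, then asks
the statistical-physics questions that a list of per-cell arrows cannot
answer directly:

- **Where do cells live, and what holds them there?** The stochastic
  dynamics `dx/dt = F(x) + ζ`, with white noise of covariance 2D, is
  simulated to its steady state; the potential landscape is `U = −ln Pss`,
  whose valleys are cell-cycle phases and whose ridges are checkpoints.
- **What drives the cycle around?** The driving force decomposes as
  `F = −D∇U + Jss/Pss`: a gradient part pulling downhill and a rotational
  curl flux `J = F·Pss − D∇Pss` that sustains the oscillation. At detailed
  balance J = 0; a living cycle is a nonequilibrium steady state.
- **What does it cost?** Entropy production rate `EPR = Σ|J|²/(D·Pss)·ΔA`
  equals heat dissipation `HDR = Σ(F·J)/D·ΔA` at stationarity — the
  thermodynamic price of keeping the oscillation coherent.
- **How do cells enter and leave the cycle?** Least-action paths minimize
  `S_T = ½∫|ẋ − F|²/D dt` between attractors; transition rates follow
  `R = C·e^{−S}` and MFPT = 1/R, cross-checked by direct first-passage
  simulation.
- **How coherent is the clock?** Peak-time variance grows linearly with
  time (slope = peak-time diffusion; phase diffusion
  `D_φ = D_peak(2π)²/2T`), the autocorrelation decays as
  `e^{−t/τ_c}cos(2πt/T)`, the power spectrum's peak and width track
  oscillation stability, and the phase coherence ξ ∈ [−1, 1] measures the
  persistence of rotation direction.
- **Which gene talks to which?** In silico perturbations propagate as
  `Δf = J(x)·(cΔx)`; the state-averaged Jacobian gives signed
  gene–gene interactions, and fitting the Hill-function derivative
  `A·K·n·x^{n−1}/(K+x^n)²` to Jacobian-vs-expression response curves
  recovers kinetic parameters (A, K, n, g).

A built-in synthetic module generates ground-truth systems — a two-gene
Hill relaxation oscillator emulating cell-cycle dynamics (with an optional
coexisting quiescent basin), a double-well equilibrium control, and a
rotator with exactly known period — so the whole pipeline is testable
without external data.

## Worked example

```bash
python examples/03_landscape_flux.py
```

prints (exact numbers reproduce with the seeds in the script):

```
landscape from 16,200,000 states; U range [0, 12.1]
decomposition residual (median over sampled cells): 0.0015 (how exactly F = -D grad U + J/Pss closes numerically)
oscillation-center barrier: 5.19 k_B-units (depth of the ring valley below the central hump; larger = more stable oscillation)
ring break level: 2.36 (worst along-valley barrier; well below the center hump = intact closed cycle valley)
```

The residual 0.0015 says the gradient + curl-flux decomposition closes to
0.15% of the typical force on the sampled region. The barrier of 5.19 means
the ring valley sits e^5.19 ≈ 180× higher in probability than the hump at
the cycle center; the break level of 2.36 — well below the hump — says the
valley forms an intact closed loop, i.e. an uninterrupted cycle.

The other scripts in `examples/` each exercise one capability: synthetic
data (01), field reconstruction and differential geometry (02),
thermodynamics (04), least-action paths and passage times (05, including
the closed-form check `uphill action = 2ΔV/D`: prints 10.014 vs 10.0),
oscillation coherence (06), perturbation and gene-network inference (07),
and the end-to-end pipeline driver (08).

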