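"""End-to-end pipeline: synthesize -> fit -> landscape -> flux -> thermo.

One config drives the whole chain and writes a manifest (seeds, parameters,
checksums) sufficient to re-execute any stage in isolation.
"""
import fluxcycle as fc

cfg = fc.RunConfig(
    system="hill_oscillator",
    n_samples=800,
    D_values=[0.01, 0.05],
    grid_nx=60,
    sde_t_total=300.0,
    sde_burn_in=50.0,
    sde_n_traj=150,
    seed=1,
    out_dir="pipeline_demo",
)
manifest = fc.run_pipeline(cfg)
print("stages:", [s["stage"] for s in manifest["stages"]])
for tag, res in manifest["results"].items():
    th = res["thermo"]
    print(f"{tag}: EPR = {th['EPR']:.3f}, flux_loop = {th['flux_loop']:.4f}, "
          f"center barrier = {res['barrier_center']:.2f}")
# EPR and loop flux fall as noise rises -- the oscillation is cheapest to
# sustain, and most strongly driven, in the low-noise regime
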