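"""End-to-end pipeline driver: samples -> field -> landscape -> flux -> thermo.

The configuration is a flat YAML/dict record validated against the known
keys (unknown keys are errors, preventing silent typos); every stochastic
stage records its seed in the run manifest so any stage can be re-executed
in isolation.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import systems as syn
from .grids import StateGrid
from .io import export_grid_fields, read_state_velocity_table, write_state_velocity_table
from .landscape import SDEConfig, barrier_heights, compute_flux, steady_state_landscape
from .thermo import mean_limit_cycle, thermo_summary
from .vector_field import find_fixed_points, fit_vector_field

__all__ = ["RunConfig", "load_config", "run_pipeline"]

log = logging.getLogger("fluxcycle")


@dataclass
class RunConfig:
    """Pipeline settings; defaults give a small but complete synthetic run."""

    system: str = "hill_oscillator"        # or a path to a state-velocity TSV
    n_samples: int = 1500
    noise_sd: float = 0.05
    D_values: list = field(default_factory=lambda: [0.01])
    grid_nx: int = 80
    sde_t_total: float = 400.0
    sde_burn_in: float = 60.0
    sde_n_traj: int = 200
    sde_dt: float = 0.01
    seed: int = 0
    out_dir: str = "fluxcycle_run"

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path_or_dict) -> RunConfig:
    """Load a RunConfig from YAML (or a dict); unknown keys are rejected."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _get_system(cfg: RunConfig):
    factories = {
        "hill_oscillator": syn.default_hill_oscillator,
        "arrest_hill_oscillator": syn.arrest_hill_oscillator,
    }
    if cfg.system in factories:
        return factories[cfg.system]()
    path = Path(cfg.system)
    if not path.exists():
        raise FileNotFoundError(
            f"config 'system' is neither a known synthetic kind "
            f"({sorted(factories)}) nor an existing file: {cfg.system}"
        )
    return None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute fit -> landscape -> flux -> thermo for each D; write artifacts.

    Returns the manifest (also written as ``manifest.json``): completed
    stages, parameters, seeds, and checksums of every written file. A stage
    failure aborts the run but the manifest still records the completed
    stages.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": [], "files": {}}
    manifest_path = out / "manifest.json"

    def record(stage: str, **info):
        log.info("stage %s done %s", stage, info)
        manifest["stages"].append({"stage": stage, **info})
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        system = _get_system(cfg)
        if system is not None:
            samples = syn.sample_velocities(
                system, cfg.n_samples, noise_sd=cfg.noise_sd, seed=cfg.seed)
            record("synthesize", system=cfg.system, n=samples.n, seed=cfg.seed)
        else:
            samples = read_state_velocity_table(cfg.system)
            record("load", path=cfg.system, n=samples.n)
        p = write_state_velocity_table(samples, out / "samples.tsv")
        manifest["files"]["samples.tsv"] = _checksum(p)

        model = fit_vector_field(samples, seed=cfg.seed)
        model.to_json(out / "model.json")
        manifest["files"]["model.json"] = _checksum(out / "model.json")
        record("fit_vector_field", heldout_rmse=model.heldout_rmse,
               bandwidth=model.bandwidth)

        fps = find_fixed_points(model, seed=cfg.seed)
        record("fixed_points", n=len(fps),
               kinds=[fp.kind for fp in fps])

        results = {}
        for D in cfg.D_values:
            sde = SDEConfig(D=D, dt=cfg.sde_dt, t_total=cfg.sde_t_total,
                            burn_in=cfg.sde_burn_in, n_traj=cfg.sde_n_traj,
                            seed=cfg.seed)
            grid = StateGrid.from_rect(model.domain, cfg.grid_nx)
            land = steady_state_landscape(model, sde, grid)
            decomp = compute_flux(model, land)
            loop = None
            if any(fp.kind == "unstable_focus" for fp in fps):
                try:
                    loop = mean_limit_cycle(model)
                except Exception:
                    loop = None
            th = thermo_summary(model, land, decomp, loop=loop)
            bars = barrier_heights(land, fps)
            tag = f"D_{D:g}"
            export_grid_fields(grid, {"pss": land.pss, "U": land.U},
                               out / f"landscape_{tag}.tsv")
            manifest["files"][f"landscape_{tag}.tsv"] = _checksum(out / f"landscape_{tag}.tsv")
            results[tag] = {
                "thermo": th.to_dict(),
                "barrier_center": bars.barrier_center,
                "barriers": bars.barrier_to_saddle,
            }
            with open(out / f"thermo_{tag}.json", "w") as fh:
                json.dump(results[tag], fh, indent=2, default=str)
            record(f"landscape_flux_thermo[{tag}]", D=D, seed=cfg.seed,
                   EPR=th.EPR, HDR=th.HDR)
        manifest["results"] = results
    except Exception as exc:
        manifest["failed"] = repr(exc)
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
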