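"""Pipeline orchestration: run stages from a config, write outputs + manifest."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash, save_config
from .errors import ParameterError, SpinefemError
from .geometry import build_base_geometry, geometry_to_geojson
from .meshing import write_vtk
from .morphogenesis import (
    PROCESS_NAMES,
    calibrate,
    poisson_sweep,
    run_ablation,
    run_simulation,
)
from .quantify import density_map, labeled_fraction, min_distance_to_dp, region_counts
from .synth import generate_stack, points_to_csv

log = logging.getLogger("spinefem")

STAGES = ("synth", "simulate", "quantify", "ablate", "sweep", "calibrate")


def _write_trajectory(traj, out: Path, tag: str, vtk_every: int = 10) -> list[Path]:
    files = []
    areas = out / f"{tag}_areas.csv"
    traj.records.to_csv(areas, index=False)
    files.append(areas)
    metrics = {
        "final_cortex_fraction": traj.final_cortex_fraction(),
        "final_furrow_depth_um": float(traj.final["furrow_depth"]),
        "final_medulla_fraction": float(traj.final["frac_medulla"]),
        "final_medulla_convexity_deficit": float(
            traj.final["medulla_convexity_deficit"]
        ),
        "n_steps": int(len(traj.taus) - 1),
        "n_elements": int(traj.meshes[0].n_elements),
    }
    mpath = out / f"{tag}_metrics.json"
    mpath.write_text(json.dumps(metrics, indent=2))
    files.append(mpath)
    for i in range(0, len(traj.meshes), vtk_every):
        vpath = out / f"{tag}_step{i:03d}.vtk"
        write_vtk(traj.meshes[i], vpath)
        files.append(vpath)
    return files


def run_pipeline(cfg: RunConfig, stages, out_dir=None) -> dict:
    """Run the requested stages; returns (and writes) the output manifest.

    Every output is re-derivable from the config + seed; the manifest lists
    the files, the config hash and the package version.  Stage failures are
    logged and re-raised.
    """
    stages = list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ParameterError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")

    out = Path(out_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    files: list[Path] = []
    save_config(cfg, out / "config.yaml")
    files.append(out / "config.yaml")

    geom = build_base_geometry(cfg.geometry)
    geometry_to_geojson(geom, out / "geometry.geojson")
    files.append(out / "geometry.geojson")

    traj = None
    for stage in stages:
        t0 = time.time()
        log.info("stage %s: start", stage)
        try:
            if stage == "synth":
                stack = generate_stack(cfg.generator, seed=cfg.seed)
                for sec in stack:
                    p = out / f"synth_z{sec.z_index:03d}.csv"
                    points_to_csv(sec, p)
                    files.append(p)
            elif stage == "simulate":
                traj = run_simulation(
                    geom,
                    cfg.schedule,
                    cfg.materials,
                    mesh_size=cfg.simulation.mesh_size,
                    bc=cfg.simulation.bc,
                )
                files += _write_trajectory(traj, out, "simulate")
                log.info(
                    "stage simulate: final cortex fraction %.3f",
                    traj.final_cortex_fraction(),
                )
            elif stage == "quantify":
                stack = generate_stack(cfg.generator, seed=cfg.seed)
                rows = []
                for sec in stack:
                    counts = region_counts(sec, "hoechst")
                    counts.update(
                        {
                            "z_index": sec.z_index,
                            "brdu_posterior_fraction": labeled_fraction(
                                sec, "posterior_with_brdu", "brdu"
                            ),
                        }
                    )
                    rows.append(counts)
                cpath = out / "quantify_counts.csv"
                pd.DataFrame(rows).to_csv(cpath, index=False)
                files.append(cpath)
                sec0 = stack[0]
                dm = density_map(sec0, "hoechst")
                dpath = out / "quantify_density_hoechst.csv"
                dm.to_csv(dpath)
                files.append(dpath)
                _, summary = min_distance_to_dp(sec0, "brdu")
                spath = out / "quantify_summary.json"
                spath.write_text(json.dumps(summary, indent=2))
                files.append(spath)
            elif stage == "ablate":
                for which in PROCESS_NAMES:
                    traj_a = run_ablation(
                        geom,
                        cfg.schedule,
                        which,
                        materials=cfg.materials,
                        mesh_size=cfg.simulation.mesh_size,
                        bc=cfg.simulation.bc,
                    )
                    files += _write_trajectory(
                        traj_a, out, f"ablate_{which}", vtk_every=len(traj_a.meshes)
                    )
            elif stage == "sweep":
                df = poisson_sweep(
                    geom,
                    [0.2, 0.3, 0.4],
                    cfg.schedule,
                    cfg.materials,
                    mesh_size=cfg.simulation.mesh_size,
                )
                spath = out / "sweep_poisson.csv"
                df.to_csv(spath, index=False)
                files.append(spath)
                (out / "sweep_poisson.json").write_text(
                    json.dumps(
                        {"cortex_fraction_spread_pp": df.attrs["cortex_fraction_spread"]}
                    )
                )
                files.append(out / "sweep_poisson.json")
            elif stage == "calibrate":
                result = calibrate(
                    free_params={"schedule.lambda_z_max": (2.0, 4.0)},
                    targets={"final_cortex_fraction": 0.27},
                    geometry_params=cfg.geometry,
                    schedule=cfg.schedule,
                )
                cpath = out / "calibrate_result.json"
                cpath.write_text(
                    json.dumps(
                        {
                            "anchors": result["anchors"],
                            "objective": result["objective"],
                            "converged": result["converged"],
                            "lambda_z_max": result["schedule"].lambda_z_max,
                        },
                        indent=2,
                    )
                )
                files.append(cpath)
        except SpinefemError:
            log.exception("stage %s failed", stage)
            raise
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)

    manifest = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "stages": stages,
        "files": sorted(str(p.relative_to(out)) for p in files),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
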