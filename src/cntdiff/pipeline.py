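"""End-to-end analysis pipeline driven by a YAML configuration.

A run builds (or loads) a surface, generates synthetic trajectories (or
loads a dump file), computes the structural descriptors and diffusion
coefficients, and writes delimited-text tables plus a machine-readable
JSON summary.  Every stage is seeded from the config, so a run is fully
reproducible from (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import descriptors, diffusion, groove, structures, synthetic, trajio

log = logging.getLogger("cntdiff")

#: Analysis defaults: Einstein fit window (ps), hydration cutoff (Å),
#: lateral bin (Å), tilt bin (deg), orientation bin (deg), folded cells.
DEFAULTS = {
    "fit_window": [4.0, 10.0],
    "hydration_cutoff": 5.0,
    "lateral_bin": 0.1,
    "tilt_bin": 0.36,
    "orientation_bin": 3.6,
    "n_cells": 4,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    surface: dict
    brownian: dict
    seed: int = 0
    n_replicates: int = 4
    adsorbate: dict | None = None
    solvent: dict | None = None
    analysis: dict = field(default_factory=dict)
    outdir: str = "cntdiff_out"

    def __post_init__(self):
        merged = dict(DEFAULTS)
        merged.update(self.analysis)
        self.analysis = merged

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return RunConfig(**raw)


def build_surface(cfg: dict) -> structures.Structure:
    """Build the surface a config section describes."""
    kind = cfg.get("kind", "graphene")
    a_cc = cfg.get("a_cc", structures.DEFAULT_A_CC)
    if kind == "graphene":
        return structures.build_graphene(cfg.get("n_armchair", 40),
                                         cfg.get("n_zigzag", 23), a_cc)
    if kind == "cnt":
        return structures.build_cnt(cfg.get("n", 15), cfg.get("m", 15),
                                    cfg.get("n_cells", 41), a_cc,
                                    kind=cfg.get("side", "cylinder_exterior"))
    if kind == "groove":
        return structures.build_groove(cfg.get("n", 15), cfg.get("n_cells", 41),
                                       cfg.get("gap", structures.DEFAULT_GROOVE_GAP),
                                       a_cc)
    raise ValueError(f"unknown surface kind {kind!r}")


def _write_msd(path: Path, par: diffusion.MSDCurve, perp: diffusion.MSDCurve):
    data = np.column_stack([par.lags, par.msd, perp.msd, par.msd + perp.msd])
    np.savetxt(path, data, header="lag_ps msd_par_A2 msd_perp_A2 msd_2d_A2")


def run_pipeline(config: RunConfig) -> dict:
    """Execute build -> synth -> descriptors -> diffusion (-> groove).

    Returns the summary dictionary (also written to ``summary.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    summary: dict = {"seed": config.seed, "config": {
        "surface": config.surface, "brownian": config.brownian,
        "analysis": config.analysis}}

    stage = "build"
    try:
        struct = build_surface(config.surface)
        spec = struct.spec
        trajio.structure_to_xyz(struct, outdir / "surface.xyz")
        summary["surface"] = {"kind": spec.kind, "n_atoms": struct.n_atoms,
                              "box": struct.box.tolist(),
                              "radius": spec.radius}

        stage = "synth"
        b = dict(config.brownian)
        n_rep = config.n_replicates
        paths = []
        for _ in range(n_rep):
            p = synthetic.BrownianParams(
                D_par=b.get("D_par", 1.41), D_perp=b.get("D_perp", 3.50),
                dt=b.get("dt", 0.1), n_steps=b.get("n_steps", 20000),
                seed=int(rng.integers(2 ** 31)), surface=spec,
                height=b.get("height", synthetic.DEFAULT_HEIGHT))
            path, traj = synthetic.simulate_surface_brownian(p)
            paths.append(path)
        trajio.write_lammps_dump(traj, outdir / "walker.dump")
        log.info("synth: %d replicates x %d steps", n_rep, b.get("n_steps", 20000))

        stage = "diffusion"
        window = tuple(config.analysis["fit_window"])
        msd_par = diffusion.compute_msd(paths, "par", max_lag=4 * window[1])
        msd_perp = diffusion.compute_msd(paths, "perp", max_lag=4 * window[1])
        _write_msd(outdir / "msd.tsv", msd_par, msd_perp)
        dres = diffusion.fit_diffusion(msd_par, msd_perp, window)
        summary["diffusion"] = {k: round(v, 4) for k, v in asdict(dres).items()
                                if isinstance(v, float)}

        stage = "descriptors"
        if config.adsorbate is not None:
            template, species, moieties = synthetic.dopamine_like()
            a = dict(config.adsorbate)
            model = synthetic.AdsorbateModel(
                template, species, moieties,
                d_dist=synthetic.GaussianMixture1D(
                    tuple(a.get("d_weights", (1.0,))),
                    tuple(a.get("d_centers", (3.5,))),
                    tuple(a.get("d_widths", (0.0,)))),
                tilt_dist=synthetic.GaussianMixture1D.delta(a.get("tilt", 0.0)),
                orient_dist=synthetic.GaussianMixture1D.delta(a.get("orientation", 0.0)))
            ads = synthetic.simulate_adsorbate(model, paths[0], spec,
                                               seed=int(rng.integers(2 ** 31)))
            d_amine = []
            tilts = []
            for i in range(ads.n_frames):
                frame = descriptors.make_whole(ads.coords[i], spec.box, spec.periodic)
                com = descriptors.moiety_com(frame, moieties, "amine")
                from .geometry import signed_vertical_distance
                d_amine.append(float(signed_vertical_distance(com[None, :], spec)[0]))
                tilts.append(descriptors.tilt_angle(frame[moieties.c2],
                                                    frame[moieties.c7], spec))
            summary["adsorbate"] = {"amine_d_mean": round(float(np.mean(d_amine)), 3),
                                    "tilt_mean_deg": round(float(np.mean(tilts)), 3)}

            if config.solvent is not None:
                smodel = synthetic.SolventModel(**config.solvent)
                water = synthetic.simulate_solvent(
                    smodel, spec, n_frames=min(50, ads.n_frames),
                    seed=int(rng.integers(2 ** 31)))
                counts = [descriptors.hydration_count(
                    descriptors.make_whole(ads.coords[i], spec.box, spec.periodic),
                    water.coords[i], spec,
                    cutoff=config.analysis["hydration_cutoff"])
                    for i in range(water.n_frames)]
                summary["N_water"] = {"mean": round(float(np.mean(counts)), 2),
                                      "std": round(float(np.std(counts)), 2)}

        stage = "groove"
        if spec.kind == "groove":
            labels, gtraj, _ = synthetic.simulate_wall_switching(
                config.brownian.get("jump_rate", 1.9),
                duration_ns=config.brownian.get("duration_ns", 10.0),
                dt_ps=b.get("dt", 0.1), seed=int(rng.integers(2 ** 31)), spec=spec)
            est = groove.jump_rate(groove.assign_wall(
                gtraj.coords[:, 0, :], spec, gtraj.times))
            summary["groove"] = {"jump_rate_per_ns": round(est.rate, 3),
                                 "n_events": est.n_events}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
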