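"""Reproducible multi-stage runs with a seed registry and output manifest.

A run configuration (dict or YAML file) names an output directory, a master
seed and an ordered list of stages; every stochastic stage gets a recorded
seed derived from the master seed, and the manifest lists parameters, seeds,
timings and the SHA-256 of every output file, so a rerun with the same
configuration is hash-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import descriptors, efflux, enrichment, grid, io, membrane, photobleach, thermo

log = logging.getLogger("memsolv.pipeline")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    return yaml.safe_load(Path(source).read_text())


def _grid_for(context, params):
    cfg = context["config"]
    return grid.GridSpec.for_box(cfg.box, params.get("cell_edge", 1.0),
                                 params.get("stamp_radius", 2.6))


def _stage_gen_membrane(context, params, seed, outdir):
    kind = params.get("kind", "flat")
    if kind == "flat":
        cfg = membrane.generate_flat_bilayer(
            params.get("n_lipids_per_leaflet", 256),
            params.get("dl_fraction", 0.0),
            params.get("thickness", 38.0),
            params.get("box"), params.get("positional_noise", 0.0), seed,
            params.get("water_density", 0.0))
    elif kind == "defect":
        box = params["box"]
        fp = None
        if "footprint" in params:
            f = params["footprint"]
            fp = membrane.CircularFootprint(tuple(f["center"]), f["radius"],
                                            (box[0], box[1]))
        bulk = params.get("thickness", 38.0)
        depth = params.get("thinning_depth", 0.0)
        sigma = params.get("thinning_sigma", 15.0)
        cx, cy = (fp.center if fp else (box[0] / 2, box[1] / 2))

        def thick(x, y):
            dx = x - cx - box[0] * np.round((x - cx) / box[0])
            dy = y - cy - box[1] * np.round((y - cy) / box[1])
            return bulk - depth * np.exp(-(dx**2 + dy**2) / (2 * sigma**2))

        planted = membrane.PlantedField(
            thickness_field=thick, tilt_field=params.get("tilt", 0.0),
            dl_fraction_field=params.get("dl_fraction", 0.0), footprint=fp,
            water_slab=params.get("water_density", 0.0))
        cfg = membrane.generate_defect_bilayer(
            planted, params.get("n_lipids_per_leaflet", 256), box,
            params.get("positional_noise", 0.0), seed)
    else:
        raise ValueError(f"unknown membrane kind {kind!r}")
    cfg = descriptors.assign_leaflets(cfg)
    context["config"] = cfg
    return io.write_frames(cfg, outdir / "membrane")


def _stage_gen_traj(context, params, seed, outdir):
    if "config" not in context:
        raise RuntimeError("gen-traj requires the gen-membrane stage output")
    traj = membrane.generate_trajectory(context["config"],
                                        params.get("n_frames", 10),
                                        params.get("step_sd", 1.0), None, seed)
    context["config"] = traj
    return io.write_frames(traj, outdir / "trajectory")


_MAP_BUILDERS = {
    "thickness": lambda c, g, p: {"thickness": descriptors.thickness_map(c, g)},
    "tilt": lambda c, g, p: {f"tilt_{k}": v for k, v in descriptors.tilt_map(c, g).items()},
    "order": lambda c, g, p: {"order": descriptors.order_parameter_map(c, g)},
    "end_to_end": lambda c, g, p: {"end_to_end": descriptors.end_to_end_map(c, g)},
    "contacts": lambda c, g, p: {"contacts": descriptors.interleaflet_contacts_map(
        c, g, p.get("contact_cutoff", 6.0))},
    "neighbors": lambda c, g, p: {f"neighbors_{k}": v for k, v in
                                  descriptors.neighbor_density_map(
                                      c, g, p.get("neighbor_radius", 15.0)).items()},
    "water": lambda c, g, p: {"water": descriptors.water_penetration_map(c, g)},
}


def _stage_maps(context, params, seed, outdir):
    if "config" not in context:
        raise RuntimeError("maps requires the gen-membrane stage output")
    g = _grid_for(context, params)
    outputs = []
    for name in params.get("descriptors", ["thickness"]):
        if name not in _MAP_BUILDERS:
            raise ValueError(f"unknown descriptor {name!r}")
        for label, m in _MAP_BUILDERS[name](context["config"], g, params).items():
            outputs += list(io.save_map(m, outdir / f"map_{label}"))
    return outputs


def _stage_enrich(context, params, seed, outdir):
    if "config" not in context:
        raise RuntimeError("enrich requires the gen-membrane stage output")
    cfg = context["config"]
    g = _grid_for(context, params)
    occ = enrichment.species_occupancies(cfg, g)
    emap = enrichment.enrichment_map(occ)
    outputs = list(io.save_map(emap, outdir / "map_enrichment"))
    if "anchor" in params:
        a = params["anchor"]
        anchor = membrane.CircularFootprint(tuple(a["center"]), a.get("radius", 0.0),
                                            (cfg.box[0], cfg.box[1]))
        distances = params.get("distances", list(np.arange(5.0, 60.0, 10.0)))
        prof = enrichment.enrichment_profile(occ, anchor, distances,
                                             params.get("width", 10.0))
        outputs.append(io.save_table(prof.table, outdir / "enrichment_profile.tsv"))
    return outputs


def _stage_pb_sim(context, params, seed, outdir):
    pop = photobleach.PopulationSpec(**params.get("population", {}))
    cfg = photobleach.SimConfig(chi=params["chi"], keq=params["keq"],
                                p_label=params.get("p_label", photobleach.DEFAULT_P_LABEL),
                                n_spots=params.get("n_spots", 5000), population=pop)
    res = photobleach.simulate_capture(cfg, seed=seed)
    context["pb_result"] = res
    d = res.distribution
    table = pd.DataFrame([{"label": d.label, "pct_dl": d.pct_dl,
                           "chi_subunits_per_lipid": d.chi,
                           "n1": d.n1, "n2": d.n2, "n3plus": d.n3plus}])
    return [io.save_table(table, outdir / "photobleach.tsv"),
            io.save_json(res.truth, outdir / "photobleach_truth.json")]


def _stage_titration(context, params, seed, outdir):
    pop = photobleach.PopulationSpec(**params.get("population", {}))
    cfg = photobleach.SimConfig(chi=params.get("chi", 1e-6), keq=params["keq0"],
                                n_spots=params.get("n_spots", 5000), population=pop)
    slope = params.get("ddg_slope_per_decade", 0.14)
    dg0 = thermo.free_energy(params["keq0"])
    dl_grid = params.get("dl_grid", [1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 0.1, 1.0])
    ref_log = np.log10(min(dl_grid))

    def keq_of(dl):
        return thermo.keq_from_free_energy(dg0 + slope * (np.log10(dl) - ref_log))

    ds = photobleach.simulate_titration(keq_of, dl_grid, cfg, seed=seed)
    basis = photobleach.simulated_control_basis(cfg, seed=seed + 1)
    rows = []
    for dist in ds.distributions:
        f = thermo.fit_fraction_dimer(dist, basis)
        row = {"pct_dl": dist.pct_dl, "f_dimer": f.f_dimer, "se": f.se}
        if 0 < f.f_dimer < 1:
            keq = thermo.invert_isotherm(f.f_dimer, dist.chi / 2.0)
            row["ddg"] = thermo.delta_delta_g(thermo.free_energy(keq), dg0)[0]
        rows.append(row)
    table = pd.DataFrame(rows)
    fitted = table.dropna(subset=["ddg"]) if "ddg" in table else table.iloc[:0]
    outputs = [io.save_table(table, outdir / "titration.tsv"),
               io.save_json(ds.truth, outdir / "titration_truth.json")]
    if len(fitted) >= 3:
        reg = thermo.fit_linear_ddg(fitted[["pct_dl", "ddg"]].to_numpy(),
                                    "log10_pct_dl")
        outputs.append(io.save_json(reg, outdir / "titration_regression.json"))
    return outputs


def _stage_efflux(context, params, seed, outdir):
    trace = efflux.simulate_efflux(params.get("f0_vol", 0.2),
                                   params.get("k_leak", 1e-3),
                                   params.get("k_p", 0.05),
                                   params.get("t_max", 120.0),
                                   params.get("n_points", 200),
                                   params.get("noise_sd", 0.0), seed)
    fit = efflux.fit_efflux(trace)
    df = pd.DataFrame({"t": trace.time, "value": trace.value})
    path = outdir / "efflux_trace.csv"
    df.to_csv(path, index=False)
    return [path, io.save_json(fit, outdir / "efflux_fit.json")]


_STAGES = {
    "gen-membrane": _stage_gen_membrane,
    "gen-traj": _stage_gen_traj,
    "maps": _stage_maps,
    "enrich": _stage_enrich,
    "pb-sim": _stage_pb_sim,
    "titration": _stage_titration,
    "efflux": _stage_efflux,
}


def run_pipeline(config) -> dict:
    """Execute the configured stages in order; return (and write) the manifest."""
    cfg = load_config(config)
    outdir = Path(cfg.get("outdir", "memsolv_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg.get("seed", 0))
    context: dict = {}
    manifest = {"seed": master_seed, "stages": []}
    for i, stage in enumerate(cfg.get("stages", [])):
        name = stage["name"]
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r}")
        params = {k: v for k, v in stage.items() if k != "name"}
        seed = master_seed * 1000 + i
        t0 = time.perf_counter()
        try:
            outputs = _STAGES[name](context, params, seed, outdir)
        except RuntimeError as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e
        elapsed = time.perf_counter() - t0
        log.info("stage %s finished in %.2f s", name, elapsed)
        manifest["stages"].append({
            "name": name, "params": io._jsonable(params), "seed": seed,
            "elapsed_s": round(elapsed, 4),
            "outputs": {Path(p).name: _sha256(p) for p in outputs},
        })
    io.save_json(manifest, outdir / "manifest.json")
    return manifest
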