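"""End-to-end recovery studies on planted ground truth.

These functions wire the synthetic generators to the estimators and report
how well known, planted parameters are recovered:

* :func:`planted_map_recovery` — a bilayer with a Gaussian thinning defect,
  a tilted annulus around a protein footprint and a localized DL-enrichment
  bump, pushed through the full map/enrichment pipeline;
* :func:`titration_slope_coverage` — simulated photobleaching titrations
  with a log-linear free-energy truth, scored by how often the fitted
  regression's 95% CI covers the true slope;
* :func:`isotherm_recovery` — noisy isotherm fits scored by the median
  free-energy error;
* :func:`efflux_recovery` — noisy efflux traces scored by median relative
  parameter errors.

Study sizes default to desk-scale settings (seconds to a few minutes on one
CPU); all randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import descriptors, efflux, enrichment, grid, membrane, photobleach, thermo


def planted_map_recovery(seed: int = 0, n_replicates: int = 16,
                         box=(160.0, 160.0, 100.0),
                         thinning_depth: float = 8.0, thinning_sigma: float = 15.0,
                         tilt_deg: float = 60.0, dl_bulk: float = 0.2,
                         dl_peak: float = 0.5) -> dict:
    """Recover a planted thinning depth, tilt angle and DL enrichment bump.

    The scenario: a circular protein footprint, a Gaussian thinning well of
    the given depth centered near the footprint edge (on a lattice site, so
    the noise-free minimum is exactly realized), a 60-degree tilt annulus
    hugging the footprint, and a DL-fraction bump co-centered with the
    thinning.  ``n_replicates`` independent species draws are stacked as
    frames to give the enrichment statistics occupancy.
    """
    lx, ly = box[0], box[1]
    fp_center = (80.0, 80.0)
    defect_center = (100.0, 76.0)  # a lattice site of the 20x20 layout
    fp = membrane.CircularFootprint(fp_center, 12.0, (lx, ly))
    tilt_outer_r = 30.0

    def thick(x, y):
        dx = x - defect_center[0] - lx * np.round((x - defect_center[0]) / lx)
        dy = y - defect_center[1] - ly * np.round((y - defect_center[1]) / ly)
        return 38.0 - thinning_depth * np.exp(-(dx**2 + dy**2) / (2 * thinning_sigma**2))

    def tilt(x, y):
        d = np.hypot(x - fp_center[0], y - fp_center[1])
        return np.where(d < tilt_outer_r, tilt_deg, 0.0)

    def dl(x, y):
        dx = x - defect_center[0] - lx * np.round((x - defect_center[0]) / lx)
        dy = y - defect_center[1] - ly * np.round((y - defect_center[1]) / ly)
        return dl_bulk + (dl_peak - dl_bulk) * np.exp(
            -(dx**2 + dy**2) / (2 * thinning_sigma**2))

    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_replicates):
        pf = membrane.PlantedField(thick, tilt, dl, footprint=fp)
        c = membrane.generate_defect_bilayer(pf, 400, box,
                                             seed=int(rng.integers(2**31)))
        frames.append((float(k), c.frame(0)))
    cfg = descriptors.assign_leaflets(membrane.BeadConfiguration(frames, box))
    g = grid.GridSpec.for_box(box)

    tmap = descriptors.thickness_map(cfg, g, occupancy_fraction=0.0)
    thickness_min = tmap.nanmin()

    tilt_maps = descriptors.tilt_map(cfg, g, occupancy_fraction=0.0)
    cx, cy = g.cell_centers()
    d_fp = np.hypot(cx - fp_center[0], cy - fp_center[1])
    ring = tilt_maps["outer"].mask & (d_fp >= 18.0) & (d_fp <= 24.0)
    tilt_recovered = float(np.nanmean(tilt_maps["outer"].values[ring]))
    tilt_inner = float(np.nanmean(tilt_maps["inner"].values[
        tilt_maps["inner"].mask & (d_fp >= 18.0) & (d_fp <= 24.0)]))

    occ = enrichment.species_occupancies(cfg, g)
    anchor = membrane.PointAnchor(defect_center, (lx, ly))
    prof = enrichment.enrichment_profile(
        occ, anchor, [5.0, 15.0, 25.0, 35.0, 45.0, 55.0], width=10.0)
    t = prof.table.set_index("d")["pct_e"]
    return {
        "thickness_min": thickness_min,
        "thinning_depth_recovered": 38.0 - thickness_min,
        "thinning_depth_true": thinning_depth,
        "tilt_recovered_outer": tilt_recovered,
        "tilt_recovered_inner": tilt_inner,
        "tilt_true": tilt_deg,
        "enrichment_profile": t.to_dict(),
        "enrichment_near": float(t.loc[5.0]),
        "enrichment_far": float(t.loc[55.0]),
        "n_replicates": n_replicates,
        "n_lipids": int(len(cfg.lipid_ids())),
    }


def titration_slope_coverage(seed: int = 0, n_replicates: int = 100,
                             n_spots: int = 5000, chi: float = 1e-6,
                             slope_per_decade: float = 0.135,
                             dg_ref: float = -10.4,
                             dl_grid=None) -> dict:
    """Coverage of the log-linear destabilization slope by its fitted 95% CI.

    Truth: DeltaG0(%DL) = dg_ref + slope * (log10(DL) - log10(DL_min)) over
    the sub-1% regime grid, the preferential-solvation linkage regime.  Each
    replicate simulates one titration (plus matched monomer/dimer controls),
    estimates F_Dimer per condition, converts to DeltaDeltaG and fits the
    log-linear regression; a replicate scores when the CI covers the truth.
    """
    if dl_grid is None:
        # the assay's sub-1% regime: 1e-8 ... 1 %DL, one condition per decade
        dl_grid = np.logspace(-8, 0, 9)
    ref_log = np.log10(min(dl_grid))
    keq_ref = thermo.keq_from_free_energy(dg_ref)

    def keq_of(dl):
        return thermo.keq_from_free_energy(dg_ref + slope_per_decade
                                           * (np.log10(dl) - ref_log))

    base = photobleach.SimConfig(chi=chi, keq=keq_ref, n_spots=n_spots)
    rng = np.random.default_rng(seed)
    covered = 0
    slopes = []
    rt = thermo.R_KCAL * thermo.DEFAULT_T
    for _ in range(n_replicates):
        s = int(rng.integers(2**31 - 10))
        ds = photobleach.simulate_titration(keq_of, dl_grid, base, seed=s)
        areas = ds.population.areas
        pts = []
        for dist in ds.distributions:
            # capture-model-calibrated estimate: accounts for liposome
            # co-capture, which biases the plain two-control mixture fit
            f, se_f = photobleach.fit_fraction_dimer_calibrated(
                dist, dist.chi, base.p_label, areas)
            if 0 < f < 1:
                keq = thermo.invert_isotherm(f, dist.chi / 2.0)
                # d(DeltaG)/dF propagated from the sampling se of F
                se_dg = rt * (1.0 / f + 2.0 / (1.0 - f)) * se_f
                pts.append((dist.pct_dl, thermo.free_energy(keq) - dg_ref, se_dg))
        if len(pts) < 3:
            continue
        fit = thermo.fit_linear_ddg(pts, "log10_pct_dl")
        slopes.append(fit.slope)
        lo, hi = fit.ci95_slope
        if lo <= slope_per_decade <= hi:
            covered += 1
    return {
        "coverage_pct": 100.0 * covered / n_replicates,
        "median_slope": float(np.median(slopes)),
        "slope_true": slope_per_decade,
        "n_replicates": n_replicates,
        "n_spots": n_spots,
    }


def isotherm_recovery(seed: int = 0, n_replicates: int = 100,
                      keq_true: float = 4e7, noise_sd: float = 0.05,
                      chi_star_grid=None) -> dict:
    """Median free-energy error of noisy isotherm fits.

    Eight (chi*, F) points spanning the isotherm's dynamic range, Gaussian
    noise of the stated sd on F, free energies compared at 298.15 K.
    """
    if chi_star_grid is None:
        chi_star_grid = np.logspace(-9, -6, 8)
    dg_true = thermo.free_energy(keq_true)
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_replicates):
        f = np.clip(thermo.isotherm(keq_true, chi_star_grid)
                    + rng.normal(0, noise_sd, len(chi_star_grid)), 1e-4, 1 - 1e-4)
        fit = thermo.fit_isotherm(
            np.column_stack([chi_star_grid, f, np.full(len(f), noise_sd)]))
        errs.append(abs(fit.dg - dg_true))
    return {
        "median_abs_dg_error": float(np.median(errs)),
        "dg_true": dg_true,
        "noise_sd": noise_sd,
        "n_replicates": n_replicates,
    }


def efflux_recovery(seed: int = 0, n_replicates: int = 100,
                    f0_vol: float = 0.2, k_leak: float = 1e-3,
                    k_p: float = 0.05, noise_sd: float = 0.01) -> dict:
    """Median relative errors of the efflux-fit parameters on noisy traces."""
    rng = np.random.default_rng(seed)
    errs = {"f0_vol": [], "k_leak": [], "k_p": []}
    for _ in range(n_replicates):
        tr = efflux.simulate_efflux(f0_vol, k_leak, k_p, t_max=300.0,
                                    n_points=300, noise_sd=noise_sd,
                                    seed=int(rng.integers(2**31)))
        fit = efflux.fit_efflux(tr)
        errs["f0_vol"].append(abs(fit.f0_vol - f0_vol) / f0_vol)
        errs["k_leak"].append(abs(fit.k_leak - k_leak) / k_leak)
        errs["k_p"].append(abs(fit.k_p - k_p) / k_p)
    return {f"median_rel_err_{k}": float(np.median(v)) for k, v in errs.items()} | {
        "n_replicates": n_replicates, "noise_sd": noise_sd}
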