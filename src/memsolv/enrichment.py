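"""Preferential-solvation statistics: DL enrichment maps and profiles.

The percent enrichment of the short-chain (DL) species relative to the
long-chain (PO) species at grid cell i is

    %E_i = 100 * [ (rho_DL / rho_PO)_i - (rho_DL / rho_PO)_B ] / (rho_DL / rho_PO)_B

where rho are per-cell occupancy numbers (stamped lipid contributions) and B
is the bulk ratio for the composition, i.e. the ratio expected if both
species were distributed evenly.  The distance-resolved variant sums the
occupancies over the cells of a 10 Å-wide mask at each distance d from the
protein footprint (optionally split into angular interface sectors) before
forming the same ratio-of-ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec, RegionMask, ScalarMap2D, radial_shells, stamp


@dataclass
class OccupancyRatio:
    """Per-cell DL and PO occupancy numbers plus the bulk composition ratio."""

    grid: GridSpec
    rho_dl: np.ndarray
    rho_po: np.ndarray
    bulk_ratio: float
    n_frames: int = 1

    def __post_init__(self):
        if np.any(self.rho_dl < 0) or np.any(self.rho_po < 0):
            raise ValueError("occupancy numbers must be >= 0")


def species_occupancies(config, grid: GridSpec, bulk_from: str = "counts") -> OccupancyRatio:
    """Stamp per-species occupancy fields and compute the bulk DL/PO ratio.

    The bulk ratio defaults to the system's global lipid counts (the preset
    composition); ``bulk_from='occupancy'`` instead uses total stamped
    occupancies (useful for the self-referential whole-domain check).
    """
    accs = {}
    for sp in ("DL", "PO"):
        rows = []
        for f in range(config.n_frames):
            df = config.frame(f)
            ids = df.loc[(df["lipid_id"] >= 0) & (df["species"] == sp), "lipid_id"].unique()
            rows.append(pd.DataFrame({"frame": f, "lipid_id": ids, "value": 1.0}))
        table = pd.concat(rows, ignore_index=True)
        if len(table) == 0:
            accs[sp] = None
            continue
        accs[sp] = stamp(config, table, grid, f"occupancy_{sp}")
    shape = (grid.nx, grid.ny)
    rho_dl = accs["DL"].occupancy.astype(float) if accs["DL"] else np.zeros(shape)
    rho_po = accs["PO"].occupancy.astype(float) if accs["PO"] else np.zeros(shape)
    if bulk_from == "occupancy":
        bulk = rho_dl.sum() / rho_po.sum() if rho_po.sum() > 0 else 0.0
    else:
        n_dl = n_po = 0
        for f in range(config.n_frames):
            counts = config.species_counts(f)
            n_dl += counts.get("DL", 0)
            n_po += counts.get("PO", 0)
        bulk = n_dl / n_po if n_po > 0 else 0.0
    return OccupancyRatio(grid, rho_dl, rho_po, float(bulk), config.n_frames)


def enrichment_map(occ: OccupancyRatio, occupancy_fraction: float = 0.40,
                   exclude: np.ndarray | None = None) -> ScalarMap2D:
    """Per-cell percent enrichment %E_i of DL relative to the bulk ratio.

    Cells with zero PO occupancy, or failing the occupancy-significance
    mask on the combined (DL+PO) occupancy, are masked out.
    """
    if occ.bulk_ratio <= 0:
        raise ValueError("bulk_ratio is zero: the system contains no DL lipids")
    total = occ.rho_dl + occ.rho_po
    touched = total > 0
    consider = touched if exclude is None else (touched & ~exclude)
    mean_occ = total[consider].mean() if consider.any() else 0.0
    mask = touched & (total >= occupancy_fraction * mean_occ) & (occ.rho_po > 0)
    values = np.full(total.shape, np.nan)
    ratio = np.divide(occ.rho_dl, occ.rho_po, out=np.zeros_like(occ.rho_dl),
                      where=occ.rho_po > 0)
    values[mask] = 100.0 * (ratio[mask] - occ.bulk_ratio) / occ.bulk_ratio
    return ScalarMap2D(occ.grid, values, total.astype(np.int64), mask,
                       "pct_enrichment_DL", "%", "both", occ.n_frames)


@dataclass
class SectorAssignment:
    """Named angular sectors about the footprint centroid."""

    grid: GridSpec
    labels: np.ndarray        # int per cell; -1 inside the footprint
    names: list[str]

    def mask(self, name: str) -> RegionMask:
        k = self.names.index(name)
        return RegionMask(self.grid, self.labels == k, provenance=f"sector {name}")


def interface_sectors(footprint, grid: GridSpec, dimer_axis_deg: float,
                      sector_angles: list[tuple[str, float]] | None = None) -> SectorAssignment:
    """Partition non-footprint cells into angular sectors about the centroid.

    ``sector_angles`` is a list of (name, width°) that must cover 360°; the
    first sector is centered on ``dimer_axis_deg`` (the in-plane direction
    perpendicular to the dimerization interface).  Default: three 120°
    sectors named dimer / interface2 / interface3.
    """
    if sector_angles is None:
        sector_angles = [("dimer", 120.0), ("interface2", 120.0), ("interface3", 120.0)]
    widths = [w for _, w in sector_angles]
    if not np.isclose(sum(widths), 360.0):
        raise ValueError(f"sector angles must cover 360 degrees, got {sum(widths)}")
    cx, cy = grid.cell_centers()
    fx, fy = footprint.center
    lx, ly = grid.lx, grid.ly
    dx = cx - fx - lx * np.round((cx - fx) / lx)
    dy = cy - fy - ly * np.round((cy - fy) / ly)
    ang = np.degrees(np.arctan2(dy, dx))
    # angle measured from the dimer axis, folded to [0, 360)
    rel = np.mod(ang - dimer_axis_deg + widths[0] / 2.0, 360.0)
    bounds = np.cumsum([0.0] + widths)
    labels = np.digitize(rel, bounds[1:-1]).astype(int)
    inside = np.asarray(footprint.contains(cx, cy), bool)
    labels[inside] = -1
    return SectorAssignment(grid, labels, [n for n, _ in sector_angles])


@dataclass
class EnrichmentProfile:
    """Distance-resolved %E per interface sector, as a tidy table."""

    table: pd.DataFrame  # columns: sector, d, pct_e, n_cells, rho_dl, rho_po
    bulk_ratio: float
    mode: str = "sliding"

    def sector(self, name: str) -> pd.DataFrame:
        return self.table[self.table["sector"] == name].reset_index(drop=True)


def enrichment_profile(occ: OccupancyRatio, anchor, distances,
                       width: float = 10.0,
                       sectors: SectorAssignment | None = None,
                       mode: str = "sliding") -> EnrichmentProfile:
    """%E_d per distance shell (and per sector), combining both leaflets.

    ``mode='sliding'`` uses independent masks of the given width centered at
    each distance; ``mode='cumulative'`` uses shells of increasing width
    (everything closer than d + width/2).  Bins whose shell∩sector holds no
    occupancy are reported as missing (NaN).
    """
    if occ.bulk_ratio <= 0:
        raise ValueError("bulk_ratio is zero: the system contains no DL lipids")
    shells = radial_shells(anchor, occ.grid, distances, width)
    if mode == "cumulative":
        from .grid import distance_to_anchor
        dist = distance_to_anchor(occ.grid, anchor)
        cx, cy = occ.grid.cell_centers()
        inside = np.asarray(anchor.contains(cx, cy), bool) if hasattr(anchor, "contains") \
            else np.zeros_like(dist, bool)
        shells = [RegionMask(occ.grid, (~inside) & (dist < d + width / 2.0),
                             provenance=f"cumulative d<{d + width / 2.0}")
                  for d in distances]
    elif mode != "sliding":
        raise ValueError(f"unknown mode {mode!r}")
    sector_items = ([("all", None)] if sectors is None
                    else [(n, sectors.labels == k) for k, n in enumerate(sectors.names)])
    rows = []
    for name, sector_cells in sector_items:
        for d, shell in zip(distances, shells):
            cells = shell.cells if sector_cells is None else (shell.cells & sector_cells)
            sdl, spo = occ.rho_dl[cells].sum(), occ.rho_po[cells].sum()
            if spo > 0 and sdl + spo > 0:
                pct = 100.0 * ((sdl / spo) - occ.bulk_ratio) / occ.bulk_ratio
            else:
                pct = np.nan
            rows.append((name, float(d), pct, int(cells.sum()), sdl, spo))
    table = pd.DataFrame(rows, columns=["sector", "d", "pct_e", "n_cells",
                                        "rho_dl", "rho_po"])
    return EnrichmentProfile(table, occ.bulk_ratio, mode)
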