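"""Grid machinery for 2D membrane maps.

Per-lipid descriptor values are "stamped" onto an x-y grid: a value is added
to every cell whose center lies within the stamp radius (the ester bead's
van der Waals radius) of either of the lipid's two ester beads — the union,
with no double counting.  Occupancy (how often each cell received any datum)
is accumulated identically and drives the statistical-significance mask:
after time-averaging, cells with occupancy below a fraction (default 40%) of
the mean occupancy over touched cells are masked out.

Also provides distance-shell masks around a protein footprint and a plain 3D
number-density histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

MASK_SENTINEL = -9999.0  # CSV missing-value convention, declared in JSON headers


@dataclass(frozen=True)
class GridSpec:
    """Square-cell grid tiling the periodic box.

    The nominal ``cell_edge`` (default 1 Å) is adjusted per axis so an
    integer number of cells tiles the box exactly; ``stamp_radius`` is the
    ester-bead van der Waals radius used for stamping.
    """

    lx: float
    ly: float
    cell_edge: float = 1.0
    stamp_radius: float = 2.6

    def __post_init__(self):
        if self.cell_edge <= 0:
            raise ValueError(f"cell_edge must be positive, got {self.cell_edge}")
        if self.stamp_radius < 0:
            raise ValueError(f"stamp_radius must be >= 0, got {self.stamp_radius}")
        if self.lx <= 0 or self.ly <= 0:
            raise ValueError("grid extents must be positive")

    @classmethod
    def for_box(cls, box: Sequence[float], cell_edge: float = 1.0,
                stamp_radius: float = 2.6) -> "GridSpec":
        return cls(float(box[0]), float(box[1]), cell_edge, stamp_radius)

    @property
    def nx(self) -> int:
        return max(int(round(self.lx / self.cell_edge)), 1)

    @property
    def ny(self) -> int:
        return max(int(round(self.ly / self.cell_edge)), 1)

    @property
    def hx(self) -> float:
        return self.lx / self.nx

    @property
    def hy(self) -> float:
        return self.ly / self.ny

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (nx, ny) with the cell-center coordinates."""
        xs = (np.arange(self.nx) + 0.5) * self.hx
        ys = (np.arange(self.ny) + 0.5) * self.hy
        return np.meshgrid(xs, ys, indexing="ij")

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        i = np.mod(np.floor(np.asarray(x, float) / self.hx).astype(int), self.nx)
        j = np.mod(np.floor(np.asarray(y, float) / self.hy).astype(int), self.ny)
        return i, j


@dataclass
class MapAccumulator:
    """Per-cell running sum and occupancy produced by :func:`stamp`."""

    grid: GridSpec
    value_sum: np.ndarray
    occupancy: np.ndarray
    n_frames: int
    descriptor_name: str = ""
    units: str = ""

    def merge(self, other: "MapAccumulator") -> "MapAccumulator":
        if other.grid != self.grid:
            raise ValueError("cannot merge accumulators on different grids")
        return MapAccumulator(self.grid, self.value_sum + other.value_sum,
                              self.occupancy + other.occupancy,
                              self.n_frames + other.n_frames,
                              self.descriptor_name, self.units)


@dataclass
class ScalarMap2D:
    """Occupancy-weighted, masked, time-averaged 2D map of a descriptor.

    ``values`` holds NaN on masked cells; ``mask`` is True where the cell is
    statistically significant (occupancy above the threshold fraction of the
    mean occupancy over touched cells).
    """

    grid: GridSpec
    values: np.ndarray
    occupancy: np.ndarray
    mask: np.ndarray
    descriptor_name: str = ""
    units: str = ""
    leaflet_scope: str = "both"
    n_frames: int = 1
    meta: dict = field(default_factory=dict)

    def unmasked_values(self) -> np.ndarray:
        return self.values[self.mask]

    def value_at(self, x: float, y: float) -> float:
        i, j = self.grid.cell_index(x, y)
        return float(self.values[i, j])

    def nanmin(self) -> float:
        return float(np.nanmin(self.values))

    def nanmean(self) -> float:
        return float(np.nanmean(self.values))


@dataclass
class RegionMask:
    """Boolean cell selection with provenance (shell bounds, sector id, ...)."""

    grid: GridSpec
    cells: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        if self.cells.shape != (self.grid.nx, self.grid.ny):
            raise ValueError("RegionMask shape does not match grid extents")

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())


def _stamp_cells(grid: GridSpec, px: np.ndarray, py: np.ndarray):
    """Candidate (point_index, i, j) triples for cells stamped by each point.

    A cell is stamped when its center lies within ``stamp_radius`` of the
    point, or when it contains the point (so a zero radius still lands in
    the containing cell).
    """
    r = grid.stamp_radius
    mi = int(np.floor(r / grid.hx)) + 1
    mj = int(np.floor(r / grid.hy)) + 1
    di, dj = np.meshgrid(np.arange(-mi, mi + 1), np.arange(-mj, mj + 1), indexing="ij")
    di, dj = di.ravel(), dj.ravel()

    i0 = np.floor(px / grid.hx).astype(int)
    j0 = np.floor(py / grid.hy).astype(int)
    ii = i0[:, None] + di[None, :]
    jj = j0[:, None] + dj[None, :]
    cx = (ii + 0.5) * grid.hx
    cy = (jj + 0.5) * grid.hy
    within = (cx - px[:, None]) ** 2 + (cy - py[:, None]) ** 2 <= r * r
    within[:, (di == 0) & (dj == 0)] = True  # containing cell always stamped
    pt = np.broadcast_to(np.arange(px.size)[:, None], within.shape)[within]
    return pt, np.mod(ii[within], grid.nx), np.mod(jj[within], grid.ny)


def stamp(config, per_lipid_values: pd.DataFrame, grid: GridSpec,
          descriptor_name: str = "", units: str = "") -> MapAccumulator:
    """Stamp per-(frame, lipid) values onto the grid via the ester beads.

    ``per_lipid_values`` needs columns ``frame`` (index into config.frames),
    ``lipid_id`` and ``value``.  Each datum is added once to every cell whose
    center falls within the stamp radius of the x-y position of either GL1 or
    GL2 (union of the two disks); occupancy is incremented identically.
    Periodic wrapping in x and y is respected.
    """
    vsum = np.zeros((grid.nx, grid.ny))
    occ = np.zeros((grid.nx, grid.ny), dtype=np.int64)
    frames_used = sorted(set(int(f) for f in per_lipid_values["frame"]))
    for f in frames_used:
        sub = per_lipid_values[per_lipid_values["frame"] == f]
        df = config.frame(f)
        est = df[df["role"] == "ester"]
        known = set(est["lipid_id"].unique())
        missing = set(sub["lipid_id"]) - known
        if missing:
            raise KeyError(f"value table references unknown lipid ids {sorted(missing)} in frame {f}")
        pos = est.set_index(["lipid_id", "tail_index"])[["x", "y"]]
        lids = sub["lipid_id"].to_numpy()
        vals = sub["value"].to_numpy(float)
        g1 = pos.loc[[(l, 0) for l in lids]].to_numpy()
        g2 = pos.loc[[(l, 1) for l in lids]].to_numpy()
        pts = np.vstack([g1, g2])  # 2M x 2; datum m owns rows m and m+M
        pt, ci, cj = _stamp_cells(grid, pts[:, 0], pts[:, 1])
        datum = np.mod(pt, lids.size)  # map GL2 rows back onto their datum
        # union of the two ester disks: drop duplicate (datum, cell) pairs
        key = (datum.astype(np.int64) * grid.nx + ci) * grid.ny + cj
        _, keep = np.unique(key, return_index=True)
        datum, ci, cj = datum[keep], ci[keep], cj[keep]
        np.add.at(vsum, (ci, cj), vals[datum])
        np.add.at(occ, (ci, cj), 1)
    return MapAccumulator(grid, vsum, occ, len(frames_used), descriptor_name, units)


def finalize(acc: MapAccumulator, occupancy_fraction: float = 0.40,
             exclude: np.ndarray | None = None, leaflet_scope: str = "both") -> ScalarMap2D:
    """Average the accumulator and apply the occupancy-significance mask.

    A cell is significant when its occupancy is at least
    ``occupancy_fraction`` times the mean occupancy, the mean taken over
    cells with occupancy > 0 (optionally excluding cells under ``exclude``,
    e.g. the protein footprint, which would deflate the mean).
    """
    if acc.occupancy.sum() == 0:
        raise ValueError("empty accumulator: nothing was stamped")
    touched = acc.occupancy > 0
    consider = touched if exclude is None else (touched & ~exclude)
    mean_occ = acc.occupancy[consider].mean() if consider.any() else 0.0
    mask = touched & (acc.occupancy >= occupancy_fraction * mean_occ)
    if not mask.any():
        warnings.warn("all cells fall below the occupancy threshold; map fully masked")
    values = np.full(acc.occupancy.shape, np.nan)
    values[mask] = acc.value_sum[mask] / acc.occupancy[mask]
    return ScalarMap2D(acc.grid, values, acc.occupancy.copy(), mask,
                       acc.descriptor_name, acc.units, leaflet_scope, acc.n_frames)


def distance_to_anchor(grid: GridSpec, anchor) -> np.ndarray:
    """Per-cell periodic-aware planar distance to a footprint boundary/anchor.

    ``anchor`` must expose ``boundary_distance(x, y)`` (0 inside a footprint);
    footprints additionally expose ``contains``.
    """
    cx, cy = grid.cell_centers()
    return np.asarray(anchor.boundary_distance(cx, cy), float)


def radial_shells(anchor, grid: GridSpec, distances: Sequence[float],
                  width: float = 10.0) -> list[RegionMask]:
    """Distance shells: cells whose boundary distance lies in [d−w/2, d+w/2).

    Cells inside the footprint itself are never selected.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if any(d < 0 for d in distances):
        raise ValueError("shell distances must be >= 0")
    dist = distance_to_anchor(grid, anchor)
    cx, cy = grid.cell_centers()
    inside = np.asarray(anchor.contains(cx, cy), bool) if hasattr(anchor, "contains") \
        else np.zeros_like(dist, bool)
    if inside.all():
        raise ValueError("footprint covers the whole grid")
    shells = []
    for d in distances:
        lo, hi = d - width / 2.0, d + width / 2.0
        cells = (~inside) & (dist >= lo) & (dist < hi)
        shells.append(RegionMask(grid, cells, provenance=f"shell d={d} width={width}"))
    return shells


def density3d(config, selection: Callable[[pd.DataFrame], np.ndarray] | dict,
              voxel: float, near_protein: float | None = None,
              footprint=None, z_extent: float | None = None) -> tuple[np.ndarray, dict]:
    """Time-averaged 3D number density (Å⁻³) of selected beads.

    ``selection`` is either a predicate on a frame table returning a boolean
    row mask, or a dict of column -> allowed value(s) (e.g.
    ``{"role": "ester"}`` or ``{"species": "DL"}``).  With ``near_protein``,
    beads farther than that planar cutoff from ``footprint`` are excluded.
    Returns (density array, header dict with edges).
    """
    if voxel <= 0:
        raise ValueError("voxel must be positive")
    lx, ly, lz = config.box
    if z_extent is None:
        z_extent = lz
    nx, ny, nz = (max(int(round(l / voxel)), 1) for l in (lx, ly, z_extent))
    edges = [np.linspace(0, lx, nx + 1), np.linspace(0, ly, ny + 1),
             np.linspace(-z_extent / 2, z_extent / 2, nz + 1)]
    counts = np.zeros((nx, ny, nz))
    total = 0
    for _, df in config.frames:
        if callable(selection):
            m = np.asarray(selection(df), bool)
        else:
            m = np.ones(len(df), bool)
            for col, val in selection.items():
                allowed = [val] if np.isscalar(val) or isinstance(val, str) else list(val)
                m &= df[col].isin(allowed).to_numpy()
        sub = df[m]
        if near_protein is not None:
            if footprint is None:
                raise ValueError("near_protein requires a footprint")
            d = footprint.boundary_distance(sub["x"].to_numpy(), sub["y"].to_numpy())
            sub = sub[np.asarray(d) <= near_protein]
        total += len(sub)
        h, _ = np.histogramdd(sub[["x", "y", "z"]].to_numpy(), bins=edges)
        counts += h
    if total == 0:
        warnings.warn("empty selection: 3D density is all zero")
    vx = (lx / nx) * (ly / ny) * (z_extent / nz)
    density = counts / (vx * config.n_frames)
    header = {"edges": [e.tolist() for e in edges], "voxel_volume": vx,
              "n_frames": config.n_frames}
    return density, header
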