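"""Synthetic coarse-grained bilayer generator with planted ground truth.

Builds bead configurations that look like coarse-grained (MARTINI-granularity)
two-species bilayers: each lipid has one headgroup bead, two ester beads
(GL1/GL2) and two acyl tails of chain beads.  The generator can plant a
spatially varying thickness field (e.g. a Gaussian thinning defect), a tilt
field, and a local species-ratio field, and can exclude lipids from a
protein-footprint region — so every downstream map and enrichment statistic
can be checked against known truth without running molecular dynamics.

Internal units are Angstrom throughout.  The bilayer midplane sits at z = 0;
x and y are periodic over the box, z is free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

#: lateral half-offset of the two ester beads from the lipid axis (Å)
ESTER_HALF_SPACING = 1.25
#: headgroup bead height above the ester midpoint, along the lipid axis (Å)
HEADGROUP_OFFSET = 3.0
#: spacing between consecutive chain beads along the tail axis (Å)
CHAIN_BEAD_SPACING = 3.0

FRAME_COLUMNS = [
    "lipid_id", "species", "role", "bead", "tail_index", "chain_pos",
    "leaflet", "x", "y", "z",
]


@dataclass(frozen=True)
class LipidSpec:
    """Bead roster and nominal geometry of one lipid species.

    ``bead_roster`` is an ordered list of (bead_name, role, tail_index,
    chain_pos); ester beads GL1/GL2 anchor tails 0 and 1 respectively.
    """

    species_label: str
    n_chain_beads_per_tail: int

    def __post_init__(self):
        if self.species_label not in ("PO", "DL"):
            raise ValueError(f"species_label must be 'PO' or 'DL', got {self.species_label!r}")
        if self.n_chain_beads_per_tail < 2:
            raise ValueError("each tail needs at least 2 chain beads")

    @property
    def nominal_tail_length(self) -> float:
        """Tail length in Å (chain beads equally spaced below the ester plane)."""
        return self.n_chain_beads_per_tail * CHAIN_BEAD_SPACING

    @property
    def bead_roster(self) -> list[tuple[str, str, int, int]]:
        roster = [("NH3", "headgroup", -1, 0), ("GL1", "ester", 0, 0), ("GL2", "ester", 1, 0)]
        for tail, suffix in ((0, "A"), (1, "B")):
            for k in range(1, self.n_chain_beads_per_tail + 1):
                roster.append((f"C{k}{suffix}", "chain", tail, k))
        return roster


PO_SPEC = LipidSpec("PO", 5)
DL_SPEC = LipidSpec("DL", 3)
SPECS = {"PO": PO_SPEC, "DL": DL_SPEC}


@dataclass(frozen=True)
class CircularFootprint:
    """Disk-shaped protein stand-in in the membrane plane."""

    center: tuple[float, float]
    radius: float
    box: tuple[float, float] | None = None  # (Lx, Ly) for periodic distance

    def _delta(self, x, y):
        dx = np.asarray(x, float) - self.center[0]
        dy = np.asarray(y, float) - self.center[1]
        if self.box is not None:
            lx, ly = self.box[0], self.box[1]
            dx -= lx * np.round(dx / lx)
            dy -= ly * np.round(dy / ly)
        return dx, dy

    def contains(self, x, y):
        dx, dy = self._delta(x, y)
        return np.hypot(dx, dy) <= self.radius

    def boundary_distance(self, x, y):
        """Planar distance to the footprint boundary; 0 inside."""
        dx, dy = self._delta(x, y)
        return np.maximum(np.hypot(dx, dy) - self.radius, 0.0)

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)


@dataclass(frozen=True)
class PointAnchor:
    """Zero-area anchor: distances are measured to the point itself."""

    center: tuple[float, float]
    box: tuple[float, float] | None = None

    def contains(self, x, y):
        return np.zeros(np.shape(np.asarray(x, float)), dtype=bool)

    def boundary_distance(self, x, y):
        dx = np.asarray(x, float) - self.center[0]
        dy = np.asarray(y, float) - self.center[1]
        if self.box is not None:
            lx, ly = self.box[0], self.box[1]
            dx -= lx * np.round(dx / lx)
            dy -= ly * np.round(dy / ly)
        return np.hypot(dx, dy)


@dataclass
class PlantedField:
    """Ground-truth fields the defect generator realizes.

    Each field is a callable (x, y) -> value evaluated at the lipid's lateral
    position; scalars are promoted to constant fields.  ``water_slab`` is a
    number density (Å^-3) of water beads placed outside the acyl core.
    """

    thickness_field: Callable[[np.ndarray, np.ndarray], np.ndarray] | float
    tilt_field: Callable[[np.ndarray, np.ndarray], np.ndarray] | float = 0.0
    dl_fraction_field: Callable[[np.ndarray, np.ndarray], np.ndarray] | float = 0.0
    footprint: CircularFootprint | None = None
    water_slab: float = 0.0

    @staticmethod
    def _as_field(f):
        if callable(f):
            return f
        return lambda x, y, _v=float(f): np.full_like(np.asarray(x, float), _v)

    def evaluate(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        t = np.asarray(self._as_field(self.thickness_field)(x, y), float)
        tilt = np.asarray(self._as_field(self.tilt_field)(x, y), float)
        dl = np.asarray(self._as_field(self.dl_fraction_field)(x, y), float)
        if np.any(t <= 0):
            raise ValueError("thickness_field must be positive everywhere sampled")
        if np.any((tilt < 0) | (tilt > 90)):
            raise ValueError("tilt_field must lie in [0, 90] degrees")
        if np.any((dl < 0) | (dl > 1)):
            raise ValueError("dl_fraction_field must lie in [0, 1]")
        return t, tilt, dl


@dataclass
class BeadConfiguration:
    """Frames of labeled beads plus box dimensions (Å).

    Each frame is ``(time, table)`` where the table has one row per bead with
    columns ``lipid_id, species, role, bead, tail_index, chain_pos, leaflet,
    x, y, z``.  Water beads carry ``lipid_id = -1`` and ``role = 'water'``.
    """

    frames: list[tuple[float, pd.DataFrame]]
    box: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(edge <= 0 for edge in self.box):
            raise ValueError(f"box edges must be positive, got {self.box}")
        for t, df in self.frames:
            if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
                raise ValueError("non-finite bead position encountered")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, i: int = 0) -> pd.DataFrame:
        return self.frames[i][1]

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.frames])

    def lipid_ids(self) -> np.ndarray:
        df = self.frame(0)
        return np.unique(df.loc[df["lipid_id"] >= 0, "lipid_id"].to_numpy())

    def species_counts(self, frame: int = 0) -> dict[str, int]:
        df = self.frame(frame)
        lip = df[df["lipid_id"] >= 0].drop_duplicates("lipid_id")
        return lip["species"].value_counts().to_dict()

    def copy(self) -> "BeadConfiguration":
        return BeadConfiguration(
            [(t, df.copy()) for t, df in self.frames], tuple(self.box), dict(self.meta)
        )


def _rotation_from_tilt(tilt_deg: float, azimuth_rad: float) -> np.ndarray:
    """Rotation matrix tilting the lipid axis by ``tilt_deg`` about a
    horizontal axis whose direction is set by ``azimuth_rad``."""
    th = np.deg2rad(tilt_deg)
    ux, uy = np.cos(azimuth_rad), np.sin(azimuth_rad)
    c, s = np.cos(th), np.sin(th)
    # Rodrigues for unit axis (ux, uy, 0)
    return np.array([
        [c + ux * ux * (1 - c), ux * uy * (1 - c), uy * s],
        [ux * uy * (1 - c), c + uy * uy * (1 - c), -ux * s],
        [-uy * s, ux * s, c],
    ])


def _lipid_offsets(spec: LipidSpec, leaflet_sign: int) -> tuple[list, np.ndarray]:
    """Bead offsets relative to the ester midpoint for an untilted lipid.

    ``leaflet_sign`` is +1 for the outer leaflet (headgroup up, tails down).
    """
    s = leaflet_sign
    rows, offs = [], []
    for bead, role, tail, chain_pos in spec.bead_roster:
        if role == "headgroup":
            off = (0.0, 0.0, s * HEADGROUP_OFFSET)
        elif role == "ester":
            off = ((-ESTER_HALF_SPACING if tail == 0 else ESTER_HALF_SPACING), 0.0, 0.0)
        else:  # chain
            xoff = -ESTER_HALF_SPACING if tail == 0 else ESTER_HALF_SPACING
            off = (xoff, 0.0, -s * chain_pos * CHAIN_BEAD_SPACING)
        rows.append((bead, role, tail, chain_pos))
        offs.append(off)
    return rows, np.array(offs)


def _leaflet_lattice(n: int, lx: float, ly: float) -> np.ndarray:
    """First ``n`` sites of a near-square lattice tiling the periodic box."""
    nx = int(np.ceil(np.sqrt(n * lx / ly)))
    ny = int(np.ceil(n / nx))
    xs = (np.arange(nx) + 0.5) * (lx / nx)
    ys = (np.arange(ny) + 0.5) * (ly / ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])[:n]


def _build_lipids(sites_per_leaflet, thickness_at, tilt_at, dl_at, rng,
                  positional_noise, footprint, lipid_id_start=0):
    """Shared core of the flat and defect generators.

    ``thickness_at``/``tilt_at``/``dl_at`` are arrays aligned with the
    concatenated outer+inner site list.
    """
    records = []
    lid = lipid_id_start
    idx = 0
    for leaflet, sign, sites in (("outer", 1, sites_per_leaflet[0]),
                                 ("inner", -1, sites_per_leaflet[1])):
        for (x0, y0) in sites:
            t_loc = thickness_at[idx]
            tilt_loc = tilt_at[idx]
            dl_loc = dl_at[idx]
            idx += 1
            if footprint is not None and bool(footprint.contains(x0, y0)):
                continue
            species = "DL" if rng.random() < dl_loc else "PO"
            spec = SPECS[species]
            rows, offs = _lipid_offsets(spec, sign)
            if tilt_loc != 0.0:
                rot = _rotation_from_tilt(tilt_loc, rng.uniform(0, 2 * np.pi))
                offs = offs @ rot.T
            center = np.array([x0, y0, sign * t_loc / 2.0])
            if positional_noise > 0:
                center = center + rng.normal(0.0, positional_noise, size=3)
            pos = center + offs
            for (bead, role, tail, chain_pos), p in zip(rows, pos):
                records.append((lid, species, role, bead, tail, chain_pos, leaflet,
                                p[0], p[1], p[2]))
            lid += 1
    return records, lid


def _records_to_frame(records, box) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=FRAME_COLUMNS)
    # wrap laterally into the periodic box
    df["x"] = np.mod(df["x"], box[0])
    df["y"] = np.mod(df["y"], box[1])
    return df


def _water_records(rng, box, z_exclude_half: float, density: float):
    lx, ly, lz = box
    zlo, zhi = -lz / 2.0, lz / 2.0
    slab = max((zhi - z_exclude_half) + (-z_exclude_half - zlo), 0.0)
    n = rng.poisson(density * lx * ly * slab)
    if n == 0:
        return []
    x = rng.uniform(0, lx, n)
    y = rng.uniform(0, ly, n)
    # sample z uniformly over the two outside slabs
    upper = rng.random(n) < (zhi - z_exclude_half) / slab
    z = np.where(upper,
                 rng.uniform(z_exclude_half, zhi, n),
                 rng.uniform(zlo, -z_exclude_half, n))
    return [(-1, "W", "water", "W", -1, 0, "n/a", xi, yi, zi)
            for xi, yi, zi in zip(x, y, z)]


def generate_flat_bilayer(n_lipids_per_leaflet: int, dl_fraction: float,
                          thickness: float, box: Sequence[float] | None = None,
                          positional_noise: float = 0.0, seed: int = 0,
                          water_density: float = 0.0) -> BeadConfiguration:
    """Generate a flat two-species bilayer with ester planes at ±thickness/2.

    Species are assigned by independent Bernoulli(dl_fraction) draws; lipid
    axes are perpendicular to the membrane plane.  ``positional_noise`` is the
    σ of isotropic Gaussian noise added to each lipid's position, so at noise
    0 the ester planes sit exactly at ±thickness/2.
    """
    if thickness <= 0:
        raise ValueError(f"thickness must be positive, got {thickness}")
    if not 0 <= dl_fraction <= 1:
        raise ValueError(f"dl_fraction must be in [0, 1], got {dl_fraction}")
    if n_lipids_per_leaflet < 4:
        raise ValueError("n_lipids_per_leaflet must be >= 4")
    if positional_noise < 0:
        raise ValueError(f"positional_noise must be >= 0, got {positional_noise}")
    if box is None:
        # ~64 Å² of lateral area per lipid keeps lattice spacing realistic
        edge = np.sqrt(n_lipids_per_leaflet * 64.0)
        box = (edge, edge, thickness + 60.0)
    if any(edge <= 0 for edge in box):
        raise ValueError(f"box edges must be positive, got {tuple(box)}")
    box = tuple(float(b) for b in box)

    rng = np.random.default_rng(seed)
    sites = _leaflet_lattice(n_lipids_per_leaflet, box[0], box[1])
    n2 = 2 * n_lipids_per_leaflet
    records, _ = _build_lipids(
        (sites, sites.copy()),
        thickness_at=np.full(n2, float(thickness)),
        tilt_at=np.zeros(n2),
        dl_at=np.full(n2, float(dl_fraction)),
        rng=rng, positional_noise=positional_noise, footprint=None,
    )
    if water_density > 0:
        records += _water_records(rng, box, thickness / 2.0 + HEADGROUP_OFFSET + 1.0,
                                  water_density)
    df = _records_to_frame(records, box)
    meta = {"generator": "flat", "seed": seed, "thickness": thickness,
            "dl_fraction": dl_fraction, "positional_noise": positional_noise}
    return BeadConfiguration([(0.0, df)], box, meta)


def generate_defect_bilayer(planted: PlantedField, n_lipids_per_leaflet: int,
                            box: Sequence[float], positional_noise: float = 0.0,
                            seed: int = 0) -> BeadConfiguration:
    """Generate a bilayer realizing planted thickness/tilt/species fields.

    Local ester-plane separation follows ``planted.thickness_field``; lipid
    axes are tilted by ``planted.tilt_field`` with uniformly random azimuth;
    species are drawn per-position from ``planted.dl_fraction_field``.  No
    lipid ester midpoint is placed inside the footprint.
    """
    if any(edge <= 0 for edge in box):
        raise ValueError(f"box edges must be positive, got {tuple(box)}")
    if positional_noise < 0:
        raise ValueError(f"positional_noise must be >= 0, got {positional_noise}")
    box = tuple(float(b) for b in box)
    rng = np.random.default_rng(seed)
    sites = _leaflet_lattice(n_lipids_per_leaflet, box[0], box[1])
    all_sites = np.vstack([sites, sites])
    t, tilt, dl = planted.evaluate(all_sites[:, 0], all_sites[:, 1])
    records, _ = _build_lipids(
        (sites, sites.copy()), thickness_at=t, tilt_at=tilt, dl_at=dl,
        rng=rng, positional_noise=positional_noise, footprint=planted.footprint,
    )
    if planted.water_slab > 0:
        t_max = float(np.max(t))
        records += _water_records(rng, box, t_max / 2.0 + HEADGROUP_OFFSET + 1.0,
                                  planted.water_slab)
    df = _records_to_frame(records, box)
    meta = {"generator": "defect", "seed": seed, "positional_noise": positional_noise}
    return BeadConfiguration([(0.0, df)], box, meta)


def add_interior_water(config: BeadConfiguration, x: float, y: float, n: int,
                       z_range: tuple[float, float], frame: int | None = None,
                       spread: float = 0.0, seed: int = 0) -> BeadConfiguration:
    """Return a copy with ``n`` water beads planted in a vertical column.

    Used to plant known water-penetration ground truth inside the acyl core.
    Beads are placed at lateral position (x, y) (± ``spread``) with z drawn
    uniformly from ``z_range``; applied to all frames unless ``frame`` given.
    """
    out = config.copy()
    rng = np.random.default_rng(seed)
    targets = range(out.n_frames) if frame is None else [frame]
    for i in targets:
        t, df = out.frames[i]
        z = rng.uniform(z_range[0], z_range[1], n)
        xs = np.mod(x + (rng.normal(0, spread, n) if spread > 0 else np.zeros(n)),
                    out.box[0])
        ys = np.mod(y + (rng.normal(0, spread, n) if spread > 0 else np.zeros(n)),
                    out.box[1])
        rows = pd.DataFrame(
            [(-1, "W", "water", "W", -1, 0, "n/a", xi, yi, zi)
             for xi, yi, zi in zip(xs, ys, z)],
            columns=FRAME_COLUMNS)
        out.frames[i] = (t, pd.concat([df, rows], ignore_index=True))
    return out


def generate_trajectory(config: BeadConfiguration, n_frames: int,
                        step_sd: float, region_bias: dict | None = None,
                        seed: int = 0) -> BeadConfiguration:
    """Evolve lipids by lateral Gaussian random walks with periodic wrapping.

    Roster geometry is preserved (whole-lipid displacement).  ``region_bias``
    optionally makes one species accumulate in a region: a dict with keys
    ``region`` (object with a ``contains(x, y)`` method), ``species`` and
    ``strength`` in [0, 1] — proposed steps that would take a biased lipid
    out of the region are rejected with probability ``strength``.

    Frame times increase by 1 per step; the input frame is frame 0.
    ``n_frames`` counts the total number of frames returned.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if step_sd < 0:
        raise ValueError(f"step_sd must be >= 0, got {step_sd}")
    rng = np.random.default_rng(seed)
    t0, df0 = config.frames[-1]
    lx, ly = config.box[0], config.box[1]
    frames = [(t0, df0.copy())]
    cur = df0
    lipid_ids = np.unique(cur.loc[cur["lipid_id"] >= 0, "lipid_id"].to_numpy())
    for k in range(1, n_frames):
        nxt = cur.copy()
        if step_sd > 0:
            is_lipid = nxt["lipid_id"].to_numpy() >= 0
            steps = rng.normal(0.0, step_sd, size=(lipid_ids.size, 2))
            if region_bias is not None:
                reg = region_bias["region"]
                sp = region_bias.get("species", "DL")
                strength = float(region_bias.get("strength", 1.0))
                # ester midpoints of biased lipids before the step
                est = cur[(cur["role"] == "ester")].groupby("lipid_id")[["x", "y"]].mean()
                species = cur[cur["lipid_id"] >= 0].drop_duplicates("lipid_id").set_index("lipid_id")["species"]
                for i, lid in enumerate(lipid_ids):
                    if species.loc[lid] != sp:
                        continue
                    x0, y0 = est.loc[lid, "x"], est.loc[lid, "y"]
                    if not bool(reg.contains(x0, y0)):
                        continue
                    x1 = np.mod(x0 + steps[i, 0], lx)
                    y1 = np.mod(y0 + steps[i, 1], ly)
                    if not bool(reg.contains(x1, y1)) and rng.random() < strength:
                        steps[i] = 0.0
            disp = pd.DataFrame(steps, index=lipid_ids, columns=["dx", "dy"])
            dx = nxt.loc[is_lipid, "lipid_id"].map(disp["dx"]).to_numpy()
            dy = nxt.loc[is_lipid, "lipid_id"].map(disp["dy"]).to_numpy()
            nxt.loc[is_lipid, "x"] = np.mod(nxt.loc[is_lipid, "x"].to_numpy() + dx, lx)
            nxt.loc[is_lipid, "y"] = np.mod(nxt.loc[is_lipid, "y"].to_numpy() + dy, ly)
        frames.append((t0 + float(k), nxt))
        cur = nxt
    meta = dict(config.meta)
    meta.update({"trajectory_seed": seed, "step_sd": step_sd, "n_frames": n_frames})
    return BeadConfiguration(frames, config.box, meta)
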