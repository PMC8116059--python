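"""Per-lipid structural descriptors and their 2D maps.

Descriptors are computed per (frame, lipid) — tilt angle, second-rank order
parameter, chain end-to-end distance, interleaflet contacts, neighbor counts
— collected into tidy tables, and stamped onto the grid via the ester beads
(see :mod:`memsolv.grid`).  Leaflet assignment, bilayer-thickness and
water-penetration maps, time-averaged lipid conformations and the
lipid-mixing (solvation-shell coverage) metric live here too.

All lateral arithmetic is minimum-image aware: frames store wrapped
coordinates, so intra-lipid vectors are reconstructed with periodic deltas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import GridSpec, MapAccumulator, RegionMask, ScalarMap2D, finalize, stamp
from .membrane import BeadConfiguration


def pbc_delta(d, length):
    """Minimum-image displacement for a periodic axis of the given length."""
    d = np.asarray(d, float)
    return d - length * np.round(d / length)


# ---------------------------------------------------------------------------
# per-frame lipid geometry
# ---------------------------------------------------------------------------

def lipid_table(frame_df: pd.DataFrame, box) -> pd.DataFrame:
    """Per-lipid geometry for one frame.

    Returns a DataFrame indexed by lipid_id with columns: species, leaflet,
    ex/ey/ez (ester midpoint), hx/hy/hz (headgroup), tx/ty/tz (tail-end
    midpoint, i.e. the mean position of the last chain bead of each tail).
    Intra-lipid vectors use minimum-image lateral deltas anchored at GL1.
    """
    lx, ly = box[0], box[1]
    lip = frame_df[frame_df["lipid_id"] >= 0]
    g1 = lip[(lip["role"] == "ester") & (lip["tail_index"] == 0)].set_index("lipid_id")
    g2 = lip[(lip["role"] == "ester") & (lip["tail_index"] == 1)].set_index("lipid_id")
    head = lip[lip["role"] == "headgroup"].set_index("lipid_id")
    missing = set(g1.index.symmetric_difference(g2.index))
    if missing:
        raise ValueError(f"lipids missing an ester bead: {sorted(missing)}")

    out = pd.DataFrame(index=g1.index)
    out["species"] = g1["species"]
    out["leaflet"] = g1["leaflet"]
    out["ex"] = np.mod(g1["x"] + 0.5 * pbc_delta(g2["x"] - g1["x"], lx), lx)
    out["ey"] = np.mod(g1["y"] + 0.5 * pbc_delta(g2["y"] - g1["y"], ly), ly)
    out["ez"] = 0.5 * (g1["z"] + g2["z"])
    out["hx"] = np.mod(g1["x"] + pbc_delta(head["x"] - g1["x"], lx), lx)
    out["hy"] = np.mod(g1["y"] + pbc_delta(head["y"] - g1["y"], ly), ly)
    out["hz"] = head["z"]

    ch = lip[lip["role"] == "chain"]
    last = ch[ch.groupby(["lipid_id", "tail_index"])["chain_pos"].transform("max")
              == ch["chain_pos"]]
    ref = g1.loc[last["lipid_id"], ["x", "y"]].to_numpy()
    relx = ref[:, 0] + pbc_delta(last["x"].to_numpy() - ref[:, 0], lx)
    rely = ref[:, 1] + pbc_delta(last["y"].to_numpy() - ref[:, 1], ly)
    ends = pd.DataFrame({"lipid_id": last["lipid_id"].to_numpy(),
                         "x": relx, "y": rely, "z": last["z"].to_numpy()})
    tail_mid = ends.groupby("lipid_id")[["x", "y", "z"]].mean()
    out["tx"] = np.mod(tail_mid["x"], lx)
    out["ty"] = np.mod(tail_mid["y"], ly)
    out["tz"] = tail_mid["z"]
    return out


def assign_leaflets(config: BeadConfiguration, midplane: str = "global") -> BeadConfiguration:
    """Tag each lipid outer/inner by its headgroup side of the membrane midplane.

    The midplane is the per-frame mean z over all ester beads ("global");
    water beads stay "n/a".  Returns a tagged copy.
    """
    out = config.copy()
    for i, (t, df) in enumerate(out.frames):
        est = df[df["role"] == "ester"]
        if est.empty:
            raise ValueError("configuration has no ester beads")
        mid = est["z"].mean()
        head = df[df["role"] == "headgroup"].set_index("lipid_id")["z"]
        tag = pd.Series(np.where(head > mid, "outer", "inner"), index=head.index)
        if tag.nunique() == 1:
            warnings.warn("all lipids on one side of the midplane (monolayer?)")
        is_lip = df["lipid_id"] >= 0
        df.loc[is_lip, "leaflet"] = df.loc[is_lip, "lipid_id"].map(tag).to_numpy()
        out.frames[i] = (t, df)
    return out


# ---------------------------------------------------------------------------
# tidy per-lipid descriptor tables
# ---------------------------------------------------------------------------

def _tidy(config, values_by_frame, name, units) -> pd.DataFrame:
    rows = []
    for f, vals in values_by_frame:
        lt = lipid_table(config.frame(f), config.box)
        sub = pd.DataFrame({"frame": f, "lipid_id": vals.index,
                            "species": lt.loc[vals.index, "species"].to_numpy(),
                            "leaflet": lt.loc[vals.index, "leaflet"].to_numpy(),
                            "value": vals.to_numpy(float)})
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    out.attrs["descriptor_name"] = name
    out.attrs["units"] = units
    return out


def tilt_angles(config: BeadConfiguration) -> pd.DataFrame:
    """Per-lipid tilt: angle between the ester-midpoint -> tail-end axis and
    the -z direction, in degrees.

    A vertical outer-leaflet lipid scores 0°, a vertical inner-leaflet lipid
    180° (single convention covering both leaflets).  Degenerate zero-length
    axes are dropped with a warning.
    """
    per_frame = []
    for f in range(config.n_frames):
        lt = lipid_table(config.frame(f), config.box)
        ax = pbc_delta(lt["tx"] - lt["ex"], config.box[0])
        ay = pbc_delta(lt["ty"] - lt["ey"], config.box[1])
        az = (lt["tz"] - lt["ez"]).to_numpy()
        norm = np.sqrt(ax**2 + ay**2 + az**2)
        ok = norm > 1e-12
        if not ok.all():
            warnings.warn(f"dropping {int((~ok).sum())} lipids with zero-length axis")
        cosang = np.clip(-az[ok] / norm[ok], -1.0, 1.0)
        per_frame.append((f, pd.Series(np.degrees(np.arccos(cosang)), index=lt.index[ok])))
    return _tidy(config, per_frame, "tilt_angle", "deg")


def order_parameters(config: BeadConfiguration) -> pd.DataFrame:
    """Per-lipid mean second-rank order parameter over chain-bond vectors.

    For each bond b between consecutive chain beads, P2 = (3 cos²θ_b − 1)/2
    with θ_b measured against the z axis; per-lipid mean over all bonds.
    """
    lx, ly = config.box[0], config.box[1]
    per_frame = []
    for f in range(config.n_frames):
        df = config.frame(f)
        ch = df[df["role"] == "chain"].sort_values(["lipid_id", "tail_index", "chain_pos"])
        same = (ch["lipid_id"].to_numpy()[1:] == ch["lipid_id"].to_numpy()[:-1]) & \
               (ch["tail_index"].to_numpy()[1:] == ch["tail_index"].to_numpy()[:-1])
        bx = pbc_delta(np.diff(ch["x"].to_numpy()), lx)[same]
        by = pbc_delta(np.diff(ch["y"].to_numpy()), ly)[same]
        bz = np.diff(ch["z"].to_numpy())[same]
        lid = ch["lipid_id"].to_numpy()[1:][same]
        cos2 = bz**2 / (bx**2 + by**2 + bz**2)
        p2 = 0.5 * (3.0 * cos2 - 1.0)
        per_frame.append((f, pd.Series(p2).groupby(lid).mean()))
    return _tidy(config, per_frame, "order_parameter", "")


def end_to_end_distances(config: BeadConfiguration) -> pd.DataFrame:
    """Per-lipid mean acyl-chain end-to-end distance (first-to-last chain bead)."""
    lx, ly = config.box[0], config.box[1]
    per_frame = []
    for f in range(config.n_frames):
        df = config.frame(f)
        ch = df[df["role"] == "chain"]
        firsts = ch[ch.groupby(["lipid_id", "tail_index"])["chain_pos"].transform("min")
                    == ch["chain_pos"]].set_index(["lipid_id", "tail_index"])
        lasts = ch[ch.groupby(["lipid_id", "tail_index"])["chain_pos"].transform("max")
                   == ch["chain_pos"]].set_index(["lipid_id", "tail_index"])
        single = firsts.index.intersection(lasts.index)[
            (firsts.loc[firsts.index.intersection(lasts.index), "chain_pos"]
             == lasts.loc[firsts.index.intersection(lasts.index), "chain_pos"]).to_numpy()]
        if len(single):
            firsts = firsts.drop(single)
            lasts = lasts.drop(single)
        dx = pbc_delta(lasts["x"] - firsts["x"], lx)
        dy = pbc_delta(lasts["y"] - firsts["y"], ly)
        dz = (lasts["z"] - firsts["z"]).to_numpy()
        dist = pd.Series(np.sqrt(dx**2 + dy**2 + dz**2),
                         index=firsts.index).groupby(level="lipid_id").mean()
        per_frame.append((f, dist))
    return _tidy(config, per_frame, "end_to_end", "A")


def chain_contact_counts(frame_df: pd.DataFrame, box, cutoff: float,
                         scored_leaflet: str) -> pd.Series:
    """Bead-pair contact count per acyl chain against the opposing leaflet.

    For each chain (lipid, tail) in ``scored_leaflet``, counts bead pairs
    (own chain bead, opposing-leaflet chain bead) within ``cutoff`` (3D
    distance, periodic in x-y).  Indexed by (lipid_id, tail_index).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    lx, ly = box[0], box[1]
    ch = frame_df[frame_df["role"] == "chain"]
    own = ch[ch["leaflet"] == scored_leaflet]
    opp = ch[(ch["leaflet"] != scored_leaflet) & (ch["leaflet"] != "n/a")]
    idx = pd.MultiIndex.from_frame(own[["lipid_id", "tail_index"]].drop_duplicates())
    if opp.empty or own.empty:
        return pd.Series(0.0, index=idx)
    zbig = 4.0 * (float(np.abs(ch["z"]).max()) + cutoff + 1.0)
    def lift(df):
        return np.column_stack([np.mod(df["x"], lx), np.mod(df["y"], ly),
                                df["z"].to_numpy() + zbig / 2.0])
    tree = cKDTree(lift(opp), boxsize=(lx, ly, zbig))
    n = tree.query_ball_point(lift(own), cutoff, return_length=True)
    counts = pd.Series(n, index=pd.MultiIndex.from_frame(
        own[["lipid_id", "tail_index"]])).groupby(level=[0, 1]).sum()
    return counts.reindex(idx, fill_value=0).astype(float)


def interleaflet_contacts(config: BeadConfiguration, cutoff: float = 6.0,
                          species_scope: str = "all") -> pd.DataFrame:
    """Per-lipid mean interleaflet contacts per chain.

    Contacts are bead pairs within ``cutoff`` between a lipid's chain beads
    and any opposing-leaflet chain bead; ``species_scope`` restricts which
    lipids are scored (all | PO | DL) while contacts are counted against all
    opposing chains.
    """
    per_frame = []
    for f in range(config.n_frames):
        df = config.frame(f)
        parts = []
        for leaf in ("outer", "inner"):
            c = chain_contact_counts(df, config.box, cutoff, leaf)
            parts.append(c.groupby(level="lipid_id").mean())
        vals = pd.concat(parts)
        if species_scope != "all":
            lt = lipid_table(df, config.box)
            vals = vals[lt.loc[vals.index, "species"] == species_scope]
        per_frame.append((f, vals))
    return _tidy(config, per_frame, "interleaflet_contacts", "contacts/chain")


def neighbor_counts(config: BeadConfiguration, radius: float = 15.0,
                    level: str = "ester") -> pd.DataFrame:
    """Per-lipid count of same-leaflet neighbors within ``radius`` (x-y,
    periodic), neighbors located by the centroid of their ``level`` beads."""
    lx, ly = config.box[0], config.box[1]
    per_frame = []
    for f in range(config.n_frames):
        df = config.frame(f)
        lt = lipid_table(df, config.box)
        if level == "ester":
            pts = lt[["ex", "ey"]].to_numpy()
        elif level == "headgroup":
            pts = lt[["hx", "hy"]].to_numpy()
        elif level == "chain":
            ch = df[df["role"] == "chain"]
            g1 = df[(df["role"] == "ester") & (df["tail_index"] == 0)].set_index("lipid_id")
            ref = g1.loc[ch["lipid_id"], ["x", "y"]].to_numpy()
            rx = ref[:, 0] + pbc_delta(ch["x"].to_numpy() - ref[:, 0], lx)
            ry = ref[:, 1] + pbc_delta(ch["y"].to_numpy() - ref[:, 1], ly)
            cen = pd.DataFrame({"lipid_id": ch["lipid_id"].to_numpy(), "x": rx, "y": ry}) \
                .groupby("lipid_id").mean().loc[lt.index]
            pts = np.mod(cen[["x", "y"]].to_numpy(), (lx, ly))
        else:
            raise ValueError(f"unknown level {level!r}")
        vals = pd.Series(0.0, index=lt.index)
        for leaf in ("outer", "inner"):
            sel = (lt["leaflet"] == leaf).to_numpy()
            if sel.sum() == 0:
                continue
            sub = np.mod(pts[sel], (lx, ly))
            tree = cKDTree(sub, boxsize=(lx, ly))
            n = tree.query_ball_point(sub, radius, return_length=True) - 1
            vals.loc[lt.index[sel]] = n.astype(float)
        per_frame.append((f, vals))
    return _tidy(config, per_frame, "neighbor_count", "neighbors")


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------

def _map_from_table(config, table: pd.DataFrame, grid: GridSpec,
                    leaflet: str = "both", occupancy_fraction: float = 0.40,
                    exclude=None) -> ScalarMap2D:
    sub = table if leaflet == "both" else table[table["leaflet"] == leaflet]
    acc = stamp(config, sub, grid, table.attrs.get("descriptor_name", ""),
                table.attrs.get("units", ""))
    return finalize(acc, occupancy_fraction, exclude=exclude, leaflet_scope=leaflet)


def tilt_map(config, grid: GridSpec, occupancy_fraction: float = 0.40) -> dict[str, ScalarMap2D]:
    """Per-leaflet time-averaged tilt-angle maps (degrees)."""
    table = tilt_angles(config)
    return {leaf: _map_from_table(config, table, grid, leaf, occupancy_fraction)
            for leaf in ("outer", "inner")}


def order_parameter_map(config, grid: GridSpec, leaflet: str = "both",
                        occupancy_fraction: float = 0.40) -> ScalarMap2D:
    return _map_from_table(config, order_parameters(config), grid, leaflet,
                           occupancy_fraction)


def end_to_end_map(config, grid: GridSpec, leaflet: str = "both",
                   occupancy_fraction: float = 0.40) -> ScalarMap2D:
    return _map_from_table(config, end_to_end_distances(config), grid, leaflet,
                           occupancy_fraction)


def interleaflet_contacts_map(config, grid: GridSpec, cutoff: float = 6.0,
                              species_scope: str = "all",
                              occupancy_fraction: float = 0.40) -> ScalarMap2D:
    return _map_from_table(config, interleaflet_contacts(config, cutoff, species_scope),
                           grid, "both", occupancy_fraction)


def neighbor_density_map(config, grid: GridSpec, radius: float = 15.0,
                         level: str = "ester",
                         occupancy_fraction: float = 0.40) -> dict[str, ScalarMap2D]:
    table = neighbor_counts(config, radius, level)
    return {leaf: _map_from_table(config, table, grid, leaf, occupancy_fraction)
            for leaf in ("outer", "inner")}


def _layer_z_maps(config, grid, layer, species, occupancy_fraction):
    """Finalized per-leaflet maps of the mean z of the chosen layer's beads."""
    out = {}
    for leaf in ("outer", "inner"):
        per_frame = []
        for f in range(config.n_frames):
            lt = lipid_table(config.frame(f), config.box)
            sel = lt["leaflet"] == leaf
            if species is not None:
                sel &= lt["species"] == species
            z = lt.loc[sel, "ez" if layer == "ester" else "hz"]
            per_frame.append((f, z))
        table = _tidy(config, per_frame, f"{layer}_z_{leaf}", "A")
        out[leaf] = _map_from_table(config, table, grid, "both", occupancy_fraction)
    return out


def thickness_map(config, grid: GridSpec, layer: str = "ester",
                  species: str | None = None,
                  occupancy_fraction: float = 0.40) -> ScalarMap2D:
    """Bilayer thickness d_B: per-cell (outer layer mean z) − (inner layer mean z).

    ``layer`` selects the ester planes (default) or the headgroup/phosphate
    level; ``species`` optionally restricts the stamped lipids to PO or DL.
    Cells where only one leaflet is represented are masked.
    """
    if layer not in ("ester", "headgroup", "phosphate"):
        raise ValueError(f"unknown layer {layer!r}")
    layer = "headgroup" if layer == "phosphate" else layer
    zmaps = _layer_z_maps(config, grid, layer, species, occupancy_fraction)
    mo, mi = zmaps["outer"], zmaps["inner"]
    mask = mo.mask & mi.mask
    values = np.full(mask.shape, np.nan)
    values[mask] = mo.values[mask] - mi.values[mask]
    name = f"thickness_{layer}" + (f"_{species}" if species else "")
    return ScalarMap2D(grid, values, mo.occupancy + mi.occupancy, mask,
                       name, "A", "both", config.n_frames,
                       meta={"outer_z": mo, "inner_z": mi})


def water_penetration_map(config, grid: GridSpec,
                          occupancy_fraction: float = 0.40) -> ScalarMap2D:
    """Per-cell time-averaged count of water beads inside the acyl core.

    The core is bounded by the local (per-cell) outer and inner ester
    surfaces taken from the thickness-map intermediates; cells lacking
    either surface are masked.
    """
    zmaps = _layer_z_maps(config, grid, "ester", None, occupancy_fraction)
    zo, zi = zmaps["outer"].values, zmaps["inner"].values
    mask = zmaps["outer"].mask & zmaps["inner"].mask
    counts = np.zeros(mask.shape)
    n_water = 0
    for f in range(config.n_frames):
        df = config.frame(f)
        w = df[df["role"] == "water"]
        n_water += len(w)
        if w.empty:
            continue
        i, j = grid.cell_index(w["x"].to_numpy(), w["y"].to_numpy())
        z = w["z"].to_numpy()
        ok = mask[i, j] & (z > zi[i, j]) & (z < zo[i, j])
        np.add.at(counts, (i[ok], j[ok]), 1)
    if n_water == 0:
        warnings.warn("configuration contains no water beads")
    values = np.full(mask.shape, np.nan)
    values[mask] = counts[mask] / config.n_frames
    return ScalarMap2D(grid, values, counts.astype(np.int64), mask,
                       "water_penetration", "beads/cell", "both", config.n_frames)


# ---------------------------------------------------------------------------
# average conformation & mixing
# ---------------------------------------------------------------------------

@dataclass
class AverageConformation:
    """Mean bead positions (Å) of lipids resident in a region.

    Positions are in a frame-local coordinate system centered laterally on
    each lipid's ester midpoint (z kept absolute); keyed by bead name.
    """

    mean_positions: dict[str, np.ndarray]
    n_samples: int
    species_scope: str = "all"
    leaflet: str = "outer"

    def axis_lateral_extent(self) -> float:
        """RMS lateral offset of chain beads — 0 for a straight vertical mean."""
        pts = np.array([p for b, p in self.mean_positions.items() if b.startswith("C")])
        if pts.size == 0:
            return float("nan")
        return float(np.sqrt(np.mean(pts[:, 0] ** 2 + pts[:, 1] ** 2)))


def average_conformation(config, region: RegionMask, species_scope: str = "all",
                         leaflet: str = "outer") -> AverageConformation:
    """Time-average the 3D conformation of lipids residing in ``region``.

    For every frame, lipids whose ester midpoint falls in the region (and
    match the species/leaflet scope) contribute their bead positions
    relative to the ester midpoint (laterally).  Isotropic dynamics (random
    azimuth) average to a straight vertical structure.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    n_samples = 0
    lx, ly = config.box[0], config.box[1]
    for f in range(config.n_frames):
        df = config.frame(f)
        lt = lipid_table(df, config.box)
        i, j = region.grid.cell_index(lt["ex"].to_numpy(), lt["ey"].to_numpy())
        sel = region.cells[i, j]
        if species_scope != "all":
            sel &= (lt["species"] == species_scope).to_numpy()
        if leaflet != "both":
            sel &= (lt["leaflet"] == leaflet).to_numpy()
        resident = lt.index[sel]
        if len(resident) == 0:
            continue
        n_samples += len(resident)
        beads = df[df["lipid_id"].isin(resident)]
        ref = lt.loc[beads["lipid_id"], ["ex", "ey"]].to_numpy()
        relx = pbc_delta(beads["x"].to_numpy() - ref[:, 0], lx)
        rely = pbc_delta(beads["y"].to_numpy() - ref[:, 1], ly)
        relz = beads["z"].to_numpy()
        for bead, rx, ry, rz in zip(beads["bead"], relx, rely, relz):
            if bead not in sums:
                sums[bead] = np.zeros(3)
                counts[bead] = 0
            sums[bead] += (rx, ry, rz)
            counts[bead] += 1
    means = {b: sums[b] / counts[b] for b in sums}
    return AverageConformation(means, n_samples, species_scope, leaflet)


@dataclass
class MixingResult:
    """Cumulative solvation-shell coverage of a trajectory."""

    times: np.ndarray
    per_lipid: pd.DataFrame  # lipids x frames, running fraction
    mean_curve: np.ndarray

    @property
    def final_mean(self) -> float:
        return float(self.mean_curve[-1])


def mixing_fraction(trajectory: BeadConfiguration, shell_cutoff: float) -> MixingResult:
    """Running fraction of same-leaflet lipids ever seen in the first shell.

    Per lipid and frame: the fraction of all other same-leaflet lipids whose
    ester midpoint has come within ``shell_cutoff`` (x-y, periodic) at any
    frame so far.  Monotone non-decreasing; reported mean is over lipids.
    """
    if trajectory.n_frames < 2:
        raise ValueError("mixing_fraction needs at least 2 frames")
    lx, ly = trajectory.box[0], trajectory.box[1]
    lt0 = lipid_table(trajectory.frame(0), trajectory.box)
    curves = {}
    for leaf in ("outer", "inner"):
        ids = lt0.index[lt0["leaflet"] == leaf].to_numpy()
        if ids.size == 0:
            continue
        if ids.size == 1:
            raise ValueError(f"{leaf} leaflet has a single lipid; mixing undefined")
        ever = np.zeros((ids.size, ids.size), dtype=bool)
        frac = np.zeros((ids.size, trajectory.n_frames))
        pos_index = {lid: k for k, lid in enumerate(ids)}
        for f in range(trajectory.n_frames):
            lt = lipid_table(trajectory.frame(f), trajectory.box)
            pts = np.mod(lt.loc[ids, ["ex", "ey"]].to_numpy(), (lx, ly))
            tree = cKDTree(pts, boxsize=(lx, ly))
            pairs = tree.query_pairs(shell_cutoff, output_type="ndarray")
            if pairs.size:
                ever[pairs[:, 0], pairs[:, 1]] = True
                ever[pairs[:, 1], pairs[:, 0]] = True
            frac[:, f] = ever.sum(axis=1) / (ids.size - 1)
        for lid in ids:
            curves[lid] = frac[pos_index[lid]]
    per_lipid = pd.DataFrame(curves).T
    per_lipid.columns = trajectory.times
    return MixingResult(trajectory.times, per_lipid,
                        per_lipid.to_numpy().mean(axis=0))
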