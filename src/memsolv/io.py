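"""Readers and writers: GRO/PDB configurations, map CSVs, tables, fit JSON.

Coordinate files go through MDAnalysis; internal units are Angstrom, with
nm conversion handled at the GRO boundary by the format layer.  Maps are
serialized as a CSV matrix plus a JSON header declaring the grid spec,
descriptor, units and the masked-cell sentinel.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec, ScalarMap2D, MASK_SENTINEL
from .membrane import BeadConfiguration, FRAME_COLUMNS

_CHAIN_RE = re.compile(r"^[CD](\d)([AB])$")

#: default bead-name -> (role, tail_index, chain_pos) resolution
DEFAULT_ROSTER = {
    "NH3": ("headgroup", -1, 0),
    "NC3": ("headgroup", -1, 0),
    "PO4": ("headgroup", -1, 0),
    "GL1": ("ester", 0, 0),
    "GL2": ("ester", 1, 0),
    "W": ("water", -1, 0),
}

#: residue-name prefix -> species label
SPECIES_MAP = {"PO": "PO", "DL": "DL", "W": "W", "SOL": "W"}


def _resolve_bead(name: str, roster_map: dict) -> tuple[str, int, int]:
    if name in roster_map:
        return roster_map[name]
    m = _CHAIN_RE.match(name)
    if m:
        return ("chain", 0 if m.group(2) == "A" else 1, int(m.group(1)))
    raise KeyError(f"unknown bead name {name!r}: not in the roster map and not a chain bead")


def _mda_universe(config: BeadConfiguration, frame: int = 0):
    import MDAnalysis as mda

    df = config.frame(frame)
    lipid_ids = df["lipid_id"].to_numpy()
    # each lipid is a residue; each water bead its own residue
    res_key = np.where(lipid_ids >= 0, lipid_ids, -(np.arange(len(df)) + 2))
    _, resindex = np.unique(res_key, return_inverse=True)
    n_res = resindex.max() + 1
    u = mda.Universe.empty(len(df), n_residues=n_res, atom_resindex=resindex,
                           trajectory=True)
    u.add_TopologyAttr("names", df["bead"].to_numpy())
    resnames = np.empty(n_res, dtype=object)
    resids = np.zeros(n_res, dtype=int)
    for k in range(n_res):
        rows = np.where(resindex == k)[0]
        sp = df["species"].iloc[rows[0]]
        resnames[k] = "W" if sp == "W" else sp
        lid = df["lipid_id"].iloc[rows[0]]
        resids[k] = lid + 1 if lid >= 0 else 0
    # GRO/PDB resids must be positive; number waters after the lipids
    nxt = resids.max() + 1 if (resids > 0).any() else 1
    for k in range(n_res):
        if resids[k] == 0:
            resids[k] = nxt
            nxt += 1
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.atoms.positions = df[["x", "y", "z"]].to_numpy()
    u.dimensions = [config.box[0], config.box[1], config.box[2], 90, 90, 90]
    return u


def write_gro(config: BeadConfiguration, path, frame: int = 0) -> Path:
    """Write one frame as GRO (MDAnalysis converts internal Å to nm)."""
    path = Path(path)
    _mda_universe(config, frame).atoms.write(str(path))
    return path


def write_pdb(config: BeadConfiguration, path, frame: int = 0) -> Path:
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis warns about absent attrs
        _mda_universe(config, frame).atoms.write(str(path))
    return path


def write_frames(config: BeadConfiguration, prefix, fmt: str = "gro") -> list[Path]:
    """One coordinate file per frame plus a JSON sidecar with the metadata."""
    prefix = Path(prefix)
    writer = write_gro if fmt == "gro" else write_pdb
    paths = [writer(config, prefix.with_name(f"{prefix.name}_f{i:04d}.{fmt}"), i)
             for i in range(config.n_frames)]
    sidecar = prefix.with_name(f"{prefix.name}_meta.json")
    save_json({"box": list(config.box), "n_frames": config.n_frames,
               "times": config.times.tolist(), "meta": config.meta}, sidecar)
    return paths


def read_configuration(path, fmt: str | None = None,
                       roster_map: dict | None = None) -> BeadConfiguration:
    """Read a GRO or PDB file into a BeadConfiguration (positions in Å).

    Bead names are resolved to roles via ``roster_map`` (default covers
    NH3/NC3/PO4 headgroups, GL1/GL2 esters, C*/D* chain beads, W water);
    species come from the residue-name prefix.  Lipids missing an ester
    bead raise an error listing their ids.
    """
    import MDAnalysis as mda

    roster = dict(DEFAULT_ROSTER)
    if roster_map:
        roster.update(roster_map)
    path = Path(path)
    u = mda.Universe(str(path))
    rows = []
    for atom in u.atoms:
        resname = str(atom.resname).strip()
        species = None
        for prefix, sp in SPECIES_MAP.items():
            if resname.startswith(prefix):
                species = sp
                break
        if species is None:
            raise KeyError(f"unknown residue name {resname!r}")
        role, tail, chain_pos = _resolve_bead(str(atom.name).strip(), roster)
        if species == "W" or role == "water":
            rows.append((-1, "W", "water", "W", -1, 0, "n/a", *atom.position))
        else:
            rows.append((int(atom.resid) - 1, species, role, str(atom.name).strip(),
                         tail, chain_pos, "n/a", *atom.position))
    df = pd.DataFrame(rows, columns=FRAME_COLUMNS)
    lip = df[df["lipid_id"] >= 0]
    est_counts = lip[lip["role"] == "ester"].groupby("lipid_id").size()
    bad = sorted(set(lip["lipid_id"]) - set(est_counts[est_counts == 2].index))
    if bad:
        raise ValueError(f"lipids missing ester beads: {bad}")
    dims = u.dimensions
    box = (float(dims[0]), float(dims[1]), float(dims[2]))
    return BeadConfiguration([(0.0, df)], box, {"source": str(path)})


def read_trajectory(paths, **kw) -> BeadConfiguration:
    """Concatenate per-frame coordinate files into a multi-frame configuration."""
    configs = [read_configuration(p, **kw) for p in paths]
    frames = [(float(i), c.frame(0)) for i, c in enumerate(configs)]
    return BeadConfiguration(frames, configs[0].box, {"source": [str(p) for p in paths]})


# ---------------------------------------------------------------------------
# maps, tables, fits
# ---------------------------------------------------------------------------

def save_map(m: ScalarMap2D, prefix) -> tuple[Path, Path]:
    """CSV matrix (masked cells as the sentinel) plus a JSON header."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    vals = np.where(m.mask, m.values, MASK_SENTINEL)
    np.savetxt(csv_path, vals, delimiter=",", fmt="%.8g")
    header = {
        "descriptor": m.descriptor_name, "units": m.units,
        "leaflet_scope": m.leaflet_scope, "n_frames": m.n_frames,
        "cell_edge": m.grid.cell_edge, "stamp_radius": m.grid.stamp_radius,
        "lx": m.grid.lx, "ly": m.grid.ly, "nx": m.grid.nx, "ny": m.grid.ny,
        "mask_sentinel": MASK_SENTINEL,
        "convention": "rows are x cells, columns are y cells; masked cells "
                      "hold the sentinel value",
    }
    save_json(header, json_path)
    occ_path = prefix.with_name(prefix.name + "_occupancy.csv")
    np.savetxt(occ_path, m.occupancy, delimiter=",", fmt="%d")
    return csv_path, json_path


def load_map(prefix) -> ScalarMap2D:
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    vals = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", ndmin=2)
    occ_path = prefix.with_name(prefix.name + "_occupancy.csv")
    occ = (np.loadtxt(occ_path, delimiter=",", ndmin=2).astype(np.int64)
           if occ_path.exists() else np.zeros_like(vals, dtype=np.int64))
    mask = vals != header["mask_sentinel"]
    values = np.where(mask, vals, np.nan)
    grid = GridSpec(header["lx"], header["ly"], header["cell_edge"],
                    header["stamp_radius"])
    return ScalarMap2D(grid, values, occ, mask, header["descriptor"],
                       header["units"], header["leaflet_scope"], header["n_frames"])


def save_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def save_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path


def read_step_distributions(path) -> list:
    """Read photobleaching CSV (label, pct_dl, chi_subunits_per_lipid, n1, n2, n3plus)."""
    from .thermo import StepDistribution

    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(StepDistribution.from_counts(
            int(r["n1"]), int(r["n2"]), int(r["n3plus"]),
            chi=float(r["chi_subunits_per_lipid"]),
            pct_dl=float(r["pct_dl"]), label=str(r["label"])))
    return out


def read_efflux_trace(path):
    from .efflux import EffluxTrace

    df = pd.read_csv(path)
    return EffluxTrace(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())
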