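"""Descriptor correctness: planted-truth recovery, closed-form values and
hand-constructed fixtures."""

import numpy as np
import pandas as pd
import pytest
from conftest import gaussian_bump

from memsolv import descriptors, grid, membrane
from memsolv.membrane import FRAME_COLUMNS


def defect_config(box=(128.0, 128.0, 100.0), n=256, depth=8.0, sigma=15.0,
                  tilt=0.0, tilt_region=None, seed=3):
    """Static defect bilayer with the thinning center on a lattice site."""
    # 256 sites on a 128 Å box -> 16x16 lattice, spacing 8, sites at 4,12,...
    center = (68.0, 68.0)  # a lattice site
    thick = gaussian_bump(center, -depth, sigma, box, baseline=38.0)
    if tilt_region is not None:
        tfield = lambda x, y: np.where(
            tilt_region.contains(x, y), tilt, 0.0)
    else:
        tfield = tilt
    pf = membrane.PlantedField(thick, tfield, 0.0)
    cfg = membrane.generate_defect_bilayer(pf, n, box, seed=seed)
    return descriptors.assign_leaflets(cfg), center, thick


class TestLeaflets:
    def test_flat_bilayer_splits_in_half(self, flat_mixed):
        lt = descriptors.lipid_table(flat_mixed.frame(0), flat_mixed.box)
        assert (lt["leaflet"].value_counts() == 100).all()

    def test_tilted_lipids_keep_headgroup_leaflet(self):
        box = (96.0, 96.0, 100.0)
        region = membrane.CircularFootprint((48.0, 48.0), 25.0, (96.0, 96.0))
        pf = membrane.PlantedField(
            38.0, lambda x, y: np.where(region.contains(x, y), 60.0, 0.0), 0.0)
        cfg = membrane.generate_defect_bilayer(pf, 144, box, seed=6)
        tagged = descriptors.assign_leaflets(cfg)
        lt = descriptors.lipid_table(tagged.frame(0), box)
        # generator built outer lipids at +z: headgroup side decides, tilt or not
        assert (lt.loc[lt["ez"] > 0, "leaflet"] == "outer").all()
        assert (lt.loc[lt["ez"] < 0, "leaflet"] == "inner").all()

    def test_monolayer_warns(self):
        cfg = membrane.generate_flat_bilayer(8, 0.0, 38.0, seed=0)
        df = cfg.frame(0)
        cfg.frames[0] = (0.0, df[df["leaflet"] == "outer"].reset_index(drop=True))
        with pytest.warns(UserWarning, match="one side"):
            descriptors.assign_leaflets(cfg)


class TestThicknessMap:
    def test_flat_is_uniform_38(self, flat_mixed, unit_grid):
        m = descriptors.thickness_map(flat_mixed, unit_grid(flat_mixed))
        assert np.allclose(m.values[m.mask], 38.0)

    def test_planted_thinning_recovered_within_half_angstrom(self):
        cfg, center, thick = defect_config()
        g = grid.GridSpec.for_box(cfg.box)
        m = descriptors.thickness_map(cfg, g, occupancy_fraction=0.0)
        assert abs(m.nanmin() - 30.0) <= 0.5
        assert m.value_at(*center) == pytest.approx(30.0, abs=0.5)

    def test_species_restricted_maps_agree_on_aligned_bilayer(self, flat_mixed, unit_grid):
        # diffusive frames give PO and DL stamps on common cells; both
        # species' esters sit on the same planes, so the species-restricted
        # thickness maps agree wherever both are defined
        traj = membrane.generate_trajectory(flat_mixed, 25, 3.0, seed=30)
        g = unit_grid(traj)
        m_po = descriptors.thickness_map(traj, g, species="PO",
                                         occupancy_fraction=0.0)
        m_dl = descriptors.thickness_map(traj, g, species="DL",
                                         occupancy_fraction=0.0)
        both = m_po.mask & m_dl.mask
        assert both.any()
        assert np.allclose(m_po.values[both], m_dl.values[both], atol=1e-9)

    def test_headgroup_layer_sits_above_esters(self, flat_po, unit_grid):
        g = unit_grid(flat_po)
        m_est = descriptors.thickness_map(flat_po, g, layer="ester")
        m_head = descriptors.thickness_map(flat_po, g, layer="headgroup")
        assert np.nanmean(m_head.values) == pytest.approx(
            np.nanmean(m_est.values) + 2 * membrane.HEADGROUP_OFFSET, abs=1e-9)


class TestTiltMap:
    def test_planted_uniform_tilt_recovered(self):
        region = membrane.CircularFootprint((68.0, 68.0), 30.0, (128.0, 128.0))
        cfg, _, _ = defect_config(depth=0.0, tilt=60.0, tilt_region=region)
        maps = descriptors.tilt_map(cfg, grid.GridSpec.for_box(cfg.box),
                                    occupancy_fraction=0.0)
        cx, cy = maps["outer"].grid.cell_centers()
        # buffer > stamp radius + ester offset keeps boundary-straddling
        # stamps out of both selections
        d = np.hypot(cx - 68.0, cy - 68.0)
        sel = maps["outer"].mask & (d <= 24.0)
        assert np.allclose(maps["outer"].values[sel], 60.0, atol=1e-9)
        # inner leaflet on the paper's 0-180 convention
        sel_i = maps["inner"].mask & (d <= 24.0)
        assert np.allclose(maps["inner"].values[sel_i], 120.0, atol=1e-9)
        far = maps["outer"].mask & (d >= 36.0)
        assert np.allclose(maps["outer"].values[far], 0.0, atol=1e-9)

    def test_azimuthal_mean_direction_vanishes_under_isotropy(self):
        # many independent azimuth draws at fixed 60 deg tilt: the lateral
        # projection of the lipid axis must average to ~0
        frames = []
        for k in range(64):
            pf = membrane.PlantedField(38.0, 60.0, 0.0)
            c = membrane.generate_defect_bilayer(pf, 36, (48.0, 48.0, 90.0), seed=100 + k)
            frames.append((float(k), c.frame(0)))
        combo = membrane.BeadConfiguration(frames, (48.0, 48.0, 90.0))
        combo = descriptors.assign_leaflets(combo)
        vecs = []
        for f in range(combo.n_frames):
            lt = descriptors.lipid_table(combo.frame(f), combo.box)
            vx = descriptors.pbc_delta(lt["tx"] - lt["ex"], combo.box[0])
            vy = descriptors.pbc_delta(lt["ty"] - lt["ey"], combo.box[1])
            vecs.append(np.column_stack([vx, vy]))
        v = np.vstack(vecs)
        n = v.shape[0]
        # axis lateral magnitude ~ L sin60; mean of n iid vanishes like 1/sqrt(n)
        mag = np.linalg.norm(v, axis=1).mean()
        assert np.linalg.norm(v.mean(axis=0)) < 4 * mag / np.sqrt(n)


class TestOrderParameter:
    def test_vertical_chains_score_one(self, flat_po, unit_grid):
        m = descriptors.order_parameter_map(flat_po, unit_grid(flat_po),
                                            occupancy_fraction=0.0)
        assert np.allclose(m.values[m.mask], 1.0)

    def test_magic_angle_scores_zero(self):
        magic = np.degrees(np.arccos(1 / np.sqrt(3)))
        pf = membrane.PlantedField(38.0, magic, 0.0)
        cfg = descriptors.assign_leaflets(
            membrane.generate_defect_bilayer(pf, 36, (48.0, 48.0, 90.0), seed=1))
        table = descriptors.order_parameters(cfg)
        assert np.allclose(table["value"], 0.0, atol=1e-12)

    def test_range_invariant(self):
        # random tilts in [0, 90]: P2 stays within [-0.5, 1]
        pf = membrane.PlantedField(
            38.0, lambda x, y: np.mod(x * 7.3 + y * 3.1, 90.0), 0.0)
        cfg = descriptors.assign_leaflets(
            membrane.generate_defect_bilayer(pf, 100, (80.0, 80.0, 90.0), seed=2))
        v = descriptors.order_parameters(cfg)["value"]
        assert (v >= -0.5 - 1e-12).all() and (v <= 1.0 + 1e-12).all()


class TestEndToEnd:
    def test_straight_tails_closed_form(self, flat_mixed):
        table = descriptors.end_to_end_distances(flat_mixed)
        lt = descriptors.lipid_table(flat_mixed.frame(0), flat_mixed.box)
        sp = lt.loc[table["lipid_id"], "species"].to_numpy()
        # straight n-bead tail with 3 Å spacing: (n-1)*3
        assert np.allclose(table["value"][sp == "PO"], 12.0)
        assert np.allclose(table["value"][sp == "DL"], 6.0)

    def test_dl_shorter_than_po_on_every_cell(self, flat_mixed, unit_grid):
        g = unit_grid(flat_mixed)
        tab = descriptors.end_to_end_distances(flat_mixed)
        po = tab[tab.lipid_id.isin(
            descriptors.lipid_table(flat_mixed.frame(0), flat_mixed.box)
            .query("species=='PO'").index)]
        dl = tab[~tab.lipid_id.isin(po.lipid_id)]
        from memsolv.grid import finalize, stamp
        m_po = finalize(stamp(flat_mixed, po, g), 0.0)
        m_dl = finalize(stamp(flat_mixed, dl, g), 0.0)
        both = m_po.mask & m_dl.mask
        assert (m_dl.values[both] < m_po.values[both]).all()


class TestInterleafletContacts:
    def test_thick_bilayer_has_none(self, flat_po, unit_grid):
        m = descriptors.interleaflet_contacts_map(flat_po, unit_grid(flat_po),
                                                  cutoff=6.0, occupancy_fraction=0.0)
        assert np.allclose(m.values[m.mask], 0.0)

    def test_hand_constructed_pair_count(self):
        # two opposing single-lipid leaflets with known interdigitation:
        # place chain beads so exactly k bead pairs fall within the cutoff
        rows = []
        # outer lipid 0: esters at z=+3, chain beads at z = 0, -3, -6
        for bead, tail, pos, x, z in [("GL1", 0, 0, 10.0, 3.0), ("GL2", 1, 0, 12.5, 3.0),
                                      ("C1A", 0, 1, 10.0, 0.0), ("C2A", 0, 2, 10.0, -3.0),
                                      ("C3A", 0, 3, 10.0, -6.0),
                                      ("C1B", 1, 1, 12.5, 0.0), ("C2B", 1, 2, 12.5, -3.0),
                                      ("C3B", 1, 3, 12.5, -6.0)]:
            role = "ester" if pos == 0 else "chain"
            rows.append((0, "DL", role, bead, tail, pos, "outer", x, 10.0, z))
        rows.append((0, "DL", "headgroup", "NH3", -1, 0, "outer", 11.25, 10.0, 6.0))
        # inner lipid 1 laterally offset by 2 Å, chains pointing up
        for bead, tail, pos, x, z in [("GL1", 0, 0, 12.0, -3.0), ("GL2", 1, 0, 14.5, -3.0),
                                      ("C1A", 0, 1, 12.0, 0.0), ("C2A", 0, 2, 12.0, 3.0),
                                      ("C3A", 0, 3, 12.0, 6.0),
                                      ("C1B", 1, 1, 14.5, 0.0), ("C2B", 1, 2, 14.5, 3.0),
                                      ("C3B", 1, 3, 14.5, 6.0)]:
            role = "ester" if pos == 0 else "chain"
            rows.append((1, "DL", role, bead, tail, pos, "inner", x, 10.0, z))
        rows.append((1, "DL", "headgroup", "NH3", -1, 0, "inner", 13.25, 10.0, -6.0))
        df = pd.DataFrame(rows, columns=FRAME_COLUMNS)
        box = (40.0, 40.0, 40.0)
        cutoff = 4.0
        # brute-force oracle over all chain-bead pairs
        out_ch = df[(df.leaflet == "outer") & (df.role == "chain")]
        in_ch = df[(df.leaflet == "inner") & (df.role == "chain")]
        d = np.linalg.norm(out_ch[["x", "y", "z"]].to_numpy()[:, None, :]
                           - in_ch[["x", "y", "z"]].to_numpy()[None, :, :], axis=2)
        k_expected = int((d <= cutoff).sum())
        counts = descriptors.chain_contact_counts(df, box, cutoff, "outer")
        assert counts.sum() == k_expected
        assert k_expected > 0

    def test_global_pair_symmetry(self):
        cfg = descriptors.assign_leaflets(
            membrane.generate_flat_bilayer(64, 0.4, 16.0, seed=9))
        df = cfg.frame(0)
        s_out = descriptors.chain_contact_counts(df, cfg.box, 6.0, "outer").sum()
        s_in = descriptors.chain_contact_counts(df, cfg.box, 6.0, "inner").sum()
        assert s_out == s_in

    def test_dl_fewer_contacts_than_po(self):
        cfg = descriptors.assign_leaflets(
            membrane.generate_flat_bilayer(100, 0.5, 22.0, seed=10))
        tab = descriptors.interleaflet_contacts(cfg, cutoff=6.0)
        lt = descriptors.lipid_table(cfg.frame(0), cfg.box)
        sp = lt.loc[tab["lipid_id"], "species"].to_numpy()
        assert tab["value"][sp == "DL"].mean() < tab["value"][sp == "PO"].mean()

    def test_nonpositive_cutoff_rejected(self, flat_po):
        with pytest.raises(ValueError, match="cutoff"):
            descriptors.chain_contact_counts(flat_po.frame(0), flat_po.box, 0.0, "outer")


class TestNeighborDensity:
    def test_lattice_count_matches_brute_force(self, flat_po):
        radius = 15.0
        table = descriptors.neighbor_counts(flat_po, radius=radius)
        lt = descriptors.lipid_table(flat_po.frame(0), flat_po.box)
        lx, ly = flat_po.box[0], flat_po.box[1]
        for leaf in ("outer", "inner"):
            pts = lt.loc[lt.leaflet == leaf, ["ex", "ey"]].to_numpy()
            dx = descriptors.pbc_delta(pts[:, None, 0] - pts[None, :, 0], lx)
            dy = descriptors.pbc_delta(pts[:, None, 1] - pts[None, :, 1], ly)
            within = (dx**2 + dy**2 <= radius**2)
            expected = within.sum(axis=1) - 1
            got = table[table.leaflet == leaf].set_index("lipid_id").loc[
                lt.index[lt.leaflet == leaf], "value"].to_numpy()
            assert (got == expected).all()

    def test_single_lipid_has_no_neighbors(self):
        cfg = membrane.generate_flat_bilayer(4, 0.0, 38.0, box=(64, 64, 98), seed=0)
        cfg = descriptors.assign_leaflets(cfg)
        df = cfg.frame(0)
        keep = df[(df.lipid_id == df.lipid_id.min()) | (df.leaflet == "inner")]
        cfg.frames[0] = (0.0, keep.reset_index(drop=True))
        table = descriptors.neighbor_counts(cfg, radius=15.0)
        outer = table[table.leaflet == "outer"]
        assert len(outer) == 1 and (outer["value"] == 0).all()


class TestWaterPenetration:
    def test_dry_core_is_zero(self, flat_mixed, unit_grid):
        cfg = flat_mixed.copy()
        m = descriptors.water_penetration_map(cfg, unit_grid(cfg),
                                              occupancy_fraction=0.0)
        assert np.allclose(m.values[m.mask], 0.0)

    def test_planted_column_recovered(self, flat_mixed, unit_grid):
        g = unit_grid(flat_mixed)
        x0, y0 = 36.0, 44.0  # atop a lattice site so the ester surfaces exist
        cfg = membrane.add_interior_water(flat_mixed, x0, y0, 5, (-10.0, 10.0), seed=1)
        m = descriptors.water_penetration_map(cfg, g, occupancy_fraction=0.0)
        i, j = g.cell_index(x0, y0)
        assert m.values[i, j] == pytest.approx(5.0)
        others = m.values[m.mask].sum() - m.values[i, j]
        assert others == pytest.approx(0.0)

    def test_planted_enrichment_ratio_recovered(self, unit_grid):
        # 3x more interstitial water planted in a defect column than in a
        # bulk column: the map recovers the planted ratio
        cfg = membrane.generate_flat_bilayer(100, 0.0, 38.0, seed=15)
        cfg = descriptors.assign_leaflets(cfg)
        cfg = membrane.add_interior_water(cfg, 20.0, 20.0, 30, (-12.0, 12.0), seed=2)
        cfg = membrane.add_interior_water(cfg, 60.0, 60.0, 10, (-12.0, 12.0), seed=3)
        g = unit_grid(cfg)
        m = descriptors.water_penetration_map(cfg, g, occupancy_fraction=0.0)
        i1, j1 = g.cell_index(20.0, 20.0)
        i2, j2 = g.cell_index(60.0, 60.0)
        assert m.values[i1, j1] / m.values[i2, j2] == pytest.approx(3.0, rel=0.10)


class TestAverageConformation:
    def _whole_grid_region(self, cfg):
        g = grid.GridSpec.for_box(cfg.box)
        return grid.RegionMask(g, np.ones((g.nx, g.ny), bool), "all")

    def test_static_vertical_lipid_is_exact(self, flat_po):
        region = self._whole_grid_region(flat_po)
        avg = descriptors.average_conformation(flat_po, region, leaflet="outer")
        assert avg.n_samples == 64
        assert avg.mean_positions["NH3"] == pytest.approx([0.0, 0.0, 22.0])
        assert avg.mean_positions["GL1"] == pytest.approx([-1.25, 0.0, 19.0])
        assert avg.mean_positions["C5A"] == pytest.approx([-1.25, 0.0, 4.0])

    def test_random_azimuth_tilt_averages_to_vertical_contracted(self):
        # 60 deg tilt, isotropic azimuth: mean structure is vertical and
        # laterally contracted; cross-check against direct averaging of the
        # same rotation sampled densely (quadrature oracle)
        frames = []
        box = (48.0, 48.0, 90.0)
        for k in range(400):
            pf = membrane.PlantedField(38.0, 60.0, 0.0)
            c = membrane.generate_defect_bilayer(pf, 16, box, seed=500 + k)
            frames.append((float(k), c.frame(0)))
        combo = descriptors.assign_leaflets(membrane.BeadConfiguration(frames, box))
        region = self._whole_grid_region(combo)
        avg = descriptors.average_conformation(combo, region, leaflet="outer")
        # quadrature oracle: average the rotated template over azimuth
        phis = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        rots = np.mean([membrane._rotation_from_tilt(60.0, p) for p in phis], axis=0)
        rows, offs = membrane._lipid_offsets(membrane.PO_SPEC, 1)
        expect = {bead: rots @ off for (bead, *_), off in zip(rows, offs)}
        for bead in ("NH3", "C5A", "GL1"):
            got = avg.mean_positions[bead] - [0, 0, 19.0]
            assert np.allclose(got, expect[bead], atol=0.5)  # sampling bound
        # laterally centered: x and y means near zero for the tail ends
        tail = 0.5 * (avg.mean_positions["C5A"] + avg.mean_positions["C5B"])
        assert np.hypot(tail[0], tail[1]) < 0.5

    def test_consistent_azimuth_keeps_tilt(self):
        # all lipids tilted with the SAME azimuth: no averaging-out, the mean
        # structure is tilted at exactly the planted angle
        box = (48.0, 48.0, 90.0)
        rot = membrane._rotation_from_tilt(60.0, 0.7)
        rows_t, offs = membrane._lipid_offsets(membrane.PO_SPEC, 1)
        offs = offs @ rot.T
        records = []
        for k, (x0, y0) in enumerate([(12, 12), (12, 36), (36, 12), (36, 36)]):
            for (bead, role, tail, pos), off in zip(rows_t, offs):
                records.append((k, "PO", role, bead, tail, pos, "outer",
                                x0 + off[0], y0 + off[1], 19.0 + off[2]))
            # a token inner leaflet so the midplane lands between leaflets
            for (bead, role, tail, pos), off in zip(
                    *[(r, o) for r, o in [membrane._lipid_offsets(membrane.PO_SPEC, -1)]][0]):
                records.append((100 + k, "PO", role, bead, tail, pos, "inner",
                                x0 + off[0], y0 + off[1], -19.0 + off[2]))
        df = pd.DataFrame(records, columns=FRAME_COLUMNS)
        cfg = membrane.BeadConfiguration([(0.0, df)], box)
        region = self._whole_grid_region(cfg)
        avg = descriptors.average_conformation(cfg, region, leaflet="outer")
        tail = 0.5 * (avg.mean_positions["C5A"] + avg.mean_positions["C5B"])
        ester = 0.5 * (avg.mean_positions["GL1"] + avg.mean_positions["GL2"])
        axis = tail - ester
        ang = np.degrees(np.arccos(-axis[2] / np.linalg.norm(axis)))
        assert ang == pytest.approx(60.0, abs=1e-9)

    def test_empty_region_gives_zero_samples(self, flat_po):
        g = grid.GridSpec.for_box(flat_po.box)
        empty = grid.RegionMask(g, np.zeros((g.nx, g.ny), bool), "empty")
        avg = descriptors.average_conformation(flat_po, empty)
        assert avg.n_samples == 0 and avg.mean_positions == {}


class TestMixing:
    def test_frozen_trajectory_constant_first_shell(self, flat_mixed):
        traj = membrane.generate_trajectory(flat_mixed, 4, 0.0, seed=1)
        mix = descriptors.mixing_fraction(traj, 12.0)
        assert np.allclose(mix.mean_curve, mix.mean_curve[0])
        lt = descriptors.lipid_table(flat_mixed.frame(0), flat_mixed.box)
        pts = lt[lt.leaflet == "outer"][["ex", "ey"]].to_numpy()
        dx = descriptors.pbc_delta(pts[:, None, 0] - pts[None, :, 0], flat_mixed.box[0])
        dy = descriptors.pbc_delta(pts[:, None, 1] - pts[None, :, 1], flat_mixed.box[1])
        n_shell = ((dx**2 + dy**2 <= 12.0**2).sum(axis=1) - 1)
        expected = n_shell / (len(pts) - 1)
        lid0 = lt.index[lt.leaflet == "outer"][0]
        assert mix.per_lipid.loc[lid0].iloc[0] == pytest.approx(expected[0])

    def test_single_lipid_leaflet_rejected(self):
        cfg = membrane.generate_flat_bilayer(4, 0.0, 38.0, seed=0)
        cfg = descriptors.assign_leaflets(cfg)
        df = cfg.frame(0)
        keep = df[(df.lipid_id == df.lipid_id.min()) | (df.leaflet == "inner")]
        cfg.frames[0] = (0.0, keep.reset_index(drop=True))
        traj = membrane.generate_trajectory(cfg, 3, 1.0, seed=0)
        with pytest.raises(ValueError, match="single lipid"):
            descriptors.mixing_fraction(traj, 10.0)

    def test_two_frames_required(self, flat_mixed):
        with pytest.raises(ValueError, match="2 frames"):
            descriptors.mixing_fraction(flat_mixed, 10.0)
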