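"""Membrane-structure maps of a bilayer with a planted thinning defect.

Builds a coarse-grained bilayer whose ester planes follow a Gaussian
thinning well (8 Å deep, sigma 15 Å) next to a circular protein footprint,
with a 60-degree lipid-tilt annulus around the footprint, then recovers
both features with the grid-stamped map pipeline.
"""

import numpy as np

from memsolv import descriptors, grid, membrane

box = (160.0, 160.0, 100.0)
footprint = membrane.CircularFootprint((80.0, 80.0), 12.0, (160.0, 160.0))
defect_center = (100.0, 76.0)


def thickness_field(x, y):
    dx, dy = x - defect_center[0], y - defect_center[1]
    return 38.0 - 8.0 * np.exp(-(dx**2 + dy**2) / (2 * 15.0**2))


def tilt_field(x, y):
    return np.where(np.hypot(x - 80.0, y - 80.0) < 30.0, 60.0, 0.0)


planted = membrane.PlantedField(thickness_field, tilt_field, 0.0,
                                footprint=footprint)
cfg = membrane.generate_defect_bilayer(planted, 400, box, seed=7)
cfg = descriptors.assign_leaflets(cfg)

g = grid.GridSpec.for_box(box)  # 1 Å cells, 2.6 Å ester stamp radius
thickness = descriptors.thickness_map(cfg, g, occupancy_fraction=0.0)
tilt = descriptors.tilt_map(cfg, g, occupancy_fraction=0.0)

cx, cy = g.cell_centers()
ring = tilt["outer"].mask & (np.hypot(cx - 80.0, cy - 80.0) < 24.0) \
    & (np.hypot(cx - 80.0, cy - 80.0) > 18.0)

print(f"bulk thickness        : {np.nanmax(thickness.values):.2f} A (planted 38)")
print(f"map minimum           : {thickness.nanmin():.2f} A (planted 38 - 8 = 30)")
print(f"tilt in the annulus   : {np.nanmean(tilt['outer'].values[ring]):.2f} deg "
      "(planted 60)")
# The map minimum sits at the planted defect: hydrophobic mismatch thins the
# bilayer locally, and the tilt annulus mimics lipids splaying around the
# exposed short helices of a membrane protein.
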