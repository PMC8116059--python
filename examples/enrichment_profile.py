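"""Preferential-solvation statistics around a planted DL-enrichment bump.

Plants a localized excess of short-chain (DL) lipids on a 20% DL background,
then computes the percent-enrichment map and the distance-resolved profile
(10 Å sliding shells) that quantifies how far the enrichment extends.
"""

import numpy as np

from memsolv import enrichment, grid, membrane

box = (96.0, 96.0, 100.0)
center = (68.0, 68.0)


def dl_fraction(x, y):
    dx, dy = x - center[0], y - center[1]
    return 0.2 + 0.3 * np.exp(-(dx**2 + dy**2) / (2 * 12.0**2))


# stack independent species draws as frames to accumulate occupancy
frames = []
for k in range(24):
    pf = membrane.PlantedField(38.0, 0.0, dl_fraction)
    c = membrane.generate_defect_bilayer(pf, 144, box, seed=100 + k)
    frames.append((float(k), c.frame(0)))
cfg = membrane.BeadConfiguration(frames, box)

g = grid.GridSpec.for_box(box)
occ = enrichment.species_occupancies(cfg, g)
print(f"bulk DL/PO occupancy ratio: {occ.bulk_ratio:.3f}")

anchor = membrane.PointAnchor(center, (box[0], box[1]))
profile = enrichment.enrichment_profile(occ, anchor,
                                        [5.0, 15.0, 25.0, 35.0, 45.0], width=10.0)
print("distance (A)   %E (DL enrichment vs bulk)")
for _, row in profile.table.iterrows():
    print(f"   {row.d:5.0f}       {row.pct_e:+7.1f}")
# %E > 0 marks shells where DL out-populates its bulk share: the planted bump
# (peak ratio 4x bulk) shows up only within ~2 sigma of its center, the same
# readout used to show short-chain lipids preferentially solvating a
# thinned-membrane defect.
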