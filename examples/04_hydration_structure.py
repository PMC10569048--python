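"""Hydration metrics: tetrahedral order S_g of a dense water box and
bound-water / hydrogen-bond counts in the R1 = 3.5 Å shell of a
duplex.

S_g = 0 is a perfect tetrahedral cage and random packing averages
0.25; a dense random box falls in between because excluded volume
induces partial ordering of the four nearest neighbours."""

import numpy as np

from helixatmos import (HelixSpec, LabeledStructure, TrajectoryWindow,
                        build_duplex_pair, place_waters)
from helixatmos import hydration

# dense bulk-like water box
empty = LabeledStructure(
    positions=np.empty((0, 3)), names=np.array([], dtype=object),
    resnames=np.array([], dtype=object), resids=np.array([], dtype=int),
    charges=np.empty(0), masses=np.empty(0),
    box=np.array([24.0, 24.0, 24.0]), groups={})
bulk = place_waters(empty, 320, seed=3, hard_core=2.4)
wb = TrajectoryWindow.single_frame(bulk)
sg, _ = hydration.tetrahedral_order(wb, axis_group=None)
print(f"bulk box: <S_g> = {np.nanmean(sg):.3f} "
      "(0 = tetrahedral cage, 0.25 = random directions)")

# hydration shell of a duplex pair
pair = build_duplex_pair(HelixSpec(n_bp=10), 2.8, 0.0,
                         np.array([80.0, 80.0, 34.0]), periodic_z=True)
solvated = place_waters(pair, 600, seed=5, hard_core=2.4)
wp = TrajectoryWindow.single_frame(solvated)
n_bound = hydration.bound_waters(wp, r1=3.5)[0]
n_hb = hydration.hydrogen_bonds(wp, region_cut=3.5)[0]
print(f"waters with surface distance <= 3.5 Å (R1): {n_bound:.0f} "
      f"of {600}")
print(f"water-water hydrogen bonds inside R1: {n_hb:.0f} "
      "(3.5 Å / 150° geometric criterion)")
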