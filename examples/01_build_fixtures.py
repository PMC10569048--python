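"""Build a parallel B-form duplex pair with a magnesium atmosphere and
write it to disk.

The pair sits at interhelical distance d = 2.8 nm (the condensed
state) with helix 2 rotated by θ = 0.25 rad; ions are drawn from a
0.05 M bulk.  The printed distance is re-measured from the generated
coordinates, confirming the construction."""

import numpy as np

from helixatmos import (HelixSpec, IonPlacementSpec, build_duplex_pair,
                        place_ions, write_structure)
from helixatmos.electro import interhelical_distance

box = np.array([118.0, 118.0, 68.0])      # Å, z-periodic helix repeat
pair = build_duplex_pair(HelixSpec(), separation=2.8, theta=0.25,
                         box=box, periodic_z=True)
pair = place_ions(pair, IonPlacementSpec(species="MG", valence=2,
                                         concentration=0.05, seed=1))

d = interhelical_distance(pair)
n_mg = pair.meta["placements"]["MG"]["count"]
write_structure(pair, "pair_mg.pdb")

print(f"atoms: {pair.n_atoms}  (phosphates carry -1e each)")
print(f"re-measured interhelical distance: {d:.6f} nm (built at 2.8)")
print(f"Mg2+ placed: {n_mg} (Poisson draw at 0.05 M in this box)")
print("wrote pair_mg.pdb (+ JSON sidecar with charges and groups)")
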