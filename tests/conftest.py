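"""Shared fixtures: small duplex pairs and free-atom boxes built by the
synthetic-data module at test time."""

import numpy as np
import pytest

from helixatmos import (HelixSpec, LabeledStructure, TrajectoryWindow,
                        build_duplex_pair)


def free_atoms(n, mass=24.0, box=50.0, name="NA", charge=0.0, seed=0):
    """A box of unconnected atoms (ion-like), for velocity/spectral
    fixtures."""
    rng = np.random.default_rng(seed)
    box3 = np.array([box] * 3, dtype=float)
    return LabeledStructure(
        positions=rng.uniform(0, box, size=(n, 3)),
        names=np.array([name] * n, dtype=object),
        resnames=np.array(["ION"] * n, dtype=object),
        resids=np.arange(n) + 1,
        charges=np.full(n, charge), masses=np.full(n, mass),
        box=box3, groups={f"ion:{name}": np.arange(n)})


@pytest.fixture
def box118():
    return np.array([118.0, 118.0, 68.0])


@pytest.fixture
def duplex_pair(box118):
    """20-bp pair at the condensed-state geometry (d = 2.8 nm,
    θ = 0.25 rad) under z-periodicity."""
    return build_duplex_pair(HelixSpec(), 2.8, 0.25, box118,
                             periodic_z=True)


@pytest.fixture
def small_pair():
    """Cheap 10-bp pair in a tight box."""
    spec = HelixSpec(n_bp=10)
    return build_duplex_pair(spec, 2.8, 0.0,
                             np.array([80.0, 80.0, 34.0]),
                             periodic_z=True)


def single_frame(structure):
    return TrajectoryWindow.single_frame(structure)
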