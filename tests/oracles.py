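"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the surface oracle is a
plain Monte-Carlo surface integration, and the random clusters are built
directly from arrays.
"""

from __future__ import annotations

import numpy as np

from sapsa import Atom, Conformer, Topology

VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "H": 1.20, "S": 1.80}


def mc_accessible_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo probe-center surface integration, per atom.

    Uniform random directions on each atom's expanded sphere; a sample
    survives if it lies outside every other expanded sphere.
    """
    R = np.asarray(radii, dtype=float) + probe
    n_atoms = len(R)
    areas = np.zeros(n_atoms)
    for i in range(n_atoms):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + R[i] * v
        buried = np.zeros(n_samples, dtype=bool)
        for j in range(n_atoms):
            if j == i:
                continue
            buried |= np.sum((pts - coords[j]) ** 2, axis=1) < R[j] ** 2
        areas[i] = (1.0 - buried.mean()) * 4.0 * np.pi * R[i] ** 2
    return areas


def random_cluster(rng: np.random.Generator, n_atoms: int = 6, box: float = 2.5):
    """A random unbonded atom cluster as a fully typed Conformer."""
    coords = rng.uniform(-box, box, size=(n_atoms, 3))
    elements = rng.choice(list(VDW), size=n_atoms)
    atoms = [Atom(k, e, f"{e}{k}") for k, e in enumerate(elements)]
    topology = Topology(atoms=atoms, bonds=set())
    for a in topology.atoms:
        a.radius = VDW[a.element]
        a.is_polar = a.element in ("N", "O")
    return Conformer(topology=topology, coordinates=coords), np.array(
        [VDW[e] for e in elements]
    )
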