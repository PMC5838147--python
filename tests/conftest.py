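import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from sapsa import Atom, Conformer, Ensemble, RadiusTable, Topology, classify_polarity


@pytest.fixture(scope="session")
def bondi():
    return RadiusTable.bondi()


def _typed(topology: Topology, table: RadiusTable) -> Topology:
    for a in topology.atoms:
        a.radius = table[a.element]
    classify_polarity(topology)
    return topology


@pytest.fixture
def amide_fragment(bondi):
    """A minimal amide-like fragment: C-C(=O)-N(-H)-C with methyl hydrogens.

    Atom order: C0(methyl C), H1, H2, H3 (on C0), C4(carbonyl), O5, N6, H7(amide).
    """
    atoms = [
        Atom(0, "C", "CM"),
        Atom(1, "H", "HM1"),
        Atom(2, "H", "HM2"),
        Atom(3, "H", "HM3"),
        Atom(4, "C", "C"),
        Atom(5, "O", "O"),
        Atom(6, "N", "N"),
        Atom(7, "H", "HN"),
    ]
    bonds = {(0, 1), (0, 2), (0, 3), (0, 4), (4, 5), (4, 6), (6, 7)}
    top = Topology(atoms=atoms, bonds=bonds)
    return _typed(top, bondi)


@pytest.fixture
def amide_conformer(amide_fragment):
    coords = np.array(
        [
            [0.00, 0.00, 0.00],  # CM
            [-0.51, 0.89, -0.36],
            [-0.51, -0.89, -0.36],
            [0.00, 0.00, 1.09],
            [1.50, 0.00, -0.50],  # C
            [2.20, 0.95, -0.30],  # O
            [1.95, -1.15, -1.05],  # N
            [2.92, -1.20, -1.25],  # HN
        ]
    )
    return Conformer(topology=amide_fragment, coordinates=coords)


@pytest.fixture
def amide_ensemble(amide_conformer):
    """Three slightly shifted frames of the amide fragment."""
    frames = []
    for k, dx in enumerate((0.0, 0.05, -0.05)):
        c = amide_conformer.coordinates.copy()
        c[:, 0] += dx
        frames.append(
            Conformer(topology=amide_conformer.topology, coordinates=c, frame_index=k)
        )
    return Ensemble(topology=amide_conformer.topology, frames=frames)
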