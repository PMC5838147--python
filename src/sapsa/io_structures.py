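"""Conformational-ensemble I/O and atom typing.

Molecules are represented by a lightweight :class:`Topology` (atoms + bonds)
shared by all frames of an :class:`Ensemble`.  Atom typing assigns van der
Waals radii from a :class:`RadiusTable` (Bondi values by default) and marks
polarity: nitrogen, oxygen, and every hydrogen bonded to one of them count as
polar.  Polarity of a hydrogen therefore depends on bonding, which is why
bond information (CONECT records, an explicit bond file, or distance-based
inference) is resolved before classification.

Multi-model PDB files are read and written through Biopython (``Bio.PDB``);
one MODEL block corresponds to one conformer.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.Atom import Atom as _BioAtom
from Bio.PDB.Chain import Chain as _BioChain
from Bio.PDB.Model import Model as _BioModel
from Bio.PDB.Residue import Residue as _BioResidue
from Bio.PDB.Structure import Structure as _BioStructure
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Topology",
    "Conformer",
    "Ensemble",
    "RadiusTable",
    "BONDI_RADII",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "infer_bonds",
    "classify_polarity",
    "assign_radii",
    "load_ensemble",
]

#: Bondi van der Waals radii (Angstrom) for the elements that occur in
#: peptides; shipped as the explicit default of :class:`RadiusTable`.
BONDI_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "H": 1.20, "S": 1.80}

#: Default scale factor for distance-based bond inference:
#: i and j are bonded iff d_ij <= scale * (r_i + r_j) + tolerance.
BOND_SCALE: float = 0.6


@dataclass
class Atom:
    """One atom of a topology.

    ``radius`` is assigned from a :class:`RadiusTable`; ``is_polar`` is set
    only by :func:`classify_polarity` because hydrogen polarity depends on
    the bonded heavy atom.
    """

    index: int
    element: str
    name: str
    residue_name: str = "UNK"
    residue_index: int = 1
    radius: float | None = None
    is_polar: bool | None = None


@dataclass
class Topology:
    """Ordered atoms plus an (unordered-pair) bond set."""

    atoms: list[Atom]
    bonds: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.bonds = {_canon(b) for b in self.bonds}

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def validate(self) -> None:
        n = self.n_atoms
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
        for atom in self.atoms:
            if atom.element == "H" and len(self.bonded_to(atom.index)) != 1:
                raise ValueError(
                    f"hydrogen atom {atom.index} ({atom.name}) must have exactly "
                    f"one bond, found {len(self.bonded_to(atom.index))}"
                )

    def bonded_to(self, i: int) -> list[int]:
        """Indices bonded to atom ``i``."""
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def heavy_indices(self) -> np.ndarray:
        return np.array([a.index for a in self.atoms if a.element != "H"], dtype=int)


def _canon(pair: Iterable[int]) -> tuple[int, int]:
    i, j = pair
    return (int(min(i, j)), int(max(i, j)))


@dataclass
class Conformer:
    """A single coordinate frame over a shared topology (Angstrom)."""

    topology: Topology
    coordinates: np.ndarray
    frame_index: int = 0
    time_ps: float | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate shape {self.coordinates.shape} does not match "
                f"{self.topology.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")


@dataclass
class Ensemble:
    """An ordered set of conformers sharing one topology."""

    topology: Topology
    frames: list[Conformer]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("ensemble requires at least one frame")
        for f in self.frames:
            if f.topology is not self.topology and f.topology.n_atoms != self.topology.n_atoms:
                raise ValueError("all frames must share the ensemble topology")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array."""
        return np.stack([f.coordinates for f in self.frames])


class RadiusTable(Mapping[str, float]):
    """Element -> van der Waals radius (Angstrom).

    The table must be explicit: every element looked up at compute time has
    to be present, otherwise a ``KeyError`` with the offending element is
    raised.  ``RadiusTable.bondi()`` gives the standard Bondi set.
    """

    def __init__(self, radii: Mapping[str, float], bond_scale: float = BOND_SCALE):
        for el, r in radii.items():
            if r <= 0:
                raise ValueError(f"radius for {el} must be positive, got {r}")
        self._radii = dict(radii)
        self.bond_scale = float(bond_scale)

    @classmethod
    def bondi(cls) -> "RadiusTable":
        return cls(BONDI_RADII)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RadiusTable":
        """Load ``{radii: {element: r}, bond_scale: s}`` (or a bare mapping)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "radii" in data:
            return cls(data["radii"], data.get("bond_scale", BOND_SCALE))
        return cls(data)

    @classmethod
    def default(cls) -> "RadiusTable":
        """The packaged Bondi configuration file."""
        ref = resources.files("sapsa").joinpath("data/bondi_radii.yaml")
        data = yaml.safe_load(ref.read_text())
        return cls(data["radii"], data.get("bond_scale", BOND_SCALE))

    def __getitem__(self, element: str) -> float:
        try:
            return self._radii[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} is not in the radius table "
                f"(known: {sorted(self._radii)})"
            ) from None

    def __iter__(self):
        return iter(self._radii)

    def __len__(self) -> int:
        return len(self._radii)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    """Heuristic element from a PDB atom name when the element column is blank."""
    stripped = name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    if stripped[0].isdigit():  # e.g. 1HB
        stripped = stripped.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _parse_conect(path: str | Path) -> set[tuple[int, int]]:
    """Serial-number bond pairs from CONECT records (Bio.PDB discards them)."""
    bonds: set[tuple[int, int]] = set()
    with open(path) as fh:
        for line in fh:
            if not line.startswith("CONECT"):
                continue
            fields = line[6:].split()
            if len(fields) < 2:
                continue
            center = int(fields[0])
            for other in fields[1:]:
                bonds.add(_canon((center, int(other))))
    return bonds


def read_multimodel_pdb(path: str | Path) -> Ensemble:
    """Read a (multi-)MODEL PDB file into an :class:`Ensemble`.

    Each MODEL becomes one frame, in file order; a file without MODEL
    records yields a single-frame ensemble.  Elements come from the element
    column when present, with an atom-name fallback.  CONECT records, if
    any, populate the topology bonds (serials are mapped to 0-based indices
    of the first model).

    Raises
    ------
    ValueError
        If models disagree in atom count (the offending model is named) or
        an element cannot be determined.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models found in {path}")

    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    first_atoms = list(models[0].get_atoms())
    for idx, bio_atom in enumerate(first_atoms):
        element = (bio_atom.element or "").strip()
        if not element or element == "X":
            element = _element_from_name(bio_atom.get_name())
        element = element.capitalize()
        residue = bio_atom.get_parent()
        atoms.append(
            Atom(
                index=idx,
                element=element,
                name=bio_atom.get_name(),
                residue_name=residue.get_resname().strip(),
                residue_index=residue.get_id()[1],
            )
        )
        serial_to_index[bio_atom.get_serial_number()] = idx

    conect = _parse_conect(path)
    bonds = {
        _canon((serial_to_index[i], serial_to_index[j]))
        for i, j in conect
        if i in serial_to_index and j in serial_to_index
    }
    topology = Topology(atoms=atoms, bonds=bonds)

    frames: list[Conformer] = []
    n_expected = len(first_atoms)
    for m_i, model in enumerate(models):
        coords = np.array([a.get_coord() for a in model.get_atoms()], dtype=float)
        if coords.shape[0] != n_expected:
            raise ValueError(
                f"model {m_i + 1} has {coords.shape[0]} atoms, expected {n_expected}"
            )
        frames.append(Conformer(topology=topology, coordinates=coords, frame_index=m_i))

    return Ensemble(topology=topology, frames=frames, metadata={"source": str(path)})


def write_multimodel_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a standard MODEL/ENDMDL multi-model PDB.

    Coordinates are written at PDB precision (3 decimals); topology bonds
    are emitted as CONECT records so a round-trip preserves connectivity.
    """
    structure = _BioStructure("ens")
    for f_i, frame in enumerate(ensemble.frames):
        model = _BioModel(f_i, serial_num=f_i + 1)
        chain = _BioChain("A")
        model.add(chain)
        structure.add(model)
        residues: dict[int, _BioResidue] = {}
        for atom, xyz in zip(ensemble.topology.atoms, frame.coordinates):
            res_key = atom.residue_index
            if res_key not in residues:
                residue = _BioResidue((" ", res_key, " "), atom.residue_name, "")
                chain.add(residue)
                residues[res_key] = residue
            name = atom.name
            # PDB column alignment: single-letter elements start in column 14
            fullname = name if len(name) >= 4 else (" " + name).ljust(4)
            bio_atom = _BioAtom(
                name=name,
                coord=np.asarray(xyz, dtype=float),
                bfactor=0.0,
                occupancy=1.0,
                altloc=" ",
                fullname=fullname,
                serial_number=atom.index + 1,
                element=atom.element.upper(),
            )
            residues[res_key].add(bio_atom)

    io = PDBIO()
    io.set_structure(structure)
    io.save(str(path))

    if ensemble.topology.bonds:
        text = Path(path).read_text().rstrip("\n")
        lines = text.split("\n")
        end = lines.pop() if lines and lines[-1].startswith("END") else "END"
        for i, j in sorted(ensemble.topology.bonds):
            lines.append(f"CONECT{i + 1:5d}{j + 1:5d}")
        lines.append(end)
        Path(path).write_text("\n".join(lines) + "\n")


def read_bond_file(path: str | Path) -> set[tuple[int, int]]:
    """Two whitespace-separated integer columns of 0-based atom indices."""
    bonds = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, j = line.split()[:2]
            bonds.add(_canon((int(i), int(j))))
    return bonds


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

def assign_radii(topology: Topology, radius_table: RadiusTable) -> Topology:
    """Set every atom's vdW radius from the table (unknown element is an error)."""
    for atom in topology.atoms:
        atom.radius = radius_table[atom.element]
    return topology


def infer_bonds(
    conformer: Conformer,
    radius_table: RadiusTable,
    tolerance: float = 0.0,
) -> set[tuple[int, int]]:
    """Distance-based bond inference.

    A pair (i, j) is bonded iff ``d_ij <= scale * (r_i + r_j) + tolerance``
    with the table's vdW radii and its ``bond_scale`` (default 0.6).  Every
    hydrogen must end with exactly one bond, otherwise a ``ValueError``
    names the atom — ambiguous structures need CONECT records or an explicit
    bond file instead.
    """
    atoms = conformer.topology.atoms
    radii = np.array([radius_table[a.element] for a in atoms])
    coords = conformer.coordinates
    scale = radius_table.bond_scale

    tree = cKDTree(coords)
    cutoff = scale * 2.0 * radii.max() + tolerance
    bonds: set[tuple[int, int]] = set()
    for i, j in tree.query_pairs(cutoff):
        d = np.linalg.norm(coords[i] - coords[j])
        if d <= scale * (radii[i] + radii[j]) + tolerance:
            bonds.add(_canon((i, j)))

    counts = {a.index: 0 for a in atoms}
    for i, j in bonds:
        counts[i] += 1
        counts[j] += 1
    for atom in atoms:
        if atom.element == "H" and counts[atom.index] != 1:
            raise ValueError(
                f"hydrogen atom {atom.index} ({atom.name}) has "
                f"{counts[atom.index]} inferred bonds; supply CONECT records "
                "or an explicit bond file"
            )
    return bonds


def classify_polarity(topology: Topology) -> Topology:
    """Mark polar atoms: all N, all O, and every H bonded to an N or O.

    Carbon, sulfur and carbon-bound hydrogens are apolar.  Pure rule on the
    topology; requires bonds for the hydrogens.
    """
    has_h = any(a.element == "H" for a in topology.atoms)
    if has_h and not topology.bonds:
        raise ValueError("polarity classification requires bonds (hydrogens present)")
    by_index = {a.index: a for a in topology.atoms}
    for atom in topology.atoms:
        if atom.element in ("N", "O"):
            atom.is_polar = True
        elif atom.element == "H":
            neighbors = topology.bonded_to(atom.index)
            if len(neighbors) != 1:
                raise ValueError(
                    f"hydrogen atom {atom.index} must have exactly one bond"
                )
            atom.is_polar = by_index[neighbors[0]].element in ("N", "O")
        else:
            atom.is_polar = False
    return topology


def load_ensemble(
    path: str | Path,
    radius_table: RadiusTable | None = None,
    bond_file: str | Path | None = None,
    require_hydrogens: bool = True,
) -> Ensemble:
    """Read a multi-model PDB and fully type it for surface computation.

    Bond source precedence: CONECT records in the file, then an explicit
    ``bond_file``, then distance inference on the first frame.  Structures
    without hydrogens are rejected by default because the polar-hydrogen
    rule needs them; protonation is out of scope.
    """
    table = radius_table or RadiusTable.default()
    ensemble = read_multimodel_pdb(path)
    topology = ensemble.topology

    if require_hydrogens and not any(a.element == "H" for a in topology.atoms):
        raise ValueError(
            f"{path} contains no hydrogen atoms; the polar-hydrogen rule "
            "requires an explicitly protonated structure"
        )

    assign_radii(topology, table)
    if not topology.bonds:
        if bond_file is not None:
            topology.bonds = read_bond_file(bond_file)
        else:
            topology.bonds = infer_bonds(ensemble.frames[0], table)
    topology.validate()
    classify_polarity(topology)
    return ensemble
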