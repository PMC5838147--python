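"""Synthetic conformer-ensemble generators.

Two generators back the surface/ensemble pipeline with controllable,
seeded test data:

* :func:`sample_ensemble` — a torsional Metropolis Monte-Carlo chain with a
  deliberately minimal, non-physical energy (soft-sphere clash penalty plus
  a hydrogen-bond-count reward).  Its only contract is to produce
  topologically valid, reproducible, conformationally diverse ensembles; it
  does not emulate any force field.
* :func:`make_two_state_fixture` — a hand-built mini-molecule whose single
  polar nitrogen is occluded by a mobile apolar carbon in a "shielded"
  state and clear of it in an "exposed" state, with states drawn i.i.d.
  The ensemble-mean SAPSA therefore has the closed form
  ``p * A_exposed + (1 - p) * A_shielded`` where both state areas are
  directly computable, which makes ensemble averaging testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .io_structures import (
    Atom,
    Conformer,
    Ensemble,
    RadiusTable,
    Topology,
    classify_polarity,
)

__all__ = [
    "SamplerConfig",
    "sample_ensemble",
    "make_two_state_fixture",
    "two_state_conformers",
    "make_decomposition_pair",
]

_KB = 0.0019872041  # Boltzmann constant in the sampler's kcal/mol-style units

#: Provenance record of the molecular-dynamics protocol this sampler stands
#: in for (implicit-solvent Langevin dynamics); metadata only, never used.
EMULATED_MD = {
    "length_ns": 20,
    "n_conformations": 20000,
    "dielectric": 80,
    "friction_per_ps": 1.0,
    "temperature_K": 300,
}


@dataclass
class SamplerConfig:
    """Torsional Metropolis Monte-Carlo settings.

    ``rotatable_bonds`` are bond pairs whose removal splits the molecule
    (ring torsions are rejected — cyclic-backbone moves are out of scope).
    The energy is non-physical by design; see module docstring.
    """

    seed: int
    n_frames: int
    temperature: float = 300.0
    torsion_step: float = 60.0  # max proposal rotation, degrees
    rotatable_bonds: list[tuple[int, int]] = field(default_factory=list)
    clash_energy_scale: float = 10.0
    hbond_reward: float = 1.0
    emulated_md: dict = field(default_factory=lambda: dict(EMULATED_MD))

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _downstream_atoms(topology: Topology, bond: tuple[int, int]) -> np.ndarray:
    """Atoms on the j-side of bond (i, j); error if the bond is in a ring."""
    g = nx.Graph()
    g.add_nodes_from(range(topology.n_atoms))
    g.add_edges_from(topology.bonds)
    i, j = bond
    if not g.has_edge(i, j):
        raise ValueError(f"rotatable bond ({i},{j}) is not a bond of the topology")
    g.remove_edge(i, j)
    if nx.has_path(g, i, j):
        raise ValueError(
            f"bond ({i},{j}) is part of a ring; ring torsions are not supported"
        )
    return np.array(sorted(nx.node_connected_component(g, j)), dtype=int)


def _clash_energy(
    coords: np.ndarray, radii: np.ndarray, bonded: set[tuple[int, int]], scale: float
) -> float:
    n = len(coords)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    thresh = 0.8 * (radii[:, None] + radii[None, :])
    overlap = np.maximum(0.0, thresh - d)
    iu = np.triu_indices(n, k=1)
    mask = np.ones(len(iu[0]), dtype=bool)
    for k, (i, j) in enumerate(zip(*iu)):
        if (i, j) in bonded:
            mask[k] = False
    return float(scale * np.sum(overlap[iu][mask] ** 2))


def _hbond_count(coords: np.ndarray, topology: Topology) -> int:
    """Donor-H ... acceptor (N/O) contacts closer than 2.5 Angstrom."""
    by_index = {a.index: a for a in topology.atoms}
    donors = []
    for a in topology.atoms:
        if a.element == "H":
            nb = topology.bonded_to(a.index)
            if nb and by_index[nb[0]].element in ("N", "O"):
                donors.append((a.index, nb[0]))
    acceptors = [a.index for a in topology.atoms if a.element in ("N", "O")]
    count = 0
    for h, heavy in donors:
        for acc in acceptors:
            if acc == heavy:
                continue
            if np.linalg.norm(coords[h] - coords[acc]) < 2.5:
                count += 1
    return count


def _energy(coords: np.ndarray, topology: Topology, radii: np.ndarray, config: SamplerConfig) -> float:
    e = _clash_energy(coords, radii, topology.bonds, config.clash_energy_scale)
    if config.hbond_reward:
        e -= config.hbond_reward * _hbond_count(coords, topology)
    return e


def sample_ensemble(start: Conformer, config: SamplerConfig) -> Ensemble:
    """Run the Metropolis torsion chain and record every step as a frame.

    One random torsion rotation is proposed per step and accepted with
    probability ``min(1, exp(-dE/kT))``.  The chain is fully reproducible
    from ``config.seed``.
    """
    topology = start.topology
    if any(a.radius is None for a in topology.atoms):
        raise ValueError("all atoms need radii before sampling")
    radii = np.array([a.radius for a in topology.atoms], dtype=float)
    downstream = [_downstream_atoms(topology, b) for b in config.rotatable_bonds]

    rng = np.random.default_rng(config.seed)
    coords = start.coordinates.copy()
    energy = _energy(coords, topology, radii, config)
    kt = _KB * config.temperature

    frames: list[Conformer] = []
    n_accept = 0
    for step in range(config.n_frames):
        if config.rotatable_bonds:
            b_i = rng.integers(len(config.rotatable_bonds))
            i, j = config.rotatable_bonds[b_i]
            angle = np.deg2rad(rng.uniform(-config.torsion_step, config.torsion_step))
            axis = coords[j] - coords[i]
            axis /= np.linalg.norm(axis)
            rot = Rotation.from_rotvec(angle * axis)
            proposal = coords.copy()
            moved = downstream[b_i]
            proposal[moved] = rot.apply(proposal[moved] - coords[i]) + coords[i]
            e_new = _energy(proposal, topology, radii, config)
            if e_new <= energy or rng.random() < np.exp(-(e_new - energy) / kt):
                coords = proposal
                energy = e_new
                n_accept += 1
        frames.append(Conformer(topology=topology, coordinates=coords.copy(), frame_index=step))

    metadata = {
        "sampler": "torsional-metropolis",
        "seed": config.seed,
        "n_frames": config.n_frames,
        "temperature_K": config.temperature,
        "torsion_step_deg": config.torsion_step,
        "acceptance_rate": n_accept / max(1, config.n_frames),
        "emulated_md": dict(config.emulated_md),
    }
    return Ensemble(topology=topology, frames=frames, metadata=metadata)


# ---------------------------------------------------------------------------
# Two-state fixture
# ---------------------------------------------------------------------------

def _two_state_topology(table: RadiusTable) -> Topology:
    """C0 anchor; polar N1-H2; mobile apolar occluder C3 bonded to C0."""
    atoms = [
        Atom(0, "C", "C0"),
        Atom(1, "N", "N1"),
        Atom(2, "H", "H2"),
        Atom(3, "C", "C3"),
    ]
    topology = Topology(atoms=atoms, bonds={(0, 1), (1, 2), (0, 3)})
    for a in topology.atoms:
        a.radius = table[a.element]
    classify_polarity(topology)
    return topology


def _shield_distance(delta_area: float, R_n: float, R_c: float) -> float:
    """Occluder center distance from N giving a spherical cap of ``delta_area``
    on N's expanded sphere: A_cap = 2 pi R_n (R_n - (d^2 + R_n^2 - R_c^2)/(2d))."""
    c = R_n - delta_area / (2.0 * np.pi * R_n)
    disc = c * c - R_n * R_n + R_c * R_c
    if disc <= 0:
        raise ValueError("delta_area too large for this geometry")
    return c + np.sqrt(disc)


def two_state_conformers(
    delta_area: float = 30.0,
    radius_table: RadiusTable | None = None,
    probe_radius: float = 1.4,
) -> tuple[Conformer, Conformer]:
    """(exposed, shielded) conformers of the two-state mini-molecule.

    In the shielded state the occluder carbon sits above the nitrogen at
    the center distance whose spherical cap on the nitrogen's probe-center
    sphere equals ``delta_area`` (the realized SAPSA gap also includes
    partial occlusion of the amide hydrogen, so compute the state areas with
    the surface engine rather than relying on ``delta_area`` exactly).
    The fixture's geometry is synthetic, not chemically sensible.
    """
    table = radius_table or RadiusTable.default()
    topology = _two_state_topology(table)
    n_pos = np.array([1.47, 0.0, 0.0])
    base = np.array(
        [
            [0.0, 0.0, 0.0],  # C0
            n_pos,  # N1
            n_pos + np.array([0.94, 0.37, 0.0]),  # H2 (~1.01 A from N)
            [0.0, 0.0, 0.0],  # C3, set per state
        ]
    )
    exposed = base.copy()
    exposed[3] = np.array([-3.0, 0.0, 0.0])  # far side of the anchor

    R_n = table["N"] + probe_radius
    R_c = table["C"] + probe_radius
    d = _shield_distance(delta_area, R_n, R_c)
    shielded = base.copy()
    shielded[3] = n_pos + np.array([0.0, d, 0.0])

    return (
        Conformer(topology=topology, coordinates=exposed, frame_index=0),
        Conformer(topology=topology, coordinates=shielded, frame_index=1),
    )


def make_two_state_fixture(
    p_exposed: float,
    delta_area: float = 30.0,
    n_frames: int = 1000,
    seed: int = 0,
    radius_table: RadiusTable | None = None,
) -> Ensemble:
    """i.i.d. two-state ensemble with exposure probability ``p_exposed``.

    The expected ensemble-mean SAPSA is the mixture
    ``p * A_exposed + (1 - p) * A_shielded``; compute the two state areas
    with :func:`sapsa.surface.conformer_surface` on the conformers returned
    by :func:`two_state_conformers`.
    """
    if not 0.0 <= p_exposed <= 1.0:
        raise ValueError("p_exposed must be in [0, 1]")
    exposed, shielded = two_state_conformers(delta_area, radius_table)
    rng = np.random.default_rng(seed)
    states = rng.random(n_frames) < p_exposed
    frames = [
        Conformer(
            topology=exposed.topology,
            coordinates=(exposed if s else shielded).coordinates.copy(),
            frame_index=k,
        )
        for k, s in enumerate(states)
    ]
    return Ensemble(
        topology=exposed.topology,
        frames=frames,
        metadata={
            "source": "two-state fixture",
            "p_exposed": p_exposed,
            "delta_area": delta_area,
            "seed": seed,
            "states_exposed": states.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# Paired fixtures for the truncation decomposition
# ---------------------------------------------------------------------------

def _methyl_positions(cg: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """Three H positions around a terminal methyl carbon (1.09 A, tetrahedral-ish)."""
    axis = cg - cb
    axis /= np.linalg.norm(axis)
    # any perpendicular pair
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    perp2 = np.cross(axis, perp)
    hs = []
    for k in range(3):
        ang = 2.0 * np.pi * k / 3.0
        direction = 0.34 * axis + 0.94 * (np.cos(ang) * perp + np.sin(ang) * perp2)
        hs.append(cg + 1.09 * direction / np.linalg.norm(direction))
    return np.array(hs)


def make_decomposition_pair(
    n_frames: int = 400,
    seed: int = 0,
    p_exposed_A: float = 0.2,
    p_exposed_B: float = 0.8,
    delta_area: float = 30.0,
    radius_table: RadiusTable | None = None,
) -> tuple[Ensemble, Ensemble, int]:
    """Ensembles (A, B) plus A's truncation target for decomposition tests.

    Molecule A carries a terminal ethyl-like arm (Cb-Cg(H3)) kept far from
    the polar nitrogen in every frame, so trimming the methyl has almost no
    direct shielding effect; A and B differ mainly in how often the mobile
    occluder shields the nitrogen (``p_exposed_A`` vs ``p_exposed_B``),
    emulating a terminal group that acts through the conformer distribution
    rather than through direct occlusion.  B's topology equals A's after
    the CH3 -> H edit (same atom order).
    """
    table = radius_table or RadiusTable.default()
    exposed, shielded = two_state_conformers(delta_area, table)
    core_top = exposed.topology

    cb = np.array([0.0, -1.54, 0.0])
    cg = np.array([0.0, -3.08, 0.0])
    h_on_cb_end = cb + np.array([0.0, -1.09, 0.0])  # B's hydrogen in place of Cg

    def build_A() -> tuple[Topology, np.ndarray, np.ndarray]:
        atoms = [
            Atom(0, "C", "C0"),
            Atom(1, "N", "N1"),
            Atom(2, "H", "H2"),
            Atom(3, "C", "C3"),
            Atom(4, "C", "CB"),
            Atom(5, "C", "CG"),
            Atom(6, "H", "HG1"),
            Atom(7, "H", "HG2"),
            Atom(8, "H", "HG3"),
        ]
        bonds = {(0, 1), (1, 2), (0, 3), (0, 4), (4, 5), (5, 6), (5, 7), (5, 8)}
        top = Topology(atoms=atoms, bonds=bonds)
        for a in top.atoms:
            a.radius = table[a.element]
        classify_polarity(top)
        hs = _methyl_positions(cg, cb)
        ex = np.vstack([exposed.coordinates, cb, cg, hs])
        sh = np.vstack([shielded.coordinates, cb, cg, hs])
        return top, ex, sh

    def build_B() -> tuple[Topology, np.ndarray, np.ndarray]:
        atoms = [
            Atom(0, "C", "C0"),
            Atom(1, "N", "N1"),
            Atom(2, "H", "H2"),
            Atom(3, "C", "C3"),
            Atom(4, "C", "CB"),
            Atom(5, "H", "HB"),
        ]
        bonds = {(0, 1), (1, 2), (0, 3), (0, 4), (4, 5)}
        top = Topology(atoms=atoms, bonds=bonds)
        for a in top.atoms:
            a.radius = table[a.element]
        classify_polarity(top)
        ex = np.vstack([exposed.coordinates, cb, h_on_cb_end])
        sh = np.vstack([shielded.coordinates, cb, h_on_cb_end])
        return top, ex, sh

    rng = np.random.default_rng(seed)

    def assemble(top, ex, sh, p) -> Ensemble:
        states = rng.random(n_frames) < p
        frames = [
            Conformer(topology=top, coordinates=(ex if s else sh).copy(), frame_index=k)
            for k, s in enumerate(states)
        ]
        return Ensemble(
            topology=top,
            frames=frames,
            metadata={"source": "decomposition fixture", "p_exposed": p, "seed": seed},
        )

    top_a, ex_a, sh_a = build_A()
    top_b, ex_b, sh_b = build_B()
    ens_a = assemble(top_a, ex_a, sh_a, p_exposed_A)
    ens_b = assemble(top_b, ex_b, sh_b, p_exposed_B)
    return ens_a, ens_b, 5  # atom 5 (CG) is the truncation target
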