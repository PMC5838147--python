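"""Ensemble-level SAPSA statistics, conformer clustering, and the
side-chain truncation decomposition.

The decomposition separates the SAPSA difference between two molecules that
differ by one terminal group (e.g. Abu vs Ala: one extra methyl) into

* a *direct shielding* component — recompute SAPSA on molecule A's own
  trajectory after editing the group away; any change is pure steric
  occlusion, because the scaffold geometry is untouched; and
* a *conformational* component — the remaining difference to molecule B's
  own ensemble, attributable to the group's influence on which scaffold
  conformations are populated.

By construction the two components sum exactly to mean(B) - mean(A).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .io_structures import Atom, Conformer, Ensemble, RadiusTable, Topology, classify_polarity
from .surface import SurfaceConfig, conformer_surface

__all__ = [
    "EnsembleSAPSA",
    "TruncationSpec",
    "DecompositionReport",
    "ensemble_sapsa",
    "truncate_side_chain",
    "decompose_side_chain_effect",
    "leader_cluster",
    "ClusterResult",
    "kabsch_rmsd",
]


@dataclass
class EnsembleSAPSA:
    """Time-averaged SAPSA of an ensemble with block statistics.

    ``mean``/``sd`` are over per-frame values (population sd, divisor n);
    blocks are consecutive non-overlapping windows of ``block_size`` frames
    (the last block may be short), giving the block-average series used for
    trajectory-convergence plots.
    """

    per_frame: np.ndarray
    mean: float
    sd: float
    block_size: int
    block_means: np.ndarray
    block_sds: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.per_frame)

    @property
    def block_sd_of_means(self) -> float:
        """Spread of the block means (population sd) — an alternative 'plus/minus'."""
        return float(np.std(self.block_means))

    def summary(self) -> str:
        lines = [
            "Ensemble SAPSA",
            f"  frames      : {self.n_frames}",
            f"  mean        : {self.mean:8.2f} A^2",
            f"  sd (frames) : {self.sd:8.2f} A^2",
            f"  block size  : {self.block_size}",
            f"  blocks      : {len(self.block_means)}"
            f"  (sd of block means: {self.block_sd_of_means:.2f} A^2)",
        ]
        return "\n".join(lines)

    def blocks_frame(self):
        """Block series as a pandas DataFrame (block_index, mean, sd)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "block_index": np.arange(len(self.block_means)),
                "mean": self.block_means,
                "sd": self.block_sds,
            }
        )

    def plot_blocks(self, ax=None, **kwargs):
        """Errorbar plot of block means +/- block sds (matplotlib required)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(self.block_means))
        ax.errorbar(x, self.block_means, yerr=self.block_sds, fmt="o-", **kwargs)
        ax.set_xlabel("block")
        ax.set_ylabel("SAPSA ($\\AA^2$)")
        return ax


def ensemble_sapsa(
    ensemble: Ensemble,
    config: SurfaceConfig = SurfaceConfig(),
    block_size: int = 1000,
) -> EnsembleSAPSA:
    """Per-frame SAPSA over the whole ensemble plus block statistics.

    The default block of 1000 frames corresponds to 1 ns when 20,000 frames
    span 20 ns of sampling.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    per_frame = np.array(
        [conformer_surface(frame, config).sapsa for frame in ensemble.frames]
    )
    n = len(per_frame)
    n_blocks = int(np.ceil(n / block_size))
    block_means = np.empty(n_blocks)
    block_sds = np.empty(n_blocks)
    for b in range(n_blocks):
        window = per_frame[b * block_size : (b + 1) * block_size]
        block_means[b] = window.mean()
        block_sds[b] = window.std()
    return EnsembleSAPSA(
        per_frame=per_frame,
        mean=float(per_frame.mean()),
        sd=float(per_frame.std()),
        block_size=block_size,
        block_means=block_means,
        block_sds=block_sds,
    )


@dataclass(frozen=True)
class TruncationSpec:
    """Replace a terminal heavy atom (and its hydrogens) by a single atom.

    The canonical use is trimming a terminal CH3 to H, converting an Abu
    side chain into an Ala side chain on the parent molecule's own
    trajectory.
    """

    target_atom: int
    replacement_element: str = "H"
    new_bond_length: float = 1.09  # standard C-H, Angstrom


def _heavy_neighbors(topology: Topology, i: int) -> list[int]:
    by_index = {a.index: a for a in topology.atoms}
    return [j for j in topology.bonded_to(i) if by_index[j].element != "H"]


def truncate_side_chain(
    ensemble: Ensemble,
    spec: TruncationSpec,
    radius_table: RadiusTable | None = None,
) -> Ensemble:
    """Apply the terminal-group edit to every frame of an ensemble.

    In each frame the hydrogens bonded to the target atom are deleted, the
    target's element is changed to the replacement (radius from the table,
    polarity re-derived), and the target is repositioned along the bond
    vector from its single heavy neighbor at ``new_bond_length``.  All other
    coordinates are untouched, so the scaffold geometry of every conformer
    is preserved exactly.
    """
    table = radius_table or RadiusTable.default()
    topology = ensemble.topology
    by_index = {a.index: a for a in topology.atoms}
    target = by_index[spec.target_atom]

    heavy = _heavy_neighbors(topology, target.index)
    if len(heavy) != 1:
        raise ValueError(
            f"target atom {target.index} ({target.name}) is not terminal: "
            f"{len(heavy)} heavy-atom neighbors"
        )
    anchor = heavy[0]
    if spec.replacement_element not in table:
        raise KeyError(
            f"replacement element {spec.replacement_element!r} absent from radius table"
        )

    doomed = {
        j for j in topology.bonded_to(target.index) if by_index[j].element == "H"
    }
    keep = [a.index for a in topology.atoms if a.index not in doomed]
    remap = {old: new for new, old in enumerate(keep)}

    new_atoms: list[Atom] = []
    for old in keep:
        a = by_index[old]
        if old == target.index:
            new_atoms.append(
                Atom(
                    index=remap[old],
                    element=spec.replacement_element,
                    name=spec.replacement_element + a.name[1:],
                    residue_name=a.residue_name,
                    residue_index=a.residue_index,
                    radius=table[spec.replacement_element],
                )
            )
        else:
            new_atoms.append(
                Atom(
                    index=remap[old],
                    element=a.element,
                    name=a.name,
                    residue_name=a.residue_name,
                    residue_index=a.residue_index,
                    radius=a.radius,
                )
            )
    new_bonds = {
        (remap[i], remap[j])
        for i, j in topology.bonds
        if i not in doomed and j not in doomed
    }
    new_topology = Topology(atoms=new_atoms, bonds=new_bonds)
    new_topology.validate()
    classify_polarity(new_topology)

    keep_arr = np.array(keep, dtype=int)
    t_new = remap[target.index]
    a_new = remap[anchor]
    new_frames = []
    for frame in ensemble.frames:
        coords = frame.coordinates[keep_arr].copy()
        bond = coords[t_new] - coords[a_new]
        norm = np.linalg.norm(bond)
        if norm == 0:
            raise ValueError("degenerate bond geometry at truncation site")
        coords[t_new] = coords[a_new] + bond / norm * spec.new_bond_length
        new_frames.append(
            Conformer(
                topology=new_topology,
                coordinates=coords,
                frame_index=frame.frame_index,
                time_ps=frame.time_ps,
            )
        )

    metadata = copy.deepcopy(ensemble.metadata)
    metadata.setdefault("edits", []).append(
        {
            "op": "truncate_side_chain",
            "target_atom": spec.target_atom,
            "replacement_element": spec.replacement_element,
            "new_bond_length": spec.new_bond_length,
            "removed_hydrogens": sorted(doomed),
        }
    )
    return Ensemble(topology=new_topology, frames=new_frames, metadata=metadata)


@dataclass
class DecompositionReport:
    """Shielding-vs-conformation split of a terminal-group SAPSA effect."""

    sapsa_A: EnsembleSAPSA
    sapsa_B: EnsembleSAPSA
    sapsa_A_truncated: EnsembleSAPSA
    direct_shielding_component: float
    conformational_component: float

    def summary(self) -> str:
        total = self.sapsa_B.mean - self.sapsa_A.mean
        return "\n".join(
            [
                "Side-chain SAPSA decomposition (A^2)",
                f"  mean SAPSA A            : {self.sapsa_A.mean:8.2f}",
                f"  mean SAPSA A, truncated : {self.sapsa_A_truncated.mean:8.2f}",
                f"  mean SAPSA B            : {self.sapsa_B.mean:8.2f}",
                f"  direct shielding        : {self.direct_shielding_component:8.2f}",
                f"  conformational          : {self.conformational_component:8.2f}",
                f"  total (B - A)           : {total:8.2f}",
            ]
        )


def decompose_side_chain_effect(
    ensemble_A: Ensemble,
    ensemble_B: Ensemble,
    spec: TruncationSpec,
    config: SurfaceConfig = SurfaceConfig(),
    block_size: int = 1000,
    radius_table: RadiusTable | None = None,
) -> DecompositionReport:
    """Split mean(B) - mean(A) into direct shielding and conformational parts.

    ``truncate_side_chain(ensemble_A, spec)`` must give B's topology (same
    element sequence); otherwise the first differing atom is reported.
    """
    truncated = truncate_side_chain(ensemble_A, spec, radius_table)
    elems_t = [a.element for a in truncated.topology.atoms]
    elems_b = [a.element for a in ensemble_B.topology.atoms]
    if elems_t != elems_b:
        for k, (et, eb) in enumerate(zip(elems_t, elems_b)):
            if et != eb:
                raise ValueError(
                    f"post-edit topology differs from B at atom {k}: {et} vs {eb}"
                )
        raise ValueError(
            f"post-edit topology has {len(elems_t)} atoms, B has {len(elems_b)}"
        )

    s_a = ensemble_sapsa(ensemble_A, config, block_size)
    s_b = ensemble_sapsa(ensemble_B, config, block_size)
    s_t = ensemble_sapsa(truncated, config, block_size)
    return DecompositionReport(
        sapsa_A=s_a,
        sapsa_B=s_b,
        sapsa_A_truncated=s_t,
        direct_shielding_component=s_t.mean - s_a.mean,
        conformational_component=s_b.mean - s_t.mean,
    )


# ---------------------------------------------------------------------------
# Conformer clustering
# ---------------------------------------------------------------------------

def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Best-fit (optimally superposed) RMSD between two coordinate sets."""
    import warnings

    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    with warnings.catch_warnings():
        # identical structures give rssd ~ 0 and a benign uniqueness warning
        warnings.simplefilter("ignore", UserWarning)
        _, rssd = Rotation.align_vectors(xc, yc)
    return float(rssd / np.sqrt(len(x)))


@dataclass
class ClusterResult:
    """Leader-clustering output on an ensemble."""

    labels: np.ndarray  # cluster id per frame
    leaders: list[int]  # frame index of each cluster's leader
    dominant_cluster: int
    representative_frame: int

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)


def leader_cluster(ensemble: Ensemble, rmsd_cutoff: float = 1.0) -> ClusterResult:
    """Leader clustering on heavy-atom best-fit RMSD, in frame order.

    Each frame joins the first existing cluster whose leader is within the
    cutoff, else starts a new cluster.  The dominant cluster is the largest;
    its representative is the member with minimal mean RMSD to the other
    members.  Deterministic given the frame order.
    """
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd_cutoff must be positive")
    heavy = ensemble.topology.heavy_indices()
    coords = [f.coordinates[heavy] for f in ensemble.frames]

    leaders: list[int] = []
    labels = np.empty(len(coords), dtype=int)
    for f_i, c in enumerate(coords):
        for c_i, leader in enumerate(leaders):
            if kabsch_rmsd(c, coords[leader]) <= rmsd_cutoff:
                labels[f_i] = c_i
                break
        else:
            leaders.append(f_i)
            labels[f_i] = len(leaders) - 1

    sizes = np.bincount(labels)
    dominant = int(sizes.argmax())
    members = np.flatnonzero(labels == dominant)
    if len(members) == 1:
        representative = int(members[0])
    else:
        mean_rmsd = [
            np.mean([kabsch_rmsd(coords[m], coords[o]) for o in members if o != m])
            for m in members
        ]
        representative = int(members[int(np.argmin(mean_rmsd))])

    return ClusterResult(
        labels=labels,
        leaders=leaders,
        dominant_cluster=dominant,
        representative_frame=representative,
    )
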