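"""Ensemble statistics, truncation editing, decomposition, clustering."""

import numpy as np
import pytest

from sapsa import (
    Conformer,
    Ensemble,
    RadiusTable,
    SurfaceConfig,
    TruncationSpec,
    conformer_surface,
    decompose_side_chain_effect,
    ensemble_sapsa,
    leader_cluster,
    make_two_state_fixture,
    truncate_side_chain,
)
from sapsa.conformer_synth import make_decomposition_pair, two_state_conformers
from sapsa.ensemble_tools import kabsch_rmsd

FAST = SurfaceConfig(n_sphere_points=240)


class TestEnsembleSAPSA:
    def test_mean_and_population_sd(self):
        ens = make_two_state_fixture(p_exposed=0.5, n_frames=12, seed=3)
        stats = ensemble_sapsa(ens, FAST, block_size=4)
        per_frame = np.array(
            [conformer_surface(f, FAST).sapsa for f in ens.frames]
        )
        assert stats.mean == pytest.approx(per_frame.mean())
        assert stats.sd == pytest.approx(per_frame.std())  # divisor n

    def test_two_frame_arithmetic(self):
        # frames with known per-frame areas: mean and sd follow directly
        ens = make_two_state_fixture(p_exposed=1.0, n_frames=1, seed=0)
        exposed, shielded = two_state_conformers()
        a_e = conformer_surface(exposed, FAST).sapsa
        a_s = conformer_surface(shielded, FAST).sapsa
        frames = [
            Conformer(topology=ens.topology, coordinates=exposed.coordinates, frame_index=0),
            Conformer(topology=ens.topology, coordinates=shielded.coordinates, frame_index=1),
        ]
        stats = ensemble_sapsa(
            Ensemble(topology=ens.topology, frames=frames), FAST, block_size=2
        )
        assert stats.mean == pytest.approx((a_e + a_s) / 2)
        assert stats.sd == pytest.approx(abs(a_e - a_s) / 2)

    def test_single_frame_sd_zero(self):
        ens = make_two_state_fixture(p_exposed=1.0, n_frames=1, seed=0)
        stats = ensemble_sapsa(ens, FAST)
        assert stats.sd == 0.0
        assert len(stats.block_means) == 1

    def test_block_partition(self):
        ens = make_two_state_fixture(p_exposed=0.5, n_frames=20, seed=1)
        stats = ensemble_sapsa(ens, FAST, block_size=5)
        assert len(stats.block_means) == 4
        for b in range(4):
            assert stats.block_means[b] == pytest.approx(
                stats.per_frame[5 * b : 5 * b + 5].mean()
            )

    def test_equal_blocks_average_to_global_mean(self):
        ens = make_two_state_fixture(p_exposed=0.3, n_frames=20, seed=2)
        stats = ensemble_sapsa(ens, FAST, block_size=5)
        assert stats.block_means.mean() == pytest.approx(stats.mean)

    def test_bad_block_size(self):
        ens = make_two_state_fixture(p_exposed=0.5, n_frames=4, seed=0)
        with pytest.raises(ValueError):
            ensemble_sapsa(ens, FAST, block_size=0)

    def test_blocks_frame_and_summary(self):
        ens = make_two_state_fixture(p_exposed=0.5, n_frames=10, seed=0)
        stats = ensemble_sapsa(ens, FAST, block_size=5)
        df = stats.blocks_frame()
        assert list(df.columns) == ["block_index", "mean", "sd"]
        assert "mean" in stats.summary()


class TestTruncation:
    def test_methyl_to_hydrogen_bookkeeping(self):
        ens_a, _, target = make_decomposition_pair(n_frames=3, seed=0)
        edited = truncate_side_chain(ens_a, TruncationSpec(target_atom=target))
        # 3 methyl H removed, C->H swap keeps one atom: net -3 atoms... the
        # swap retains the atom, so count drops by exactly the hydrogens
        assert edited.topology.n_atoms == ens_a.topology.n_atoms - 3
        assert edited.topology.atoms[target].element == "H"
        assert edited.topology.atoms[target].radius == RadiusTable.default()["H"]
        assert edited.metadata["edits"][0]["op"] == "truncate_side_chain"

    def test_new_hydrogen_placed_on_old_bond_vector(self):
        ens_a, _, target = make_decomposition_pair(n_frames=2, seed=0)
        spec = TruncationSpec(target_atom=target)
        edited = truncate_side_chain(ens_a, spec)
        anchor = 4  # CB
        for f_old, f_new in zip(ens_a.frames, edited.frames):
            old_bond = f_old.coordinates[target] - f_old.coordinates[anchor]
            new_bond = f_new.coordinates[target] - f_new.coordinates[anchor]
            assert np.linalg.norm(new_bond) == pytest.approx(1.09)
            cos = np.dot(old_bond, new_bond) / (
                np.linalg.norm(old_bond) * np.linalg.norm(new_bond)
            )
            assert cos == pytest.approx(1.0)
            # all surviving non-target coordinates untouched
            np.testing.assert_array_equal(
                f_new.coordinates[:target], f_old.coordinates[:target]
            )

    def test_non_terminal_target_rejected(self):
        ens_a, _, _ = make_decomposition_pair(n_frames=1, seed=0)
        with pytest.raises(ValueError, match="not terminal"):
            truncate_side_chain(ens_a, TruncationSpec(target_atom=0))

    def test_unknown_replacement_element_rejected(self):
        ens_a, _, target = make_decomposition_pair(n_frames=1, seed=0)
        with pytest.raises(KeyError):
            truncate_side_chain(
                ens_a, TruncationSpec(target_atom=target, replacement_element="Zz")
            )

    def test_truncation_never_decreases_per_frame_sapsa(self):
        ens_a, _, target = make_decomposition_pair(n_frames=6, seed=4)
        edited = truncate_side_chain(ens_a, TruncationSpec(target_atom=target))
        for f_a, f_t in zip(ens_a.frames, edited.frames):
            assert (
                conformer_surface(f_t, FAST).sapsa
                >= conformer_surface(f_a, FAST).sapsa - 1e-9
            )


class TestDecomposition:
    def test_components_sum_to_total_difference(self):
        ens_a, ens_b, target = make_decomposition_pair(n_frames=12, seed=5)
        report = decompose_side_chain_effect(
            ens_a, ens_b, TruncationSpec(target_atom=target), FAST, block_size=6
        )
        total = report.sapsa_B.mean - report.sapsa_A.mean
        assert (
            report.direct_shielding_component + report.conformational_component
            == pytest.approx(total, abs=1e-9)
        )

    def test_self_comparison_has_zero_conformational_component(self):
        ens_a, _, target = make_decomposition_pair(n_frames=5, seed=6)
        spec = TruncationSpec(target_atom=target)
        truncated = truncate_side_chain(ens_a, spec)
        report = decompose_side_chain_effect(ens_a, truncated, spec, FAST, block_size=5)
        assert report.conformational_component == pytest.approx(0.0, abs=1e-9)

    def test_remote_methyl_effect_is_conformational(self):
        # methyl never contacts the polar atoms: direct ~ 0, the full
        # difference comes from the altered state populations
        ens_a, ens_b, target = make_decomposition_pair(
            n_frames=60, seed=7, p_exposed_A=0.2, p_exposed_B=0.8
        )
        report = decompose_side_chain_effect(
            ens_a, ens_b, TruncationSpec(target_atom=target), FAST, block_size=30
        )
        total = report.sapsa_B.mean - report.sapsa_A.mean
        assert total > 5.0
        assert abs(report.direct_shielding_component) < 0.15 * total
        assert report.conformational_component == pytest.approx(
            total - report.direct_shielding_component
        )

    def test_topology_mismatch_names_first_differing_atom(self):
        ens_a, _, target = make_decomposition_pair(n_frames=2, seed=0)
        with pytest.raises(ValueError, match="atom"):
            decompose_side_chain_effect(
                ens_a, ens_a, TruncationSpec(target_atom=target), FAST, block_size=2
            )


class TestLeaderClustering:
    def test_identical_frames_form_one_cluster(self):
        ens = make_two_state_fixture(p_exposed=1.0, n_frames=8, seed=0)
        result = leader_cluster(ens, rmsd_cutoff=0.5)
        assert result.sizes.tolist() == [8]
        assert result.dominant_cluster == 0

    def test_two_state_mixture_gives_two_clusters(self):
        ens = make_two_state_fixture(p_exposed=0.7, n_frames=40, seed=9)
        result = leader_cluster(ens, rmsd_cutoff=0.5)
        states = np.array(ens.metadata["states_exposed"])
        assert len(result.sizes) == 2
        assert result.sizes.sum() == 40
        assert result.sizes.max() == max(states.sum(), (~states).sum())
        # representative belongs to the dominant cluster
        assert result.labels[result.representative_frame] == result.dominant_cluster

    def test_deterministic_given_frame_order(self):
        ens = make_two_state_fixture(p_exposed=0.5, n_frames=20, seed=10)
        r1 = leader_cluster(ens, rmsd_cutoff=0.5)
        r2 = leader_cluster(ens, rmsd_cutoff=0.5)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_bad_cutoff(self):
        ens = make_two_state_fixture(p_exposed=0.5, n_frames=2, seed=0)
        with pytest.raises(ValueError):
            leader_cluster(ens, rmsd_cutoff=0.0)


def test_kabsch_rmsd_zero_for_rigidly_moved_copy():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(7, 3))
    from scipy.spatial.transform import Rotation

    y = Rotation.from_rotvec([0.4, 0.2, -1.0]).apply(x) + [3.0, -2.0, 1.0]
    assert kabsch_rmsd(x, y) == pytest.approx(0.0, abs=1e-9)
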