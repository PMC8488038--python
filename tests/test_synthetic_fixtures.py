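"""Fixture generator: substrate topologies, planted ensembles, oracles
and frame-count bookkeeping."""

import dataclasses

import numpy as np
import pytest

from msper.errors import DataError, DegenerateGroupError
from msper.model import ConformationalEnsemble
from msper.pose_classification import classify_ensemble, partition_groups
from msper.contact_scoring import (
    difference_map,
    group_contact_rates,
    residue_scores,
)
from msper.ranking_aggregation import aggregate_ranks, rank_residues
from msper.synthetic_fixtures import (
    PlantedEnsembleSpec,
    brute_force_contacts,
    build_substrate_topology,
    default_fixture_config,
    frame_count,
    generate_planted_ensemble,
)


class TestTopologies:
    @pytest.mark.parametrize(
        "name,n_atoms,n_hydrogens",
        [("limonene", 26, 16), ("p-cymene", 24, 14)],
    )
    def test_builtin_atom_and_hydrogen_counts(self, name, n_atoms, n_hydrogens):
        topo = build_substrate_topology(name)
        assert topo.n_atoms == n_atoms
        assert len(topo.hydrogen_labels()) == n_hydrogens
        assert len(topo.heavy_indices()) == n_atoms - n_hydrogens

    def test_named_hydrogens_present(self):
        limonene = set(build_substrate_topology("limonene").hydrogen_labels())
        assert {"H6b", "H3a", "H9b", "H2"} <= limonene
        cymene = set(build_substrate_topology("p-cymene").hydrogen_labels())
        assert {"H3", "H5"} <= cymene

    def test_custom_benzene_spec(self):
        import math

        coords, names, elements, bonds = [], [], [], []
        for k in range(6):
            a = math.radians(60 * k)
            coords.append([1.4 * math.cos(a), 1.4 * math.sin(a), 0.0])
            names.append(f"C{k + 1}")
            elements.append("C")
            bonds.append((k, (k + 1) % 6))
        for k in range(6):
            a = math.radians(60 * k)
            coords.append([2.5 * math.cos(a), 2.5 * math.sin(a), 0.0])
            names.append(f"H{k + 1}")
            elements.append("H")
            bonds.append((k, 6 + k))
        topo = build_substrate_topology(
            {
                "name": "benzene",
                "atom_names": names,
                "elements": elements,
                "coords": np.array(coords),
                "bonds": bonds,
            }
        )
        assert topo.n_atoms == 12
        assert topo.parent_of("H3") == 2

    def test_unknown_name_rejected(self):
        with pytest.raises(DataError, match="unknown substrate"):
            build_substrate_topology("caffeine")

    def test_disconnected_bond_graph_rejected(self):
        with pytest.raises(DataError, match="not connected"):
            build_substrate_topology(
                {
                    "name": "broken",
                    "atom_names": ["C1", "C2"],
                    "elements": ["C", "C"],
                    "coords": np.zeros((2, 3)),
                    "bonds": [],
                }
            )


class TestPlantedEnsembles:
    def test_same_seed_is_bit_identical(self):
        spec = PlantedEnsembleSpec(seed=7, n_frames_per_group=5)
        a, _ = generate_planted_ensemble(spec)
        b, _ = generate_planted_ensemble(spec)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_different_seeds_differ(self):
        a, _ = generate_planted_ensemble(PlantedEnsembleSpec(seed=1, n_frames_per_group=5))
        b, _ = generate_planted_ensemble(PlantedEnsembleSpec(seed=2, n_frames_per_group=5))
        assert not np.array_equal(a.coordinates, b.coordinates)

    def test_zero_noise_scores_equal_heavy_atom_counts(self, clean_fixture):
        ensemble, truth, config = clean_fixture
        part = partition_groups(
            classify_ensemble(ensemble, config), config.target_hydrogen_labels
        )
        c_tp = group_contact_rates(ensemble, part.target_frames, config)
        c_bp = group_contact_rates(ensemble, part.byproduct_frames, config)
        scores = residue_scores(
            difference_map(c_bp, c_tp), ensemble.system
        )
        by_key = dict(zip(scores.residue_keys, scores.s_scr))
        n_by_key = dict(zip(scores.residue_keys, scores.n_heavy_atoms))
        for key in truth.planted:
            assert by_key[key] == n_by_key[key]  # C_bp=1, C_tp=0
        for key in truth.anti:
            assert by_key[key] == -n_by_key[key]
        for key in truth.neutral:
            assert by_key[key] == 0

    def test_zero_noise_full_ranking_matches_expected_order(self, clean_fixture):
        ensemble, truth, config = clean_fixture
        part = partition_groups(
            classify_ensemble(ensemble, config), config.target_hydrogen_labels
        )
        c_tp = group_contact_rates(ensemble, part.target_frames, config)
        c_bp = group_contact_rates(ensemble, part.byproduct_frames, config)
        ranked = rank_residues(
            residue_scores(difference_map(c_bp, c_tp), ensemble.system)
        )
        assert [r.residue_key for r in ranked.records] == truth.expected_order

    def test_conflicting_planted_anti_request_rejected(self):
        with pytest.raises(DataError):
            PlantedEnsembleSpec(
                seed=0, target_label="H6b", byproduct_labels=("H6b",)
            )

    def test_unknown_hydrogen_label_rejected(self):
        with pytest.raises(DataError, match="not in"):
            generate_planted_ensemble(
                PlantedEnsembleSpec(seed=0, target_label="H77")
            )

    def test_recovery_degrades_monotonically_with_noise(self):
        """Mean top-|planted| overlap with ground truth is non-increasing
        in the noise amplitude (averaged over 20 seeds)."""
        noise_levels = [0.2, 2.0, 4.0]
        mean_overlap = []
        for noise in noise_levels:
            overlaps = []
            for seed in range(20):
                spec = PlantedEnsembleSpec(
                    seed=seed, n_frames_per_group=20, noise=noise
                )
                ensemble, truth = generate_planted_ensemble(spec)
                config = default_fixture_config()
                k = len(truth.planted)
                try:
                    part = partition_groups(
                        classify_ensemble(ensemble, config),
                        config.target_hydrogen_labels,
                    )
                except DegenerateGroupError:
                    # noise so large a pose group emptied: no recovery
                    overlaps.append(0.0)
                    continue
                c_tp = group_contact_rates(ensemble, part.target_frames, config)
                c_bp = group_contact_rates(ensemble, part.byproduct_frames, config)
                ranked = rank_residues(
                    residue_scores(difference_map(c_bp, c_tp), ensemble.system)
                )
                overlaps.append(len(ranked.top(k) & set(truth.planted)) / k)
            mean_overlap.append(np.mean(overlaps))
        assert mean_overlap[0] >= mean_overlap[1] >= mean_overlap[2]
        assert mean_overlap[0] == 1.0

    def test_two_replicates_reproduce_planted_order(self):
        """The two-replicate protocol at toy scale: independently seeded
        replicates, aggregated ranks recover the planted order."""
        rankings = []
        for seed in (31, 32):
            spec = PlantedEnsembleSpec(seed=seed, n_frames_per_group=40, noise=0.2)
            ensemble, truth = generate_planted_ensemble(spec)
            config = default_fixture_config()
            part = partition_groups(
                classify_ensemble(ensemble, config), config.target_hydrogen_labels
            )
            c_tp = group_contact_rates(ensemble, part.target_frames, config)
            c_bp = group_contact_rates(ensemble, part.byproduct_frames, config)
            rankings.append(
                rank_residues(
                    residue_scores(difference_map(c_bp, c_tp), ensemble.system)
                )
            )
        agg = aggregate_ranks(rankings)
        n_p, n_a = len(truth.planted), len(truth.anti)
        assert set(agg.residue_keys[:n_p]) == set(truth.planted)
        assert set(agg.residue_keys[-n_a:]) == set(truth.anti)


class TestBruteForceOracle:
    def test_single_frame_equals_contact_indicator(self, clean_fixture):
        from msper.contact_scoring import contact_indicator

        ensemble, _, config = clean_fixture
        system = ensemble.system
        enz_idx, out = brute_force_contacts(
            dataclasses.replace(
                ensemble,
                coordinates=ensemble.coordinates[:1],
                weights=np.ones(1),
            ),
            config,
        )
        sub_idx = system.substrate_heavy_indices()
        frame = ensemble.coordinates[0]
        for a, i in enumerate(enz_idx):
            expected = contact_indicator(
                frame[i],
                system.elements[i],
                frame[sub_idx],
                [system.elements[j] for j in sub_idx],
                config.radii,
                config.contact_tolerance,
            )
            assert out[0, a] == expected

    def test_large_instance_guard(self, clean_fixture):
        ensemble, _, config = clean_fixture
        tiled = ConformationalEnsemble(
            system=ensemble.system,
            coordinates=np.broadcast_to(
                ensemble.coordinates[0],
                (60_000, ensemble.system.n_atoms, 3),
            ).copy(),
            weights=np.ones(60_000),
        )
        with pytest.raises(DataError, match="1e7"):
            brute_force_contacts(tiled, config)


class TestFrameCount:
    @pytest.mark.parametrize(
        "args,expected",
        [((10, 2, 72), 360_000), ((10, 2, 1), 5_000), ((1, 1, 1), 1_000)],
    )
    def test_output_conformation_counts(self, args, expected):
        assert frame_count(*args) == expected

    def test_non_divisible_interval_rejected(self):
        with pytest.raises(DataError, match="not divisible"):
            frame_count(1, 3, 1)

    def test_non_positive_arguments_rejected(self):
        with pytest.raises(DataError):
            frame_count(0, 2, 1)
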