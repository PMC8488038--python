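"""Contact rates, difference maps and residue scores: worked examples,
brute-force oracle equivalence and the algebraic invariants."""

import dataclasses

import numpy as np
import pytest

from conftest import toy_complex, toy_ensemble

from msper.errors import DataError
from msper.model import VdWRadiiTable
from msper.contact_scoring import (
    contact_indicator,
    difference_map,
    ensemble_contact_indicators,
    group_contact_rates,
    residue_scores,
)
from msper.pose_classification import classify_ensemble, partition_groups
from msper.synthetic_fixtures import (
    brute_force_contacts,
    default_fixture_config,
)


RADII = VdWRadiiTable()


class TestContactIndicator:
    def test_far_apart_is_no_contact(self):
        assert (
            contact_indicator(
                np.zeros(3), "C", np.array([[100.0, 0, 0]]), ["C"], RADII, 1.0
            )
            == 0
        )

    def test_boundary_distance_is_no_contact(self):
        # threshold is strict: r_C + r_C + tol exactly is out
        d = RADII.radius("C") * 2 + 1.0
        assert (
            contact_indicator(
                np.zeros(3), "C", np.array([[d, 0, 0]]), ["C"], RADII, 1.0
            )
            == 0
        )

    def test_just_inside_table_threshold_is_contact(self):
        d = RADII.radius("C") * 2 + 1.0 - 0.01
        assert (
            contact_indicator(
                np.zeros(3), "C", np.array([[d, 0, 0]]), ["C"], RADII, 1.0
            )
            == 1
        )

    def test_threshold_uses_closest_substrate_atom_radius(self):
        # nearest atom is N (smaller radius than S); distance is inside
        # the C-S threshold but outside the C-N one, and the N decides
        d = RADII.radius("C") + RADII.radius("N") + 1.0 + 0.05
        coords = np.array([[d, 0.0, 0.0], [d + 0.1, 0.0, 0.0]])
        assert (
            contact_indicator(np.zeros(3), "C", coords, ["N", "S"], RADII, 1.0)
            == 0
        )

    def test_empty_substrate_rejected(self):
        with pytest.raises(DataError, match="empty"):
            contact_indicator(
                np.zeros(3), "C", np.empty((0, 3)), [], RADII, 1.0
            )


class TestGroupContactRates:
    def _two_atom_ensemble(self, contact_pattern, weights):
        """One enzyme C, one substrate C; contact iff pattern[i]."""
        system, base = toy_complex(
            {"H6b": (0.0, 0.0, 2.0)},
            substrate_heavy=[(0.0, 0.0, 6.0)],
            enzyme_atoms=[(1, (0.0, 0.0, 0.0))],
        )
        frames = np.stack([base] * len(contact_pattern))
        for i, c in enumerate(contact_pattern):
            frames[i, 0] = (0.0, 0.0, 4.0) if c else (0.0, 0.0, 60.0)
        return toy_ensemble(system, frames, weights)

    def test_unweighted_mean(self):
        ens = self._two_atom_ensemble([1, 0, 1, 0], [1, 1, 1, 1])
        c = group_contact_rates(ens, range(4), default_fixture_config())
        assert c.rates == pytest.approx([0.5])

    def test_weighted_mean(self):
        ens = self._two_atom_ensemble([1, 0], [3, 1])
        c = group_contact_rates(ens, range(2), default_fixture_config())
        assert c.rates == pytest.approx([0.75])

    def test_zero_total_weight_rejected(self):
        ens = self._two_atom_ensemble([1, 0], [1, 0])
        with pytest.raises(DataError, match="zero total weight"):
            group_contact_rates(ens, [1], default_fixture_config())

    def test_empty_frame_set_rejected(self):
        ens = self._two_atom_ensemble([1, 0], [1, 1])
        with pytest.raises(DataError, match="empty"):
            group_contact_rates(ens, [], default_fixture_config())


class TestOracleEquivalence:
    def test_vectorised_contacts_match_brute_force_bit_exactly(self, noisy_fixture):
        ensemble, _, config = noisy_fixture
        enz_idx, fast = ensemble_contact_indicators(ensemble, config)
        enz_idx_bf, slow = brute_force_contacts(ensemble, config)
        np.testing.assert_array_equal(enz_idx, enz_idx_bf)
        np.testing.assert_array_equal(fast, slow)

    def test_rates_match_brute_force_recomputation(self, noisy_fixture):
        ensemble, _, config = noisy_fixture
        part = partition_groups(
            classify_ensemble(ensemble, config), config.target_hydrogen_labels
        )
        _, slow = brute_force_contacts(ensemble, config)
        for frames in (part.target_frames, part.byproduct_frames):
            c = group_contact_rates(ensemble, frames, config)
            w = ensemble.weights[frames]
            expected = (slow[frames] * w[:, None]).sum(axis=0) / w.sum()
            np.testing.assert_allclose(c.rates, expected, atol=1e-12)


class TestDifferenceMap:
    def _maps(self, ensemble, config):
        part = partition_groups(
            classify_ensemble(ensemble, config), config.target_hydrogen_labels
        )
        c_tp = group_contact_rates(ensemble, part.target_frames, config, "target")
        c_bp = group_contact_rates(ensemble, part.byproduct_frames, config, "byproduct")
        return c_tp, c_bp

    def test_subtraction_and_antisymmetry(self, clean_fixture):
        ensemble, _, config = clean_fixture
        c_tp, c_bp = self._maps(ensemble, config)
        d = difference_map(c_bp, c_tp)
        np.testing.assert_allclose(d.values, c_bp.rates - c_tp.rates, atol=0)
        d_swapped = difference_map(c_tp, c_bp)
        np.testing.assert_array_equal(d_swapped.values, -d.values)

    def test_identical_maps_give_zero(self, clean_fixture):
        ensemble, _, config = clean_fixture
        c_tp, _ = self._maps(ensemble, config)
        d = difference_map(c_tp, c_tp)
        assert np.all(d.values == 0)

    def test_atom_set_mismatch_rejected(self, clean_fixture):
        ensemble, _, config = clean_fixture
        c_tp, c_bp = self._maps(ensemble, config)
        shrunk = dataclasses.replace(
            c_tp, atom_indices=c_tp.atom_indices[:-1], rates=c_tp.rates[:-1]
        )
        with pytest.raises(DataError, match="different atom sets"):
            difference_map(c_bp, shrunk)


class TestResidueScores:
    def test_sums_match_pandas_groupby_oracle(self, noisy_fixture):
        import pandas as pd

        ensemble, _, config = noisy_fixture
        system = ensemble.system
        part = partition_groups(
            classify_ensemble(ensemble, config), config.target_hydrogen_labels
        )
        c_tp = group_contact_rates(ensemble, part.target_frames, config)
        c_bp = group_contact_rates(ensemble, part.byproduct_frames, config)
        d = difference_map(c_bp, c_tp)
        table = residue_scores(d, system)
        oracle = (
            pd.DataFrame(
                {
                    "key": [system.residue_keys[i] for i in d.atom_indices],
                    "d": d.values,
                }
            )
            .groupby("key")["d"]
            .sum()
        )
        for key, s in zip(table.residue_keys, table.s_scr):
            assert s == pytest.approx(oracle[key], abs=1e-12)

    def test_all_zero_difference_gives_all_zero_scores(self, clean_fixture):
        ensemble, _, config = clean_fixture
        c_tp = group_contact_rates(ensemble, [0], config)
        d = difference_map(c_tp, c_tp)
        table = residue_scores(d, ensemble.system)
        assert np.all(table.s_scr == 0)


class TestInvariants:
    def _pipeline_outputs(self, ensemble, config):
        part = partition_groups(
            classify_ensemble(ensemble, config), config.target_hydrogen_labels
        )
        c_tp = group_contact_rates(ensemble, part.target_frames, config)
        c_bp = group_contact_rates(ensemble, part.byproduct_frames, config)
        d = difference_map(c_bp, c_tp)
        s = residue_scores(d, ensemble.system)
        return c_tp, c_bp, d, s, part

    def test_bounds(self, noisy_fixture):
        ensemble, _, config = noisy_fixture
        c_tp, c_bp, d, s, _ = self._pipeline_outputs(ensemble, config)
        for c in (c_tp, c_bp):
            assert np.all((c.rates >= 0) & (c.rates <= 1))
        assert np.all((d.values >= -1) & (d.values <= 1))
        assert np.all(np.abs(s.s_scr) <= s.n_heavy_atoms + 1e-12)

    @pytest.mark.parametrize("k", [0.1, 3.0, 1e6])
    def test_weight_scale_invariance(self, noisy_fixture, k):
        ensemble, _, config = noisy_fixture
        _, _, d, s, _ = self._pipeline_outputs(ensemble, config)
        scaled = toy_ensemble(
            ensemble.system, ensemble.coordinates, ensemble.weights * k
        )
        _, _, d2, s2, _ = self._pipeline_outputs(scaled, config)
        np.testing.assert_allclose(d2.values, d.values, atol=1e-12)
        np.testing.assert_allclose(s2.s_scr, s.s_scr, atol=1e-12)

    def test_frame_permutation_invariance(self, noisy_fixture):
        ensemble, _, config = noisy_fixture
        _, _, d, s, _ = self._pipeline_outputs(ensemble, config)
        perm = np.random.default_rng(3).permutation(ensemble.n_frames)
        shuffled = toy_ensemble(
            ensemble.system,
            ensemble.coordinates[perm],
            ensemble.weights[perm],
        )
        _, _, d2, s2, _ = self._pipeline_outputs(shuffled, config)
        np.testing.assert_allclose(d2.values, d.values, atol=1e-12)
        np.testing.assert_allclose(s2.s_scr, s.s_scr, atol=1e-12)

    def test_partition_swap_antisymmetry(self, noisy_fixture):
        ensemble, _, config = noisy_fixture
        _, _, d, s, part = self._pipeline_outputs(ensemble, config)
        # feed the groups in swapped: target frames as "byproduct"
        c_tp = group_contact_rates(ensemble, part.byproduct_frames, config)
        c_bp = group_contact_rates(ensemble, part.target_frames, config)
        d_sw = difference_map(c_bp, c_tp)
        s_sw = residue_scores(d_sw, ensemble.system)
        np.testing.assert_array_equal(d_sw.values, -d.values)
        np.testing.assert_array_equal(s_sw.s_scr, -s.s_scr)
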