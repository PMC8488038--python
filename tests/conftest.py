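"""Shared builders and fixtures.

``toy_complex`` builds a minimal hand-positioned enzyme/substrate system
so unit tests can place atoms at exact distances; the planted-signal
fixtures come from the package's own generator.
"""

from __future__ import annotations

import numpy as np
import pytest

from msper.model import AtomRecord, ConformationalEnsemble, MolecularSystem
from msper.synthetic_fixtures import (
    PlantedEnsembleSpec,
    default_fixture_config,
    generate_planted_ensemble,
)


def toy_complex(
    hydrogen_positions: dict[str, tuple[float, float, float]],
    substrate_heavy: list[tuple[float, float, float]] | None = None,
    enzyme_atoms: list[tuple[int, tuple[float, float, float]]] | None = None,
):
    """Build (system, frame) with the active-site oxygen at the origin.

    ``hydrogen_positions`` maps reaction-site labels to coordinates;
    ``substrate_heavy`` lists substrate carbon positions;
    ``enzyme_atoms`` lists (residue_number, position) enzyme carbons.
    """
    substrate_heavy = substrate_heavy or [(0.0, 0.0, 6.0)]
    enzyme_atoms = enzyme_atoms or []
    atoms, coords = [], []
    idx = 0
    for resnum, pos in enzyme_atoms:
        atoms.append(
            AtomRecord(idx, f"C{idx + 1}", "C", ("A", resnum, ""), "PKT",
                       "enzyme", False)
        )
        coords.append(pos)
        idx += 1
    atoms.append(
        AtomRecord(idx, "O1", "O", ("A", 999, ""), "HEM", "cofactor", False)
    )
    coords.append((0.0, 0.0, 0.0))
    active = idx
    idx += 1
    for pos in substrate_heavy:
        atoms.append(
            AtomRecord(idx, f"CS{idx}", "C", ("A", 900, ""), "LIG",
                       "substrate", False)
        )
        coords.append(pos)
        idx += 1
    hydrogens = []
    for label, pos in hydrogen_positions.items():
        atoms.append(
            AtomRecord(idx, label, "H", ("A", 900, ""), "LIG",
                       "substrate", True)
        )
        coords.append(pos)
        hydrogens.append((label, idx))
        idx += 1
    system = MolecularSystem(
        atoms, active_site_atom=active, reaction_site_hydrogens=hydrogens
    )
    return system, np.array(coords, dtype=float)


def toy_ensemble(system, frames, weights=None):
    frames = np.asarray(frames, dtype=float)
    if weights is None:
        weights = np.ones(frames.shape[0])
    return ConformationalEnsemble(
        system=system, coordinates=frames, weights=np.asarray(weights, float)
    )


@pytest.fixture(scope="session")
def clean_fixture():
    """Zero-noise planted ensemble: scores are exact integers."""
    spec = PlantedEnsembleSpec(seed=7, n_frames_per_group=10, noise=0.0)
    ensemble, truth = generate_planted_ensemble(spec)
    return ensemble, truth, default_fixture_config()


@pytest.fixture(scope="session")
def noisy_fixture():
    """Noisy planted ensemble with non-uniform weights; 150 frames."""
    spec = PlantedEnsembleSpec(
        seed=5, n_frames_per_group=50, noise=0.2, random_weights=True
    )
    ensemble, truth = generate_planted_ensemble(spec)
    return ensemble, truth, default_fixture_config()
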