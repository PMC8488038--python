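"""Core data model: atoms, molecular systems, conformational ensembles,
van der Waals radii tables and the analysis configuration.

A *residue key* is the triple ``(chain_id, residue_number, insertion_code)``
with 1-based residue numbers as printed in PDB files, so that names like
"CYS 400" or "F87" map directly onto keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError

#: (chain_id, residue_number, insertion_code)
ResidueKey = tuple[str, int, str]

ROLES = ("enzyme", "substrate", "cofactor", "solvent", "ion")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the enzyme-substrate system.

    ``role`` partitions the system into enzyme, substrate, cofactor,
    solvent and ion atoms; contact scoring only ever sees heavy atoms of
    the enzyme (and optionally cofactor) on one side and of the substrate
    on the other.
    """

    atom_index: int
    atom_name: str
    element: str
    residue_key: ResidueKey
    residue_name: str
    role: str
    is_hydrogen: bool

    def __post_init__(self) -> None:
        if not self.element:
            raise DataError(f"atom {self.atom_index}: empty element")
        if self.role not in ROLES:
            raise DataError(f"atom {self.atom_index}: unknown role {self.role!r}")
        if self.is_hydrogen != (self.element.upper() == "H"):
            raise DataError(
                f"atom {self.atom_index}: is_hydrogen inconsistent with "
                f"element {self.element!r}"
            )


class MolecularSystem:
    """Typed atom inventory plus the geometric anchors of the analysis:
    the single active-site atom (the heme-bound oxygen in the motivating
    system) and the labelled substrate reaction-site hydrogens."""

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        active_site_atom: int,
        reaction_site_hydrogens: Sequence[tuple[str, int]],
        excluded_residues: Iterable[ResidueKey] = (),
    ) -> None:
        self.atoms = list(atoms)
        self.active_site_atom = int(active_site_atom)
        self.reaction_site_hydrogens = [(str(l), int(i)) for l, i in reaction_site_hydrogens]
        self.excluded_residues = frozenset(excluded_residues)
        self._validate()
        self._index()

    def _validate(self) -> None:
        indices = [a.atom_index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise DataError("duplicate atom_index in system")
        if indices != list(range(len(self.atoms))):
            raise DataError("atom_index must be 0..n_atoms-1 in order")
        by_index = {a.atom_index: a for a in self.atoms}
        if self.active_site_atom not in by_index:
            raise DataError("active_site_atom index not present in system")
        if by_index[self.active_site_atom].role == "substrate":
            raise DataError("active_site_atom must not be a substrate atom")
        labels = [l for l, _ in self.reaction_site_hydrogens]
        if len(set(labels)) != len(labels):
            raise DataError("reaction-site hydrogen labels must be unique")
        for label, idx in self.reaction_site_hydrogens:
            if idx not in by_index:
                raise DataError(f"reaction-site hydrogen {label}: no atom {idx}")
            atom = by_index[idx]
            if atom.role != "substrate" or not atom.is_hydrogen:
                raise DataError(
                    f"reaction-site hydrogen {label} must be a substrate hydrogen"
                )

    def _index(self) -> None:
        n = len(self.atoms)
        self.elements = np.array([a.element.upper() for a in self.atoms])
        self.atom_names = np.array([a.atom_name for a in self.atoms])
        self.roles = np.array([a.role for a in self.atoms])
        self.is_hydrogen = np.array([a.is_hydrogen for a in self.atoms])
        self.residue_keys: list[ResidueKey] = [a.residue_key for a in self.atoms]
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self._heavy = ~self.is_hydrogen
        assert self.elements.shape == (n,)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def substrate_heavy_indices(self) -> np.ndarray:
        return np.where((self.roles == "substrate") & self._heavy)[0]

    def scored_atom_indices(self, include_cofactor: bool = False) -> np.ndarray:
        """Heavy atoms entering contact scoring: enzyme role, optionally
        plus cofactor heavy atoms (the active-site atom itself is never a
        candidate contact; it belongs to the cofactor by construction)."""
        mask = (self.roles == "enzyme") & self._heavy
        if include_cofactor:
            mask |= (self.roles == "cofactor") & self._heavy
        return np.where(mask)[0]

    def enzyme_residue_keys(self) -> list[ResidueKey]:
        """Ordered unique residue keys of enzyme-role atoms."""
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            if a.role == "enzyme" and a.residue_key not in seen:
                seen[a.residue_key] = None
        return list(seen)

    def residue_name_of(self, key: ResidueKey) -> str:
        for a in self.atoms:
            if a.residue_key == key:
                return a.residue_name
        raise KeyError(key)


@dataclass
class ConformationalEnsemble:
    """Frames of coordinates (Å) with one non-negative weight per frame.

    Weights are consumed as-is (e.g. reweighting factors of an
    enhanced-sampling run, or all ones for a plain trajectory or a set of
    crystal/docking poses); they are never normalised at I/O time since
    the contact rate is a weight ratio and hence scale invariant.
    """

    system: MolecularSystem
    coordinates: np.ndarray  # (n_frames, n_atoms, 3) in Å
    weights: np.ndarray  # (n_frames,)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise DataError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.system.n_atoms:
            raise DataError(
                f"coordinate array has {self.coordinates.shape[1]} atoms, "
                f"system has {self.system.n_atoms}"
            )
        if self.n_frames < 1:
            raise DataError("ensemble must contain at least one frame")
        if self.weights.shape != (self.n_frames,):
            raise DataError(
                f"{self.weights.size} weights for {self.n_frames} frames"
            )
        if np.any(self.weights < 0):
            raise DataError("negative frame weight")
        if self.weights.sum() <= 0:
            raise DataError("frame weights must not all be zero")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]


# Bondi (1964) van der Waals radii for main-group elements; transition
# metals (absent from Bondi) from Batsanov (2001). Fully overridable.
DEFAULT_VDW_RADII: Mapping[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "FE": 2.05,
    "ZN": 2.10,
    "CU": 2.00,
    "MN": 2.05,
    "SE": 1.90,
}

#: radius of the active-site oxygen used in the pose threshold (Å)
DEFAULT_ACTIVE_SITE_RADIUS = 1.48
#: radius of a substrate reaction-site hydrogen used in the pose threshold (Å)
DEFAULT_REACTIVE_HYDROGEN_RADIUS = 1.00


@dataclass
class VdWRadiiTable:
    """Element -> vdW radius (Å) with optional per-atom-name overrides.

    ``active_site_radius`` and ``reactive_hydrogen_radius`` are the two
    radii entering the docking-pose distance threshold; they are kept
    separate from the element table because the pose definition pins them
    (O 1.48 Å, H 1.00 Å) independently of whatever set is used for the
    enzyme/substrate heavy atoms.
    """

    by_element: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VDW_RADII)
    )
    by_atom_name: dict[str, float] = field(default_factory=dict)
    active_site_radius: float = DEFAULT_ACTIVE_SITE_RADIUS
    reactive_hydrogen_radius: float = DEFAULT_REACTIVE_HYDROGEN_RADIUS

    def __post_init__(self) -> None:
        for key, r in list(self.by_element.items()) + list(self.by_atom_name.items()):
            if not np.isfinite(r) or r <= 0:
                raise ConfigError(f"non-positive vdW radius for {key!r}: {r}")
        for special, r in (
            ("active_site_radius", self.active_site_radius),
            ("reactive_hydrogen_radius", self.reactive_hydrogen_radius),
        ):
            if not np.isfinite(r) or r <= 0:
                raise ConfigError(f"non-positive {special}: {r}")

    def radius(self, element: str, atom_name: Optional[str] = None) -> float:
        """Look up a radius; atom-name overrides win, element otherwise."""
        if atom_name is not None and atom_name in self.by_atom_name:
            return self.by_atom_name[atom_name]
        try:
            return self.by_element[element.upper()]
        except KeyError:
            raise DataError(f"element {element!r} missing from vdW radii table")

    def radii_for(self, system: MolecularSystem, indices: np.ndarray) -> np.ndarray:
        """Vector of radii for the given atom indices of a system."""
        return np.array(
            [
                self.radius(system.elements[i], system.atom_names[i])
                for i in np.asarray(indices, dtype=int)
            ]
        )


@dataclass(frozen=True)
class AtomSelector:
    """Selects a single named atom of a residue: chain + residue number
    (+ optional insertion code) + atom name."""

    chain: str
    resnum: int
    atom: str
    icode: str = ""

    def residue_key(self) -> ResidueKey:
        return (self.chain, self.resnum, self.icode)


@dataclass
class ReplicateInput:
    """One replicate ensemble source: structure path + optional weights."""

    path: str
    weights_path: Optional[str] = None


# Residue-name defaults for role classification; all overridable in config.
DEFAULT_SOLVENT_RESIDUES = ("HOH", "WAT", "SOL", "TIP3", "TIP4", "SPC")
DEFAULT_ION_RESIDUES = ("NA", "CL", "K", "MG", "ZN", "CA", "NA+", "CL-", "SOD", "CLA")
DEFAULT_COFACTOR_RESIDUES = ("HEM",)


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs beyond the coordinates themselves."""

    substrate_residues: tuple[str, ...]
    active_site: AtomSelector
    reaction_site_hydrogens: tuple[str, ...]
    target_hydrogen_labels: tuple[str, ...]
    pose_tolerance: float = 1.0
    contact_tolerance: float = 1.0
    radii: VdWRadiiTable = field(default_factory=VdWRadiiTable)
    excluded_residues: frozenset[ResidueKey] = frozenset()
    include_cofactor: bool = False
    cofactor_residues: tuple[str, ...] = DEFAULT_COFACTOR_RESIDUES
    solvent_residues: tuple[str, ...] = DEFAULT_SOLVENT_RESIDUES
    ion_residues: tuple[str, ...] = DEFAULT_ION_RESIDUES
    replicate_inputs: tuple[ReplicateInput, ...] = ()
    top_k: tuple[int, ...] = (5, 10)

    def __post_init__(self) -> None:
        if not self.reaction_site_hydrogens:
            raise ConfigError("reaction_site_hydrogens must be non-empty")
        if not self.target_hydrogen_labels:
            raise ConfigError("target_hydrogen_labels must be non-empty")
        declared = set(self.reaction_site_hydrogens)
        unknown = set(self.target_hydrogen_labels) - declared
        if unknown:
            raise ConfigError(
                f"target hydrogens not declared as reaction sites: {sorted(unknown)}"
            )
        if self.pose_tolerance < 0 or self.contact_tolerance < 0:
            raise ConfigError("tolerances must be >= 0")
        if not self.substrate_residues:
            raise ConfigError("substrate_residues must be non-empty")
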