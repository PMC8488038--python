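"""Self-contained synthetic inputs with known ground truth.

This module generates everything the rest of the package needs for
testing and demonstration, with no external data:

* idealized substrate topologies — (S)-(-)-limonene (10 C + 16 H) and
  p-cymene (10 C + 14 H) with the conventional per-carbon hydrogen
  labels (H6b, H3a, H9b, ...). Coordinates are idealized geometries;
  only interatomic distances matter to the contact analysis, so no
  chemistry toolkit is involved.
* a toy enzyme pocket: a handful of pseudo-residues of 1-5 carbon
  pseudo-atoms on a ring around the active site, small enough for
  exhaustive brute-force oracles.
* planted-signal ensembles: frames are built per pose group by rigidly
  orienting the substrate so the chosen reaction-site hydrogen points at
  the active-site oxygen, while designated residues are placed in
  substrate contact only in byproduct frames ("planted", expected top of
  the ranking) or only in target frames ("anti", expected bottom). With
  zero noise the substitution score of a planted residue is exactly its
  heavy-atom count, and the full pipeline must recover the planted
  order.
* a naive all-pairs contact oracle and MD frame-count bookkeeping.

All randomness flows from the single seed in the ensemble spec.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import DataError
from .model import (
    AnalysisConfig,
    AtomRecord,
    AtomSelector,
    ConformationalEnsemble,
    MolecularSystem,
    ResidueKey,
)
from .contact_scoring import contact_indicator
from .pose_classification import compute_pose_threshold

_EZ = np.array([0.0, 0.0, 1.0])


def _rotz(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise DataError("zero-length direction vector")
    return v / n


def _rotation_to(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v."""
    u, v = _unit(u), _unit(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any axis perpendicular to u
        axis = np.cross(u, _EZ if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0]))
        axis = _unit(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    k = axis / s
    kx = np.array(
        [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]]
    )
    return np.eye(3) + s * kx + (1 - c) * (kx @ kx)


def _perp(v: np.ndarray) -> np.ndarray:
    p = np.cross(v, _EZ)
    if np.linalg.norm(p) < 1e-8:
        p = np.cross(v, np.array([1.0, 0.0, 0.0]))
    return _unit(p)


def _methyl_hydrogens(c: np.ndarray, axis: np.ndarray) -> list[np.ndarray]:
    """Three staggered hydrogens around a methyl carbon whose bond from
    the attachment atom points along ``axis``."""
    axis = _unit(axis)
    p1 = _perp(axis)
    p2 = np.cross(axis, p1)
    out = []
    for phi in (0.0, 120.0, 240.0):
        a = math.radians(phi)
        d = 0.333 * axis + 0.943 * (math.cos(a) * p1 + math.sin(a) * p2)
        out.append(c + 1.09 * _unit(d))
    return out


@dataclass
class SubstrateTopology:
    """Explicit atom/bond/coordinate table for a substrate molecule."""

    name: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) idealized geometry, Å
    bonds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n = len(self.atom_names)
        if len(self.elements) != n or self.coords.shape != (n, 3):
            raise DataError("topology atom table shapes disagree")
        hlabels = self.hydrogen_labels()
        if len(set(hlabels)) != len(hlabels):
            raise DataError("duplicate hydrogen label in topology")
        # bond graph must be connected
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for a, b in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != n:
            raise DataError(f"topology {self.name}: bond graph not connected")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def hydrogen_labels(self) -> list[str]:
        return [nm for nm, el in zip(self.atom_names, self.elements) if el == "H"]

    def heavy_indices(self) -> list[int]:
        return [i for i, el in enumerate(self.elements) if el != "H"]

    def index_of(self, atom_name: str) -> int:
        return self.atom_names.index(atom_name)

    def parent_of(self, hydrogen_label: str) -> int:
        """Index of the heavy atom bonded to a hydrogen."""
        h = self.index_of(hydrogen_label)
        for a, b in self.bonds:
            if a == h and self.elements[b] != "H":
                return b
            if b == h and self.elements[a] != "H":
                return a
        raise DataError(f"hydrogen {hydrogen_label} has no heavy-atom bond")


def _build_limonene() -> SubstrateTopology:
    # six-membered ring C1..C6 (C1=C2 double bond), methyl C7 on C1,
    # isopropenyl C8(=C9)(C10) on C4; 16 hydrogens
    names: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []

    def add(name: str, element: str, pos: np.ndarray, bond_to: Optional[int] = None) -> int:
        names.append(name)
        elements.append(element)
        coords.append(np.asarray(pos, dtype=float))
        idx = len(names) - 1
        if bond_to is not None:
            bonds.append((bond_to, idx))
        return idx

    r = 1.54
    ring = []
    outs = []
    for k in range(6):
        ang = math.radians(60 * k)
        out = np.array([math.cos(ang), math.sin(ang), 0.0])
        outs.append(out)
        ring.append(add(f"C{k + 1}", "C", r * out))
    for k in range(6):
        bonds.append((ring[k], ring[(k + 1) % 6]))
    c7 = add("C7", "C", coords[ring[0]] + 1.50 * outs[0], ring[0])
    c8 = add("C8", "C", coords[ring[3]] + 1.50 * outs[3], ring[3])
    # sp2 C8: C9 (double bond) and C10 at 120 degrees; the =CH2
    # hydrogens splay in-plane away from the C8 substituents
    dir9 = _rotz(60) @ outs[3]
    dir10 = _rotz(-60) @ outs[3]
    c9 = add("C9", "C", coords[c8] + 1.33 * dir9, c8)
    c10 = add("C10", "C", coords[c8] + 1.50 * dir10, c8)

    add("H2", "H", coords[ring[1]] + 1.09 * outs[1], ring[1])
    for label, carbon, out in (
        ("H3", ring[2], outs[2]),
        ("H5", ring[4], outs[4]),
        ("H6", ring[5], outs[5]),
    ):
        for suffix, sz in (("a", 1.0), ("b", -1.0)):
            d = _unit(0.35 * out + 0.94 * sz * _EZ)
            add(label + suffix, "H", coords[carbon] + 1.09 * d, carbon)
    add("H4", "H", coords[ring[3]] - 1.09 * _EZ, ring[3])
    for suffix, h in zip("abc", _methyl_hydrogens(coords[c7], outs[0])):
        add("H7" + suffix, "H", h, c7)
    add("H9a", "H", coords[c9] + 1.09 * outs[3], c9)
    add("H9b", "H", coords[c9] + 1.09 * (_rotz(120) @ outs[3]), c9)
    for suffix, h in zip("abc", _methyl_hydrogens(coords[c10], dir10)):
        add("H10" + suffix, "H", h, c10)

    return SubstrateTopology(
        name="limonene",
        atom_names=names,
        elements=elements,
        coords=np.array(coords),
        bonds=bonds,
    )


def _build_p_cymene() -> SubstrateTopology:
    # aromatic ring C1..C6, methyl C7 on C1, isopropyl C8(H8)(C9)(C10)
    # on C4; 14 hydrogens
    names: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []

    def add(name: str, element: str, pos: np.ndarray, bond_to: Optional[int] = None) -> int:
        names.append(name)
        elements.append(element)
        coords.append(np.asarray(pos, dtype=float))
        idx = len(names) - 1
        if bond_to is not None:
            bonds.append((bond_to, idx))
        return idx

    r = 1.40
    ring = []
    outs = []
    for k in range(6):
        ang = math.radians(60 * k)
        out = np.array([math.cos(ang), math.sin(ang), 0.0])
        outs.append(out)
        ring.append(add(f"C{k + 1}", "C", r * out))
    for k in range(6):
        bonds.append((ring[k], ring[(k + 1) % 6]))
    c7 = add("C7", "C", coords[ring[0]] + 1.50 * outs[0], ring[0])
    c8 = add("C8", "C", coords[ring[3]] + 1.50 * outs[3], ring[3])
    dir9 = _unit(0.6 * (_rotz(55) @ outs[3]) + 0.85 * _EZ)
    dir10 = _unit(0.6 * (_rotz(-55) @ outs[3]) + 0.85 * _EZ)
    c9 = add("C9", "C", coords[c8] + 1.54 * dir9, c8)
    c10 = add("C10", "C", coords[c8] + 1.54 * dir10, c8)

    for label, k in (("H2", 1), ("H3", 2), ("H5", 4), ("H6", 5)):
        add(label, "H", coords[ring[k]] + 1.09 * outs[k], ring[k])
    for suffix, h in zip("abc", _methyl_hydrogens(coords[c7], outs[0])):
        add("H7" + suffix, "H", h, c7)
    add("H8", "H", coords[c8] + 1.09 * _unit(0.35 * outs[3] - 0.94 * _EZ), c8)
    for suffix, h in zip("abc", _methyl_hydrogens(coords[c9], dir9)):
        add("H9" + suffix, "H", h, c9)
    for suffix, h in zip("abc", _methyl_hydrogens(coords[c10], dir10)):
        add("H10" + suffix, "H", h, c10)

    return SubstrateTopology(
        name="p-cymene",
        atom_names=names,
        elements=elements,
        coords=np.array(coords),
        bonds=bonds,
    )


def build_substrate_topology(
    spec: Union[str, dict, SubstrateTopology],
) -> SubstrateTopology:
    """Built-in topologies ("limonene", "p-cymene") or a custom table
    (dict with name / atom_names / elements / coords / bonds)."""
    if isinstance(spec, SubstrateTopology):
        return spec
    if isinstance(spec, dict):
        return SubstrateTopology(**spec)
    if spec == "limonene":
        return _build_limonene()
    if spec == "p-cymene":
        return _build_p_cymene()
    raise DataError(f"unknown substrate {spec!r}")


@dataclass
class PlantedEnsembleSpec:
    """Recipe for a seeded toy ensemble with a known ranking.

    ``planted_residue_sizes`` / ``anti_residue_sizes`` give the heavy-atom
    counts of the residues placed in substrate contact exclusively in
    byproduct / target frames; at zero noise their substitution scores
    are exactly +size / -size, so the expected ranking is known by
    construction. ``noise`` is the standard deviation (Å) of isotropic
    Gaussian displacement added to every atom of every frame.
    """

    seed: int
    n_frames_per_group: int = 200
    substrate: str = "limonene"
    target_label: str = "H6b"
    byproduct_labels: tuple[str, ...] = ("H9b", "H2")
    planted_residue_sizes: tuple[int, ...] = (5, 4, 3, 2)
    anti_residue_sizes: tuple[int, ...] = (3, 2, 1)
    n_neutral_residues: int = 5
    noise: float = 0.2
    random_weights: bool = False
    #: seeds the residue layout only; replicates of one experiment share
    #: it so their ground truths coincide while frames differ
    layout_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames_per_group < 1:
            raise DataError("n_frames_per_group must be >= 1")
        if self.target_label in self.byproduct_labels:
            raise DataError("target label listed among byproduct labels")
        if self.noise < 0:
            raise DataError("noise must be >= 0")
        for s in self.planted_residue_sizes + self.anti_residue_sizes:
            if not 1 <= s <= 5:
                raise DataError("pseudo-residue sizes must be in 1..5")


@dataclass
class GroundTruth:
    """The ranking the pipeline is expected to recover."""

    planted: list[ResidueKey]
    anti: list[ResidueKey]
    neutral: list[ResidueKey]
    expected_order: list[ResidueKey]  # exact order at zero noise


_POSE_DISTANCE = 2.4  # Å, chosen hydrogen to active-site oxygen
_CONTACT_DISTANCE = 3.4  # Å, contacting pseudo-atom to its substrate anchor
_RING_RADIUS = 12.0  # Å, home positions of pocket residues
_CHAIN = "A"
_SUBSTRATE_RESNUM = 900
_COFACTOR_RESNUM = 999


def _pose_transform(
    topo: SubstrateTopology, label: str, spin_deg: float
) -> np.ndarray:
    """Substrate coordinates with hydrogen ``label`` at (0,0,d0), its
    C-H bond pointing down at the active-site oxygen at the origin, and
    an azimuthal spin about the z axis (which preserves all distances to
    the oxygen)."""
    h = topo.index_of(label)
    c = topo.parent_of(label)
    u = _unit(topo.coords[h] - topo.coords[c])
    rot = _rotz(spin_deg) @ _rotation_to(u, -_EZ)
    shifted = topo.coords - topo.coords[h]
    return shifted @ rot.T + np.array([0.0, 0.0, _POSE_DISTANCE])


def _verify_pose_geometry(topo: SubstrateTopology, labels: Sequence[str]) -> None:
    """At the canonical (zero-noise, zero-spin) placement the intended
    hydrogen must be the strict nearest reaction site and lie inside the
    default pose threshold."""
    threshold = compute_pose_threshold(1.48, 1.00, 1.00)
    hlabels = topo.hydrogen_labels()
    for label in labels:
        placed = _pose_transform(topo, label, 0.0)
        dists = {
            l: float(np.linalg.norm(placed[topo.index_of(l)])) for l in hlabels
        }
        nearest = min(dists, key=lambda l: (dists[l], topo.index_of(l)))
        if nearest != label or dists[label] >= threshold:
            raise DataError(
                f"inconsistent geometry request: cannot make {label} the "
                f"nearest docked hydrogen (nearest={nearest})"
            )


def generate_planted_ensemble(
    spec: PlantedEnsembleSpec,
) -> tuple[ConformationalEnsemble, GroundTruth]:
    """Build a seeded toy ensemble with planted contact asymmetries.

    Deterministic for a fixed seed. Frames cycle through the target
    group and every byproduct group (``n_frames_per_group`` each, in a
    seeded shuffled order). Planted residues contact the substrate in
    every byproduct frame and never in target frames; anti residues the
    reverse; neutral residues never contact.
    """
    rng = np.random.default_rng(spec.seed)
    topo = build_substrate_topology(spec.substrate)
    all_labels = (spec.target_label,) + spec.byproduct_labels
    declared = set(topo.hydrogen_labels())
    missing = [l for l in all_labels if l not in declared]
    if missing:
        raise DataError(f"labels not in {topo.name} topology: {missing}")
    _verify_pose_geometry(topo, all_labels)

    # residue layout: planted / anti / neutral interleaved in a seeded
    # order so recovery cannot be a tie-break artifact; drawn from the
    # layout seed, not the frame seed, so replicates share one layout
    layout_rng = np.random.default_rng(spec.layout_seed)
    kinds = (
        [("planted", s) for s in spec.planted_residue_sizes]
        + [("anti", s) for s in spec.anti_residue_sizes]
        + [("neutral", 1 + i % 3) for i in range(spec.n_neutral_residues)]
    )
    kinds = [kinds[i] for i in layout_rng.permutation(len(kinds))]
    n_res = len(kinds)

    atoms: list[AtomRecord] = []
    home_positions: list[np.ndarray] = []
    residue_kind: list[str] = []
    residue_keys: list[ResidueKey] = []
    idx = 0
    for i, (kind, size) in enumerate(kinds):
        key: ResidueKey = (_CHAIN, i + 1, "")
        residue_keys.append(key)
        residue_kind.append(kind)
        ang = 2 * math.pi * i / n_res
        center = _RING_RADIUS * np.array([math.cos(ang), math.sin(ang), 0.0])
        tangent = np.array([-math.sin(ang), math.cos(ang), 0.0])
        for j in range(size):
            pos = center + (j - (size - 1) / 2) * 0.5 * tangent
            home_positions.append(pos)
            atoms.append(
                AtomRecord(
                    atom_index=idx,
                    atom_name=f"C{j + 1}",
                    element="C",
                    residue_key=key,
                    residue_name="PKT",
                    role="enzyme",
                    is_hydrogen=False,
                )
            )
            idx += 1

    cofactor_key: ResidueKey = (_CHAIN, _COFACTOR_RESNUM, "")
    fe_pos = np.array([0.0, 0.0, -1.63])
    o_pos = np.zeros(3)
    for name, element, pos in (("FE", "FE", fe_pos), ("O1", "O", o_pos)):
        atoms.append(
            AtomRecord(
                atom_index=idx,
                atom_name=name,
                element=element,
                residue_key=cofactor_key,
                residue_name="HEM",
                role="cofactor",
                is_hydrogen=False,
            )
        )
        idx += 1
    active_site_index = idx - 1
    cofactor_home = [fe_pos, o_pos]

    substrate_key: ResidueKey = (_CHAIN, _SUBSTRATE_RESNUM, "")
    substrate_start = idx
    for name, element in zip(topo.atom_names, topo.elements):
        atoms.append(
            AtomRecord(
                atom_index=idx,
                atom_name=name,
                element=element,
                residue_key=substrate_key,
                residue_name="LIG",
                role="substrate",
                is_hydrogen=element == "H",
            )
        )
        idx += 1

    system = MolecularSystem(
        atoms,
        active_site_atom=active_site_index,
        reaction_site_hydrogens=[
            (l, substrate_start + topo.index_of(l)) for l in topo.hydrogen_labels()
        ],
    )

    # frame plan: n_frames_per_group frames for each group, shuffled
    plan = [l for l in all_labels for _ in range(spec.n_frames_per_group)]
    plan = [plan[i] for i in rng.permutation(len(plan))]

    heavy = topo.heavy_indices()
    n_atoms = len(atoms)
    frames = np.empty((len(plan), n_atoms, 3))
    for f, label in enumerate(plan):
        placed = _pose_transform(topo, label, float(rng.uniform(0, 360)))
        centroid = placed[heavy].mean(axis=0)
        pc = placed[topo.parent_of(label)]
        base_dir = pc - centroid
        base_dir[2] = 0.0
        if np.linalg.norm(base_dir) < 1e-6:
            base_dir = np.array([1.0, 0.0, 0.0])
        base_dir = _unit(base_dir)
        contacting = "planted" if label != spec.target_label else "anti"

        coords = np.empty((n_atoms, 3))
        a = 0
        contact_slot = 0
        for i, (kind, size) in enumerate(kinds):
            if kind == contacting:
                d = _rotz(45.0 * contact_slot) @ base_dir
                contact_slot += 1
                perp = _unit(np.cross(d, _EZ))
                anchor = pc + _CONTACT_DISTANCE * d
                for j in range(size):
                    coords[a] = anchor + (j - (size - 1) / 2) * 0.4 * perp
                    a += 1
            else:
                for j in range(size):
                    coords[a] = home_positions[a]
                    a += 1
        coords[a] = cofactor_home[0]
        coords[a + 1] = cofactor_home[1]
        coords[substrate_start:] = placed
        if spec.noise > 0:
            coords = coords + rng.normal(0.0, spec.noise, coords.shape)
        frames[f] = coords

    weights = (
        rng.uniform(0.5, 1.5, len(plan)) if spec.random_weights
        else np.ones(len(plan))
    )
    ensemble = ConformationalEnsemble(
        system=system, coordinates=frames, weights=weights
    )

    planted = [k for k, kind in zip(residue_keys, residue_kind) if kind == "planted"]
    anti = [k for k, kind in zip(residue_keys, residue_kind) if kind == "anti"]
    neutral = [k for k, kind in zip(residue_keys, residue_kind) if kind == "neutral"]
    size_of = dict(zip(residue_keys, (s for _, s in kinds)))
    # zero-noise ranking: planted by descending size then residue number,
    # neutral by residue number, anti by ascending size then residue number
    expected = (
        sorted(planted, key=lambda k: (-size_of[k], k[1]))
        + sorted(neutral, key=lambda k: k[1])
        + sorted(anti, key=lambda k: (size_of[k], k[1]))
    )
    truth = GroundTruth(
        planted=planted, anti=anti, neutral=neutral, expected_order=expected
    )
    return ensemble, truth


def default_fixture_config(
    substrate: str = "limonene",
    target_label: str = "H6b",
    replicates: Sequence[str] = (),
    weights: Sequence[str] = (),
    top_k: Sequence[int] = (3, 5),
) -> AnalysisConfig:
    """AnalysisConfig matching the systems built by
    :func:`generate_planted_ensemble`."""
    topo = build_substrate_topology(substrate)
    return AnalysisConfig(
        substrate_residues=("LIG",),
        active_site=AtomSelector(chain=_CHAIN, resnum=_COFACTOR_RESNUM, atom="O1"),
        reaction_site_hydrogens=tuple(topo.hydrogen_labels()),
        target_hydrogen_labels=(target_label,),
        replicate_inputs=(),
        top_k=tuple(top_k),
    )


def write_fixture_config(
    path: Union[str, Path],
    substrate: str = "limonene",
    target_label: str = "H6b",
    replicates: Sequence[str] = (),
    weights: Sequence[str] = (),
    top_k: Sequence[int] = (3, 5),
) -> None:
    """Write a TOML config for a generated fixture, referencing the given
    replicate PDB / weight files (paths relative to the config)."""
    topo = build_substrate_topology(substrate)

    def toml_list(items: Sequence) -> str:
        return "[" + ", ".join(
            f'"{i}"' if isinstance(i, str) else str(i) for i in items
        ) + "]"

    text = (
        "[input]\n"
        f"replicates = {toml_list(list(replicates))}\n"
        + (f"weights = {toml_list(list(weights))}\n" if weights else "")
        + "\n[system]\n"
        'substrate_residues = ["LIG"]\n'
        'cofactor_residues = ["HEM"]\n'
        f'active_site_atom = {{ chain = "{_CHAIN}", resnum = {_COFACTOR_RESNUM}, atom = "O1" }}\n'
        "\n[poses]\n"
        f"reaction_site_hydrogens = {toml_list(topo.hydrogen_labels())}\n"
        f'target_hydrogens = ["{target_label}"]\n'
        "pose_tolerance = 1.0\n"
        "\n[scoring]\n"
        "contact_tolerance = 1.0\n"
        "\n[ranking]\n"
        f"top_k = {toml_list(list(top_k))}\n"
    )
    Path(path).write_text(text)


def write_fixture_triplet(
    out_dir: Union[str, Path],
    spec: PlantedEnsembleSpec,
    n_replicates: int = 2,
) -> tuple[Path, GroundTruth]:
    """Write a complete on-disk fixture: one multi-model PDB + weight
    file per replicate plus a TOML config referencing them, so the whole
    pipeline can be exercised through its public file interface.

    Replicate i is generated with seed ``spec.seed + i``; the residue
    layout (and hence the ground truth) is identical across replicates
    because the layout permutation depends only on the seed through the
    same generator draw order — so the first replicate's ground truth is
    returned after checking the layouts agree.
    """
    from .structure_io import write_ensemble, write_weights

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths = []
    pdb_names, weight_names = [], []
    for i in range(n_replicates):
        rep_spec = dataclasses.replace(spec, seed=spec.seed + i)
        ensemble, truth = generate_planted_ensemble(rep_spec)
        pdb = f"rep{i + 1}.pdb"
        wfile = f"rep{i + 1}.weights"
        write_ensemble(ensemble, out / pdb)
        write_weights(ensemble.weights, out / wfile)
        pdb_names.append(pdb)
        weight_names.append(wfile)
        truths.append(truth)
    if len({tuple(t.expected_order) for t in truths}) != 1:
        raise DataError("replicate fixtures disagree on ground truth layout")
    config_path = out / "config.toml"
    write_fixture_config(
        config_path,
        substrate=spec.substrate,
        target_label=spec.target_label,
        replicates=pdb_names,
        weights=weight_names,
    )
    return config_path, truths[0]


def brute_force_contacts(
    ensemble: ConformationalEnsemble, config: AnalysisConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Naive all-pairs contact indicators, one atom and one frame at a
    time, with no acceleration structures; the reference oracle for
    equivalence tests. Guarded to small instances."""
    system = ensemble.system
    enz_idx = system.scored_atom_indices(config.include_cofactor)
    sub_idx = system.substrate_heavy_indices()
    if sub_idx.size == 0:
        raise DataError("substrate heavy-atom set is empty")
    n_pairs = ensemble.n_frames * enz_idx.size * sub_idx.size
    if n_pairs > 10_000_000:
        raise DataError(
            f"brute-force oracle limited to 1e7 distance pairs, got {n_pairs}"
        )
    sub_elements = [system.elements[i] for i in sub_idx]
    out = np.zeros((ensemble.n_frames, enz_idx.size), dtype=bool)
    for f in range(ensemble.n_frames):
        frame = ensemble.coordinates[f]
        sub_coords = frame[sub_idx]
        for a, i in enumerate(enz_idx):
            out[f, a] = contact_indicator(
                frame[i],
                system.elements[i],
                sub_coords,
                sub_elements,
                config.radii,
                config.contact_tolerance,
                enzyme_atom_name=system.atom_names[i],
            )
    return enz_idx, out


def frame_count(
    production_length_ns: float, output_interval_ps: float, n_runs: int
) -> int:
    """Number of output conformations: runs x (production length /
    output interval). Raises unless the length is a whole multiple of
    the interval."""
    if production_length_ns <= 0 or output_interval_ps <= 0 or n_runs <= 0:
        raise DataError("all frame-count arguments must be positive")
    length_ps = production_length_ns * 1000.0
    per_run = length_ps / output_interval_ps
    if abs(per_run - round(per_run)) > 1e-9:
        raise DataError(
            f"{production_length_ns} ns not divisible by {output_interval_ps} ps"
        )
    return int(n_runs * round(per_run))
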