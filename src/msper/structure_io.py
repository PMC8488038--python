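"""Reading and writing structures, ensembles, weight files, radii tables
and the TOML analysis configuration.

Ensembles come in as multi-model PDB files (MODEL/ENDMDL) or as a
directory of single-model PDB files (sorted by file name); biotite does
the PDB heavy lifting. Frame weights are a plain text file of
whitespace-separated non-negative floats, one per frame; no weight file
means all weights are 1, the convention for poses from crystal
structures, NMR models, docking or unweighted MD.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ConfigError, DataError
from .model import (
    AnalysisConfig,
    AtomRecord,
    AtomSelector,
    ConformationalEnsemble,
    DEFAULT_VDW_RADII,
    MolecularSystem,
    ReplicateInput,
    ResidueKey,
    VdWRadiiTable,
)

PathLike = Union[str, Path]


def _guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise DataError(f"cannot infer element for atom name {atom_name!r}")


def _classify_role(res_name: str, config: AnalysisConfig) -> str:
    name = res_name.upper()
    if name in {r.upper() for r in config.substrate_residues}:
        return "substrate"
    if name in {r.upper() for r in config.cofactor_residues}:
        return "cofactor"
    if name in {r.upper() for r in config.solvent_residues}:
        return "solvent"
    if name in {r.upper() for r in config.ion_residues}:
        return "ion"
    return "enzyme"


def _read_stack(path: Path) -> struc.AtomArrayStack:
    if path.is_dir():
        files = sorted(path.glob("*.pdb"))
        if not files:
            raise DataError(f"no .pdb files in directory {path}")
        arrays = []
        for f in files:
            model = PDBFile.read(str(f)).get_structure(model=1)
            arrays.append(model)
        counts = {a.array_length() for a in arrays}
        if len(counts) != 1:
            raise DataError(
                f"atom count varies across frame files in {path}: {sorted(counts)}"
            )
        return struc.stack(arrays)
    try:
        stack = PDBFile.read(str(path)).get_structure()
    except Exception as exc:  # biotite raises on inconsistent models
        raise DataError(f"failed to read {path}: {exc}") from exc
    if stack.stack_depth() < 1:
        raise DataError(f"{path}: zero models")
    return stack


def read_weights(path: PathLike, n_frames: int) -> np.ndarray:
    """Read one weight per frame from a whitespace-separated text file."""
    tokens = Path(path).read_text().split()
    try:
        weights = np.array([float(t) for t in tokens], dtype=np.float64)
    except ValueError as exc:
        raise DataError(f"non-numeric weight in {path}: {exc}") from exc
    if weights.size != n_frames:
        raise DataError(
            f"{path}: {weights.size} weights for {n_frames} frames"
        )
    if np.any(weights < 0):
        raise DataError(f"{path}: negative weight")
    return weights


def build_system(
    stack: struc.AtomArrayStack, config: AnalysisConfig
) -> MolecularSystem:
    """Type the atoms of a parsed structure and resolve the active-site
    atom and reaction-site hydrogen selectors declared in the config."""
    n = stack.array_length()
    chain_ids = stack.chain_id
    res_ids = stack.res_id
    ins_codes = (
        stack.ins_code if "ins_code" in stack.get_annotation_categories()
        else np.array([""] * n)
    )
    atoms = []
    for i in range(n):
        element = str(stack.element[i]).strip().upper()
        if not element:
            element = _guess_element(str(stack.atom_name[i]))
        res_name = str(stack.res_name[i]).strip()
        atoms.append(
            AtomRecord(
                atom_index=i,
                atom_name=str(stack.atom_name[i]).strip(),
                element=element,
                residue_key=(str(chain_ids[i]), int(res_ids[i]), str(ins_codes[i]).strip()),
                residue_name=res_name,
                role=_classify_role(res_name, config),
                is_hydrogen=element == "H",
            )
        )

    sel = config.active_site
    active_hits = [
        a.atom_index
        for a in atoms
        if a.residue_key == sel.residue_key() and a.atom_name == sel.atom
    ]
    if len(active_hits) != 1:
        raise DataError(
            f"active-site selector {sel} matched {len(active_hits)} atoms"
        )

    substrate_by_name = {
        a.atom_name: a.atom_index for a in atoms if a.role == "substrate"
    }
    hydrogens = []
    for label in config.reaction_site_hydrogens:
        if label not in substrate_by_name:
            raise DataError(
                f"reaction-site hydrogen {label!r} not found in substrate"
            )
        hydrogens.append((label, substrate_by_name[label]))

    return MolecularSystem(
        atoms,
        active_site_atom=active_hits[0],
        reaction_site_hydrogens=hydrogens,
        excluded_residues=config.excluded_residues,
    )


def read_ensemble(
    path: PathLike,
    weights_path: Optional[PathLike] = None,
    *,
    config: AnalysisConfig,
) -> ConformationalEnsemble:
    """Read a conformational ensemble from a multi-model PDB file or a
    directory of per-frame PDB files, plus an optional weight file."""
    stack = _read_stack(Path(path))
    system = build_system(stack, config)
    coords = np.asarray(stack.coord, dtype=np.float64)
    if weights_path is not None:
        weights = read_weights(weights_path, coords.shape[0])
    else:
        weights = np.ones(coords.shape[0])
    return ConformationalEnsemble(system=system, coordinates=coords, weights=weights)


def _stack_from_ensemble(ensemble: ConformationalEnsemble) -> struc.AtomArrayStack:
    system = ensemble.system
    n = system.n_atoms
    stack = struc.AtomArrayStack(ensemble.n_frames, n)
    stack.coord = np.asarray(ensemble.coordinates, dtype=np.float32)
    stack.chain_id = np.array([a.residue_key[0] for a in system.atoms])
    stack.res_id = np.array([a.residue_key[1] for a in system.atoms])
    stack.ins_code = np.array([a.residue_key[2] for a in system.atoms])
    stack.res_name = np.array([a.residue_name for a in system.atoms])
    stack.atom_name = np.array([a.atom_name for a in system.atoms])
    stack.element = np.array([a.element for a in system.atoms])
    stack.hetero = np.array([a.role != "enzyme" for a in system.atoms])
    return stack


def write_ensemble(ensemble: ConformationalEnsemble, path: PathLike) -> None:
    """Write an ensemble as a multi-model PDB file (weights not included;
    see :func:`write_weights`)."""
    pdb = PDBFile()
    pdb.set_structure(_stack_from_ensemble(ensemble))
    pdb.write(str(path))


def write_weights(weights: Sequence[float], path: PathLike) -> None:
    Path(path).write_text("\n".join(repr(float(w)) for w in weights) + "\n")


_SPECIAL_RADII_KEYS = ("ACTIVE_SITE", "REACTIVE_HYDROGEN")


def load_radii_table(path: Optional[PathLike] = None) -> VdWRadiiTable:
    """Build the vdW radii table, optionally applying overrides from a
    two-column ``key radius`` text file.

    Keys are element symbols, or the special keys ``ACTIVE_SITE`` and
    ``REACTIVE_HYDROGEN`` overriding the two pose-threshold radii.
    Without a file the shipped defaults apply (Bondi-type element set;
    active-site O 1.48 Å; reactive H 1.00 Å).
    """
    table = VdWRadiiTable()
    if path is None:
        return table
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ConfigError(f"{path}:{lineno}: expected 'key radius'")
        key, raw = parts[0].upper(), parts[1]
        try:
            radius = float(raw)
        except ValueError:
            raise ConfigError(f"{path}:{lineno}: non-numeric radius {raw!r}")
        if radius <= 0:
            raise ConfigError(f"{path}:{lineno}: non-positive radius {radius}")
        if key == "ACTIVE_SITE":
            table.active_site_radius = radius
        elif key == "REACTIVE_HYDROGEN":
            table.reactive_hydrogen_radius = radius
        elif key in DEFAULT_VDW_RADII:
            table.by_element[key] = radius
        else:
            raise ConfigError(f"{path}:{lineno}: unknown element key {key!r}")
    return table


def _residue_key_from_toml(entry: dict) -> ResidueKey:
    try:
        return (str(entry["chain"]), int(entry["resnum"]), str(entry.get("icode", "")))
    except KeyError as exc:
        raise ConfigError(f"excluded residue entry missing key: {exc}") from exc


def load_config(path: PathLike) -> AnalysisConfig:
    """Load and validate a TOML analysis configuration.

    Required keys: ``[system] substrate_residues``, ``[system]
    active_site_atom`` (chain / resnum / atom), ``[poses]
    reaction_site_hydrogens`` and ``[poses] target_hydrogens``. Relative
    file paths are resolved against the config file's directory. If
    ``[system] active_site_anchor`` names the residue covalently holding
    the active-site atom (CYS 400 in the motivating system), that residue
    is added to the exclusion set.
    """
    path = Path(path)
    try:
        doc = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: invalid TOML: {exc}") from exc
    base = path.parent

    def resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    try:
        system = doc["system"]
        poses = doc["poses"]
        substrate = tuple(system["substrate_residues"])
        sel = system["active_site_atom"]
        active = AtomSelector(
            chain=str(sel["chain"]),
            resnum=int(sel["resnum"]),
            atom=str(sel["atom"]),
            icode=str(sel.get("icode", "")),
        )
        hydrogens = tuple(str(h) for h in poses["reaction_site_hydrogens"])
        targets = tuple(str(h) for h in poses["target_hydrogens"])
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required config key {exc}") from exc

    scoring = doc.get("scoring", {})
    radii_file = scoring.get("radii_file")
    radii = load_radii_table(resolve(radii_file) if radii_file else None)

    excluded: set[ResidueKey] = {
        _residue_key_from_toml(e) for e in scoring.get("excluded_residues", [])
    }
    if "active_site_anchor" in system:
        excluded.add(_residue_key_from_toml(system["active_site_anchor"]))

    inputs = doc.get("input", {})
    replicates = [resolve(p) for p in inputs.get("replicates", [])]
    weight_files = inputs.get("weights", [])
    if weight_files and len(weight_files) != len(replicates):
        raise ConfigError(
            f"{path}: {len(weight_files)} weight files for "
            f"{len(replicates)} replicates"
        )
    replicate_inputs = tuple(
        ReplicateInput(
            path=p,
            weights_path=resolve(weight_files[i]) if weight_files else None,
        )
        for i, p in enumerate(replicates)
    )

    ranking = doc.get("ranking", {})

    kwargs = {}
    for toml_key, attr in (
        ("cofactor_residues", "cofactor_residues"),
        ("solvent_residues", "solvent_residues"),
        ("ion_residues", "ion_residues"),
    ):
        if toml_key in system:
            kwargs[attr] = tuple(system[toml_key])

    return AnalysisConfig(
        substrate_residues=substrate,
        active_site=active,
        reaction_site_hydrogens=hydrogens,
        target_hydrogen_labels=targets,
        pose_tolerance=float(poses.get("pose_tolerance", 1.0)),
        contact_tolerance=float(scoring.get("contact_tolerance", 1.0)),
        radii=radii,
        excluded_residues=frozenset(excluded),
        include_cofactor=bool(scoring.get("include_cofactor", False)),
        replicate_inputs=replicate_inputs,
        top_k=tuple(int(k) for k in ranking.get("top_k", (5, 10))),
        **kwargs,
    )
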