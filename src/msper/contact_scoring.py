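"""Weighted contact-rate maps and residue substitution scores.

For each scored enzyme heavy atom and each frame, the atom is *in
contact* with the substrate when its distance to the closest substrate
heavy atom is strictly less than the sum of the two vdW radii plus the
contact tolerance. The group contact rate is the weighted mean of that
0/1 indicator over the frames of a pose group,

    C = sum_i c_i w_i / sum_i w_i ,

the difference map is D = C_byproduct - C_target per atom, and the
substitution candidate score of a residue is the sum of its heavy
atoms' D values. Positive scores mark residues whose contacts stabilise
byproduct poses specifically; they are the substitution candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .model import (
    AnalysisConfig,
    ConformationalEnsemble,
    MolecularSystem,
    ResidueKey,
    VdWRadiiTable,
)

# frames per vectorised chunk are sized so a chunk's distance tensor
# stays around ~5e6 doubles
_CHUNK_BUDGET = 5_000_000


def contact_indicator(
    enzyme_coord: np.ndarray,
    enzyme_element: str,
    substrate_coords: np.ndarray,
    substrate_elements: Sequence[str],
    radii: VdWRadiiTable,
    tolerance: float,
    enzyme_atom_name: Optional[str] = None,
) -> int:
    """0/1 contact indicator for one enzyme heavy atom in one frame.

    The threshold is built from the *closest* substrate heavy atom's
    radius; the comparison is strict (boundary counts as no contact).
    """
    substrate_coords = np.asarray(substrate_coords, dtype=np.float64)
    if substrate_coords.size == 0:
        raise DataError("substrate heavy-atom set is empty")
    d = np.linalg.norm(substrate_coords - np.asarray(enzyme_coord, dtype=np.float64), axis=1)
    j = int(np.argmin(d))
    threshold = (
        radii.radius(enzyme_element, enzyme_atom_name)
        + radii.radius(substrate_elements[j])
        + tolerance
    )
    return int(d[j] < threshold)


@dataclass
class ContactRateMap:
    """Per-atom weighted contact rates C for one pose group."""

    group_id: str
    atom_indices: np.ndarray  # scored atom indices into the system
    rates: np.ndarray  # C per scored atom, in [0, 1]
    total_weight: float

    def __post_init__(self) -> None:
        if self.atom_indices.shape != self.rates.shape:
            raise DataError("atom_indices and rates shape mismatch")


@dataclass
class DifferenceMap:
    """Per-atom byproduct-minus-target contact-rate difference D."""

    atom_indices: np.ndarray
    values: np.ndarray  # D per scored atom, in [-1, 1]


def _contact_indicators(
    coords: np.ndarray,
    enz_idx: np.ndarray,
    sub_idx: np.ndarray,
    r_enz: np.ndarray,
    r_sub: np.ndarray,
    tolerance: float,
) -> np.ndarray:
    """(n_frames, n_enzyme_atoms) boolean contact indicators, computed in
    frame chunks: per enzyme atom, distance to the nearest substrate
    heavy atom against that atom pair's radius sum + tolerance."""
    n_frames = coords.shape[0]
    n_e, n_s = enz_idx.size, sub_idx.size
    out = np.empty((n_frames, n_e), dtype=bool)
    chunk = max(1, _CHUNK_BUDGET // max(1, n_e * n_s))
    for start in range(0, n_frames, chunk):
        stop = min(start + chunk, n_frames)
        e = coords[start:stop][:, enz_idx, :]  # (f, E, 3)
        s = coords[start:stop][:, sub_idx, :]  # (f, S, 3)
        diff = e[:, :, None, :] - s[:, None, :, :]
        d2 = np.einsum("fesx,fesx->fes", diff, diff)
        jmin = np.argmin(d2, axis=2)  # (f, E)
        dmin = np.sqrt(np.take_along_axis(d2, jmin[:, :, None], axis=2)[:, :, 0])
        thr = r_enz[None, :] + r_sub[jmin] + tolerance
        out[start:stop] = dmin < thr
    return out


def ensemble_contact_indicators(
    ensemble: ConformationalEnsemble, config: AnalysisConfig
) -> tuple[np.ndarray, np.ndarray]:
    """All-frame contact indicators; returns (scored_atom_indices,
    (n_frames, n_scored) boolean matrix). Shared by the per-group rate
    computation so both groups see identical indicators."""
    system = ensemble.system
    enz_idx = system.scored_atom_indices(config.include_cofactor)
    sub_idx = system.substrate_heavy_indices()
    if sub_idx.size == 0:
        raise DataError("system has no substrate heavy atoms")
    if enz_idx.size == 0:
        raise DataError("system has no scored enzyme heavy atoms")
    r_enz = config.radii.radii_for(system, enz_idx)
    r_sub = np.array([config.radii.radius(system.elements[i]) for i in sub_idx])
    indicators = _contact_indicators(
        ensemble.coordinates, enz_idx, sub_idx, r_enz, r_sub,
        config.contact_tolerance,
    )
    return enz_idx, indicators


def group_contact_rates(
    ensemble: ConformationalEnsemble,
    frame_set: Iterable[int],
    config: AnalysisConfig,
    group_id: str = "",
    _indicators: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> ContactRateMap:
    """Weighted contact rate C per scored atom over a frame set.

    ``_indicators`` lets the pipeline reuse one indicator matrix for both
    pose groups instead of recomputing distances.
    """
    frames = np.asarray(sorted(set(int(i) for i in frame_set)), dtype=int)
    if frames.size == 0:
        raise DataError("frame_set is empty")
    if frames.min() < 0 or frames.max() >= ensemble.n_frames:
        raise DataError("frame index out of range")
    w = ensemble.weights[frames]
    wsum = w.sum()
    if wsum <= 0:
        raise DataError("frame_set has zero total weight")
    if _indicators is None:
        enz_idx, indicators = ensemble_contact_indicators(ensemble, config)
    else:
        enz_idx, indicators = _indicators
    c = (indicators[frames].astype(np.float64) * w[:, None]).sum(axis=0) / wsum
    # the ratio is mathematically in [0,1]; summation-order roundoff can
    # overshoot by one ulp, so clamp to keep the bound exact
    c = np.clip(c, 0.0, 1.0)
    return ContactRateMap(
        group_id=group_id,
        atom_indices=enz_idx.copy(),
        rates=c,
        total_weight=float(wsum),
    )


def difference_map(
    c_byproduct: ContactRateMap, c_target: ContactRateMap
) -> DifferenceMap:
    """D = C_byproduct - C_target, per scored atom."""
    if not np.array_equal(c_byproduct.atom_indices, c_target.atom_indices):
        raise DataError("contact-rate maps cover different atom sets")
    return DifferenceMap(
        atom_indices=c_byproduct.atom_indices.copy(),
        values=c_byproduct.rates - c_target.rates,
    )


@dataclass
class ResidueScoreTable:
    """Substitution candidate score per residue: the sum of its heavy
    atoms' contact-rate differences."""

    residue_keys: list[ResidueKey]
    residue_names: list[str]
    s_scr: np.ndarray
    n_heavy_atoms: np.ndarray

    def as_dict(self) -> dict[ResidueKey, float]:
        return dict(zip(self.residue_keys, self.s_scr))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [k[0] for k in self.residue_keys],
                "resnum": [k[1] for k in self.residue_keys],
                "icode": [k[2] for k in self.residue_keys],
                "residue_name": self.residue_names,
                "S_scr": self.s_scr,
                "n_heavy_atoms": self.n_heavy_atoms,
            }
        )


def residue_scores(
    diff: DifferenceMap, system: MolecularSystem
) -> ResidueScoreTable:
    """Sum per-atom D values within each enzyme residue.

    Every enzyme residue appears in the table; residues none of whose
    heavy atoms were scored get S_scr = 0.
    """
    universe = system.enzyme_residue_keys()
    order = {key: i for i, key in enumerate(universe)}
    s = np.zeros(len(universe))
    n = np.zeros(len(universe), dtype=int)
    for idx, d in zip(diff.atom_indices, diff.values):
        key = system.residue_keys[int(idx)]
        if key not in order:
            # cofactor atoms may be scored by config; they have no
            # residue entry in the enzyme universe and are skipped here
            continue
        s[order[key]] += d
        n[order[key]] += 1
    names = [system.residue_name_of(k) for k in universe]
    return ResidueScoreTable(
        residue_keys=universe, residue_names=names, s_scr=s, n_heavy_atoms=n
    )


def contact_table(
    system: MolecularSystem,
    c_target: ContactRateMap,
    c_byproduct: ContactRateMap,
    diff: DifferenceMap,
) -> pd.DataFrame:
    """Per-atom TSV-ready table with C_tp, C_bp and D."""
    idx = diff.atom_indices
    return pd.DataFrame(
        {
            "atom_index": idx,
            "atom_name": [system.atom_names[i] for i in idx],
            "chain": [system.residue_keys[i][0] for i in idx],
            "resnum": [system.residue_keys[i][1] for i in idx],
            "residue_name": [system.residue_names[i] for i in idx],
            "C_tp": c_target.rates,
            "C_bp": c_byproduct.rates,
            "D": diff.values,
        }
    )
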