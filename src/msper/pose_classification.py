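"""Docking-pose classification.

A frame is a docking pose for the reaction-site hydrogen closest to the
active-site atom when that minimum distance is strictly less than the
sum of the active-site atom's radius, the hydrogen's radius and a
tolerance (1.48 + 1.00 + 1.00 = 3.48 Å with the defaults). Each frame
belongs to exactly one pose group, or to UNDOCKED when no reaction-site
hydrogen is within the threshold. Exact distance ties between hydrogens
are broken toward the smaller atom index; this is deterministic and, on
real coordinates, a measure-zero event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateGroupError
from .model import AnalysisConfig, ConformationalEnsemble, MolecularSystem

#: label given to frames in which the substrate is not docked
UNDOCKED = "UNDOCKED"


def compute_pose_threshold(
    active_site_radius: float,
    reactive_hydrogen_radius: float,
    tolerance: float,
) -> float:
    """Docking-pose distance threshold: sum of the two atomic radii and
    the tolerance, all in Å."""
    for name, v in (
        ("active_site_radius", active_site_radius),
        ("reactive_hydrogen_radius", reactive_hydrogen_radius),
        ("tolerance", tolerance),
    ):
        if v < 0:
            raise DataError(f"{name} must be >= 0, got {v}")
    return active_site_radius + reactive_hydrogen_radius + tolerance


def _sorted_hydrogens(system: MolecularSystem) -> list[tuple[str, int]]:
    # sorted by atom index so that argmin's first-of-ties rule implements
    # the smallest-atom-index tie-break
    return sorted(system.reaction_site_hydrogens, key=lambda lh: lh[1])


def classify_frame(
    frame: np.ndarray, system: MolecularSystem, threshold: float
) -> tuple[str, str, float]:
    """Classify one frame; returns (label, nearest_hydrogen, min_distance).

    ``label`` is the nearest hydrogen's label if its distance to the
    active-site atom is strictly below the threshold, else UNDOCKED; the
    nearest hydrogen is reported either way.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != (system.n_atoms, 3):
        raise DataError(
            f"frame has shape {frame.shape}, expected ({system.n_atoms}, 3)"
        )
    hydrogens = _sorted_hydrogens(system)
    if not hydrogens:
        raise DataError("system declares no reaction-site hydrogens")
    origin = frame[system.active_site_atom]
    dists = np.linalg.norm(
        frame[[i for _, i in hydrogens]] - origin, axis=1
    )
    j = int(np.argmin(dists))
    nearest, dmin = hydrogens[j][0], float(dists[j])
    label = nearest if dmin < threshold else UNDOCKED
    return label, nearest, dmin


@dataclass
class PoseAssignmentTable:
    """Per-frame exclusive pose-group assignment."""

    labels: np.ndarray  # (n_frames,) str
    nearest_hydrogen: np.ndarray  # (n_frames,) str
    min_distance: np.ndarray  # (n_frames,) Å
    weights: np.ndarray  # (n_frames,)
    threshold: float

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def docked_mask(self) -> np.ndarray:
        return self.labels != UNDOCKED

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(self.n_frames),
                "label": self.labels,
                "nearest_hydrogen": self.nearest_hydrogen,
                "min_distance_A": self.min_distance,
                "weight": self.weights,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


def classify_ensemble(
    ensemble: ConformationalEnsemble, config: AnalysisConfig
) -> PoseAssignmentTable:
    """Classify every frame of an ensemble (vectorised, order-preserving)."""
    system = ensemble.system
    threshold = compute_pose_threshold(
        config.radii.active_site_radius,
        config.radii.reactive_hydrogen_radius,
        config.pose_tolerance,
    )
    hydrogens = _sorted_hydrogens(system)
    h_idx = [i for _, i in hydrogens]
    h_labels = np.array([l for l, _ in hydrogens])
    origin = ensemble.coordinates[:, system.active_site_atom, :]  # (F, 3)
    dists = np.linalg.norm(
        ensemble.coordinates[:, h_idx, :] - origin[:, None, :], axis=2
    )  # (F, H)
    jmin = np.argmin(dists, axis=1)  # first of ties = smallest atom index
    dmin = dists[np.arange(dists.shape[0]), jmin]
    nearest = h_labels[jmin]
    labels = np.where(dmin < threshold, nearest, UNDOCKED)
    return PoseAssignmentTable(
        labels=labels,
        nearest_hydrogen=nearest,
        min_distance=dmin,
        weights=ensemble.weights.copy(),
        threshold=threshold,
    )


@dataclass
class GroupPartition:
    """Frame-index partition into target, byproduct and undocked sets."""

    target_frames: np.ndarray
    byproduct_frames: np.ndarray
    undocked_frames: np.ndarray


def partition_groups(
    assignments: PoseAssignmentTable, target_labels: Iterable[str]
) -> GroupPartition:
    """Split docked frames into the target-product group (label in
    ``target_labels``) and the byproduct group (every other docked pose);
    undocked frames enter neither. Both groups must be non-empty, since
    the contact-rate difference is undefined otherwise."""
    target_labels = set(target_labels)
    if not target_labels:
        raise DataError("target_labels must be non-empty")
    if UNDOCKED in target_labels:
        raise DataError("UNDOCKED cannot be a target label")
    docked = assignments.docked_mask()
    in_target = np.isin(assignments.labels, sorted(target_labels))
    target = np.where(docked & in_target)[0]
    byproduct = np.where(docked & ~in_target)[0]
    undocked = np.where(~docked)[0]
    if target.size == 0:
        raise DegenerateGroupError("target pose group is empty")
    if byproduct.size == 0:
        raise DegenerateGroupError("byproduct pose group is empty")
    return GroupPartition(
        target_frames=target, byproduct_frames=byproduct, undocked_frames=undocked
    )


@dataclass
class PoseGroupSummary:
    """Per-label frame counts and weight totals; fractions are of the
    total docked weight."""

    counts: dict[str, int]
    weights: dict[str, float]
    fractions: dict[str, float]
    undocked_count: int
    undocked_weight: float
    total_weight: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "label": label,
                "n_frames": self.counts[label],
                "weight": self.weights[label],
                "fraction_of_docked": self.fractions[label],
            }
            for label in self.counts
        ]
        return pd.DataFrame(rows)


def summarize_groups(assignments: PoseAssignmentTable) -> PoseGroupSummary:
    """Tally frame counts and weights per pose group."""
    counts: dict[str, int] = {}
    weights: dict[str, float] = {}
    undocked_count = 0
    undocked_weight = 0.0
    for label, w in zip(assignments.labels, assignments.weights):
        label = str(label)
        if label == UNDOCKED:
            undocked_count += 1
            undocked_weight += float(w)
        else:
            counts[label] = counts.get(label, 0) + 1
            weights[label] = weights.get(label, 0.0) + float(w)
    docked_weight = sum(weights.values())
    fractions = {
        label: (w / docked_weight if docked_weight > 0 else 0.0)
        for label, w in weights.items()
    }
    return PoseGroupSummary(
        counts=counts,
        weights=weights,
        fractions=fractions,
        undocked_count=undocked_count,
        undocked_weight=undocked_weight,
        total_weight=float(assignments.weights.sum()),
    )
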