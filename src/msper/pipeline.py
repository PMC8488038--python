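"""End-to-end orchestration: classify -> partition -> contact rates ->
difference map -> residue scores -> rank, per replicate; then rank
aggregation and a convergence report when two or more replicates are
supplied. Writes TSV/JSON/PDB outputs plus a manifest and a log.

All analysis outputs are deterministic functions of the config and the
input coordinates; wall-clock timestamps appear only in the manifest and
the log, so repeated runs produce byte-identical TSV/JSON tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import __version__
from .errors import DataError, DegenerateGroupError, MsperError
from .model import AnalysisConfig, ConformationalEnsemble, ReplicateInput
from .structure_io import load_config, read_ensemble, _stack_from_ensemble
from .pose_classification import (
    classify_ensemble,
    partition_groups,
    summarize_groups,
)
from .contact_scoring import (
    ContactRateMap,
    DifferenceMap,
    contact_table,
    difference_map,
    ensemble_contact_indicators,
    group_contact_rates,
    residue_scores,
)
from .ranking_aggregation import (
    RankedList,
    aggregate_ranks,
    convergence_report,
    rank_residues,
)

logger = logging.getLogger("msper")

PathLike = Union[str, Path]


@dataclass
class ReplicateResult:
    """Everything computed for one replicate ensemble."""

    index: int
    ranked: RankedList
    c_target: ContactRateMap
    c_byproduct: ContactRateMap
    diff: DifferenceMap
    group_summary: dict
    n_frames: int


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_path: str
    config_digest: str
    tool_version: str
    timestamp: str
    input_paths: list[str]
    replicate_summaries: list[dict]
    output_paths: list[str]

    def write(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def export_difference_pdb(
    ensemble: ConformationalEnsemble,
    diff: DifferenceMap,
    path: PathLike,
    frame: int = 0,
) -> None:
    """Write one reference frame as a PDB with per-atom D values in the
    B-factor column (%6.2f, clipped to [-9.99, 99.99]); unscored atoms
    get 0.00. Loading such a file in a molecular viewer coloured by
    B-factor reproduces the difference-map figures."""
    system = ensemble.system
    bfac = np.zeros(system.n_atoms)
    bfac[diff.atom_indices] = np.clip(diff.values, -9.99, 99.99)
    single = dataclasses.replace(
        ensemble,
        coordinates=ensemble.coordinates[frame : frame + 1],
        weights=np.ones(1),
    )
    stack = _stack_from_ensemble(single)
    stack.set_annotation("b_factor", bfac.astype(np.float64))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def analyse_replicate(
    ensemble: ConformationalEnsemble,
    config: AnalysisConfig,
    index: int = 1,
) -> ReplicateResult:
    """Run the per-replicate analysis chain on an in-memory ensemble."""
    assignments = classify_ensemble(ensemble, config)
    summary = summarize_groups(assignments)
    logger.info(
        "replicate %d: %d frames, docked weight %.6g of %.6g, groups %s",
        index,
        ensemble.n_frames,
        sum(summary.weights.values()),
        summary.total_weight,
        {k: summary.counts[k] for k in sorted(summary.counts)},
    )
    try:
        partition = partition_groups(assignments, config.target_hydrogen_labels)
    except DegenerateGroupError as exc:
        raise DegenerateGroupError(f"replicate {index}: {exc}") from exc
    indicators = ensemble_contact_indicators(ensemble, config)
    c_tp = group_contact_rates(
        ensemble, partition.target_frames, config,
        group_id="target", _indicators=indicators,
    )
    c_bp = group_contact_rates(
        ensemble, partition.byproduct_frames, config,
        group_id="byproduct", _indicators=indicators,
    )
    diff = difference_map(c_bp, c_tp)
    scores = residue_scores(diff, ensemble.system)
    excluded = set(config.excluded_residues) | set(ensemble.system.excluded_residues)
    ranked = rank_residues(scores, excluded)
    return ReplicateResult(
        index=index,
        ranked=ranked,
        c_target=c_tp,
        c_byproduct=c_bp,
        diff=diff,
        group_summary={
            "n_frames": ensemble.n_frames,
            "total_weight": summary.total_weight,
            "undocked_weight": summary.undocked_weight,
            "group_counts": summary.counts,
            "group_weights": summary.weights,
        },
        n_frames=ensemble.n_frames,
    )


def _assignment_outputs(ensemble, config, out, i, outputs):
    assignments = classify_ensemble(ensemble, config)
    p = out / f"assignments_rep{i}.tsv"
    assignments.write_tsv(p)
    outputs.append(p)


def run_pipeline(
    config_path: PathLike,
    output_dir: PathLike,
    replicate_paths: Optional[Sequence[PathLike]] = None,
    weight_paths: Optional[Sequence[PathLike]] = None,
) -> RunManifest:
    """Execute the full prediction workflow from a config file.

    ``replicate_paths`` / ``weight_paths`` override the config's input
    section when given. Outputs land in ``output_dir``: per-replicate
    assignment, contact and ranked tables, a difference-map PDB, the
    aggregated ranking, a convergence report (two or more replicates), a
    manifest and a log.
    """
    config_path = Path(config_path)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        config = load_config(config_path)
        replicates: list[ReplicateInput]
        if replicate_paths:
            weights = list(weight_paths or [])
            if weights and len(weights) != len(replicate_paths):
                raise DataError(
                    f"{len(weights)} weight files for "
                    f"{len(replicate_paths)} replicates"
                )
            replicates = [
                ReplicateInput(
                    path=str(p),
                    weights_path=str(weights[i]) if weights else None,
                )
                for i, p in enumerate(replicate_paths)
            ]
        else:
            replicates = list(config.replicate_inputs)
        if not replicates:
            raise DataError("no replicate ensembles supplied")

        outputs: list[Path] = []
        results: list[ReplicateResult] = []
        for i, rep in enumerate(replicates, start=1):
            logger.info("reading replicate %d: %s", i, rep.path)
            ensemble = read_ensemble(
                rep.path, rep.weights_path, config=config
            )
            result = analyse_replicate(ensemble, config, index=i)
            results.append(result)

            _assignment_outputs(ensemble, config, out, i, outputs)
            p = out / f"contacts_rep{i}.tsv"
            contact_table(
                ensemble.system, result.c_target, result.c_byproduct, result.diff
            ).to_csv(p, sep="\t", index=False, float_format="%.6g")
            outputs.append(p)
            p = out / f"ranked_rep{i}.tsv"
            result.ranked.write_tsv(p)
            outputs.append(p)
            p = out / f"diffmap_rep{i}.pdb"
            export_difference_pdb(ensemble, result.diff, p)
            outputs.append(p)

        if len(results) >= 2:
            aggregated = aggregate_ranks([r.ranked for r in results])
            p = out / "aggregated.tsv"
            aggregated.write_tsv(p)
            outputs.append(p)
            k_values = [k for k in config.top_k if k <= len(results[0].ranked)]
            report = convergence_report([r.ranked for r in results], k_values)
            p = out / "convergence.json"
            p.write_text(json.dumps(report.to_json_dict(), indent=2) + "\n")
            outputs.append(p)
            logger.info(
                "convergence: top-k overlap %s, spearman %.4f",
                report.top_k_overlap,
                report.spearman,
            )
        else:
            logger.warning(
                "single replicate: rank aggregation and convergence "
                "report skipped"
            )

        manifest = RunManifest(
            config_path=str(config_path),
            config_digest=hashlib.sha256(config_path.read_bytes()).hexdigest(),
            tool_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
            input_paths=[r.path for r in replicates],
            replicate_summaries=[r.group_summary for r in results],
            output_paths=[str(p) for p in outputs],
        )
        manifest_path = out / "manifest.json"
        manifest.write(manifest_path)
        logger.info("wrote %d outputs to %s", len(outputs) + 1, out)
        return manifest
    except MsperError as exc:
        logger.error("%s: %s", type(exc).__name__, exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
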