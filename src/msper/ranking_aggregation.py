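"""Residue ranking, replicate aggregation and convergence diagnostics.

Residues are ranked per replicate by descending substitution score with
ordinal (consecutive-integer) ranks; active-site residues are removed
*before* ranking so ranks 1..n run over eligible residues only. Across
replicates the ranking average (arithmetic mean of a residue's ordinal
ranks) orders the final candidate list — lower is better. Because the
score is sensitive to small pose differences, agreement between
replicates is judged on the ranked lists (top-k overlap, rank
correlation) rather than on the scores themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import DataError
from .contact_scoring import ResidueScoreTable
from .model import ResidueKey


@dataclass(frozen=True)
class RankedRecord:
    residue_key: ResidueKey
    residue_name: str
    s_scr: float
    rank: int  # 1-based ordinal


@dataclass
class RankedList:
    """Residues ordered by descending S_scr with ordinal ranks."""

    records: list[RankedRecord]

    def __len__(self) -> int:
        return len(self.records)

    def rank_of(self) -> dict[ResidueKey, int]:
        return {r.residue_key: r.rank for r in self.records}

    def top(self, k: int) -> set[ResidueKey]:
        if k > len(self.records):
            raise DataError(f"k={k} exceeds ranking length {len(self.records)}")
        return {r.residue_key for r in self.records[:k]}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [r.residue_key[0] for r in self.records],
                "resnum": [r.residue_key[1] for r in self.records],
                "icode": [r.residue_key[2] for r in self.records],
                "residue_name": [r.residue_name for r in self.records],
                "S_scr": [r.s_scr for r in self.records],
                "rank": [r.rank for r in self.records],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _tie_key(key: ResidueKey) -> tuple:
    # residue number ascending, then chain, then insertion code
    return (key[1], key[0], key[2])


def rank_residues(
    scores: ResidueScoreTable, excluded: Iterable[ResidueKey] = ()
) -> RankedList:
    """Rank residues by descending S_scr after removing excluded
    (active-site) residues; exact score ties break toward the smaller
    residue number, then chain id."""
    excluded = set(excluded)
    rows = [
        (key, name, float(s))
        for key, name, s in zip(
            scores.residue_keys, scores.residue_names, scores.s_scr
        )
        if key not in excluded
    ]
    if not rows:
        raise DataError("no residues left to rank after exclusion")
    rows.sort(key=lambda r: (-r[2], _tie_key(r[0])))
    return RankedList(
        records=[
            RankedRecord(residue_key=k, residue_name=n, s_scr=s, rank=i + 1)
            for i, (k, n, s) in enumerate(rows)
        ]
    )


@dataclass
class AggregatedRanking:
    """Per-residue ranks across replicates and their mean, ordered by
    ascending ranking average."""

    residue_keys: list[ResidueKey]
    residue_names: list[str]
    per_replicate_ranks: np.ndarray  # (n_residues, n_replicates)
    ranking_average: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chain": [k[0] for k in self.residue_keys],
                "resnum": [k[1] for k in self.residue_keys],
                "icode": [k[2] for k in self.residue_keys],
                "residue_name": self.residue_names,
            }
        )
        for j in range(self.per_replicate_ranks.shape[1]):
            df[f"rank_rep{j + 1}"] = self.per_replicate_ranks[:, j]
        df["ranking_average"] = self.ranking_average
        return df

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


def aggregate_ranks(rankings: Sequence[RankedList]) -> AggregatedRanking:
    """Mean ordinal rank per residue across replicate rankings; ties on
    the average break toward the smaller residue number."""
    if not rankings:
        raise DataError("need at least one ranking to aggregate")
    universes = [frozenset(r.residue_key for r in rk.records) for rk in rankings]
    if len(set(universes)) != 1:
        raise DataError("replicate rankings cover different residue sets")
    name_of = {r.residue_key: r.residue_name for r in rankings[0].records}
    rank_maps = [rk.rank_of() for rk in rankings]
    keys = sorted(universes[0], key=_tie_key)
    ranks = np.array([[m[k] for m in rank_maps] for k in keys], dtype=float)
    avg = ranks.mean(axis=1)
    order = sorted(range(len(keys)), key=lambda i: (avg[i], _tie_key(keys[i])))
    return AggregatedRanking(
        residue_keys=[keys[i] for i in order],
        residue_names=[name_of[keys[i]] for i in order],
        per_replicate_ranks=ranks[order].astype(int),
        ranking_average=avg[order],
    )


@dataclass
class ConvergenceReport:
    """Replicate agreement: mean pairwise top-k overlap per k, and mean
    pairwise Spearman rank correlation."""

    top_k_overlap: dict[int, float]
    spearman: float
    n_replicates: int

    def to_json_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "top_k_overlap": {str(k): v for k, v in self.top_k_overlap.items()},
            "spearman": self.spearman,
        }


def convergence_report(
    rankings: Sequence[RankedList], k_values: Sequence[int]
) -> ConvergenceReport:
    """Quantify whether the top-ranked residues from independent
    replicates match: |top-k(a) ∩ top-k(b)| / k averaged over replicate
    pairs, plus the Spearman correlation of the full rank vectors."""
    if len(rankings) < 2:
        raise DataError("convergence needs at least two rankings")
    n = len(rankings[0])
    for rk in rankings:
        if frozenset(rk.rank_of()) != frozenset(rankings[0].rank_of()):
            raise DataError("rankings cover different residue sets")
    overlaps: dict[int, float] = {}
    for k in k_values:
        if k < 1 or k > n:
            raise DataError(f"k={k} out of range for ranking of length {n}")
        pair_vals = [
            len(a.top(k) & b.top(k)) / k for a, b in combinations(rankings, 2)
        ]
        overlaps[int(k)] = float(np.mean(pair_vals))
    keys = sorted(rankings[0].rank_of(), key=_tie_key)
    vectors = [np.array([rk.rank_of()[k] for k in keys]) for rk in rankings]
    rhos = [float(spearmanr(a, b).statistic) for a, b in combinations(vectors, 2)]
    return ConvergenceReport(
        top_k_overlap=overlaps,
        spearman=float(np.mean(rhos)),
        n_replicates=len(rankings),
    )
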