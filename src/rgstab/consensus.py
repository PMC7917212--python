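"""Geometric-mean consensus of per-algorithm stability rankings.

Each algorithm's stability values are converted to ascending competition
ranks ("1,1,3": ties share the minimum rank and the following rank skips
by the tie count), then a gene's consensus score is the geometric mean of
its ranks across algorithms ("geomean").  The final ordering is ascending
by the unrounded geomean, with ties broken lexicographically by gene id.

Competition ranking with geNorm's final tied pair sharing rank 1 is the
tie rule consistent with the published geomean arithmetic — e.g. ranks
(1, 1, 3, 1) give (1·1·3·1)^¼ = 1.32, whereas fractional 1.5/1.5 ranks
would give 1.46.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["competition_rank", "geomean_consensus", "ConsensusRanking", "rank_stability_values"]


def competition_rank(
    values: Mapping[str, float],
    tied_groups: Optional[Sequence[Iterable[str]]] = None,
) -> dict[str, int]:
    """Ascending competition ranks of a gene -> stability-value map.

    ``tied_groups`` forces gene sets (e.g. geNorm's final pair) to share a
    rank: every member is ranked as if it had the best value in its group.
    Groups must be disjoint.
    """
    genes = list(values)
    vals = {g: float(values[g]) for g in genes}
    for g, v in vals.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite stability value for gene {g!r}")
    if tied_groups:
        seen: set[str] = set()
        for grp in tied_groups:
            grp = list(grp)
            unknown = [g for g in grp if g not in vals]
            if unknown:
                raise KeyError(f"tied-group gene(s) not in values: {unknown}")
            if seen & set(grp):
                raise ValueError("tied_groups must be disjoint")
            seen |= set(grp)
            best = min(vals[g] for g in grp)
            for g in grp:
                vals[g] = best
    arr = np.array([vals[g] for g in genes])
    ranks = (arr[:, None] > arr[None, :]).sum(axis=1) + 1
    return {g: int(r) for g, r in zip(genes, ranks)}


@dataclass
class ConsensusRanking:
    """Per-gene algorithm ranks, geomean score, and the final ordering."""

    ranks: pd.DataFrame          # genes x algorithms, integer ranks
    geomean: pd.Series           # unrounded geometric mean of ranks
    final_rank: pd.Series        # 1..G permutation, ascending geomean
    values: Optional[pd.DataFrame] = None  # raw stability values, if known
    tie_flags: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))

    @property
    def geomean_2dp(self) -> pd.Series:
        """Geomean rounded to 2 decimals, the reported precision."""
        return self.geomean.round(2)

    def ordered_genes(self) -> list[str]:
        return list(self.final_rank.sort_values().index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"final_rank": self.final_rank, "geomean": self.geomean_2dp}
        )
        for alg in self.ranks.columns:
            df[f"rank_{alg}"] = self.ranks[alg]
            if self.values is not None and alg in self.values.columns:
                df[f"value_{alg}"] = self.values[alg]
        df.index.name = "gene"
        return df.sort_values("final_rank")

    def to_dict(self) -> dict:
        out = {}
        for g in self.ranks.index:
            out[str(g)] = {
                "ranks": {a: int(self.ranks.loc[g, a]) for a in self.ranks.columns},
                "geomean": round(float(self.geomean[g]), 2),
                "final_rank": int(self.final_rank[g]),
            }
        return out


def geomean_consensus(
    ranks_by_algorithm: Mapping[str, Mapping[str, int]],
) -> ConsensusRanking:
    """Aggregate per-algorithm gene ranks into the consensus geomean score.

    Every algorithm must rank the same gene set.  The consensus ordering is
    ascending by the unrounded geomean; exact geomean ties are broken
    lexicographically by gene id and flagged.
    """
    algs = list(ranks_by_algorithm)
    if not algs:
        raise ValueError("at least one algorithm ranking is required")
    genes = list(ranks_by_algorithm[algs[0]])
    for alg in algs:
        missing = [g for g in genes if g not in ranks_by_algorithm[alg]]
        extra = [g for g in ranks_by_algorithm[alg] if g not in genes]
        if missing or extra:
            raise ValueError(
                f"algorithm {alg!r} gene set mismatch; "
                f"missing {missing}, unexpected {extra}"
            )
    ranks = pd.DataFrame(
        {alg: [int(ranks_by_algorithm[alg][g]) for g in genes] for alg in algs},
        index=genes,
    )
    geo = pd.Series(
        np.exp(np.log(ranks.to_numpy(float)).mean(axis=1)), index=genes, name="geomean"
    )
    order = sorted(genes, key=lambda g: (geo[g], g))
    final = pd.Series({g: i + 1 for i, g in enumerate(order)}, name="final_rank")[genes]
    dup = geo.duplicated(keep=False)
    return ConsensusRanking(ranks, geo, final, tie_flags=dup)


def rank_stability_values(
    values_by_algorithm: Mapping[str, Mapping[str, float]],
    tied_groups_by_algorithm: Optional[Mapping[str, Sequence[Iterable[str]]]] = None,
) -> ConsensusRanking:
    """Convenience: competition-rank raw stability values, then aggregate."""
    tied = tied_groups_by_algorithm or {}
    ranks = {
        alg: competition_rank(vals, tied.get(alg))
        for alg, vals in values_by_algorithm.items()
    }
    res = geomean_consensus(ranks)
    res.values = pd.DataFrame(
        {alg: pd.Series(dict(vals)) for alg, vals in values_by_algorithm.items()}
    ).loc[res.ranks.index]
    return res
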