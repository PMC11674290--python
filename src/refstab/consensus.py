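"""Comprehensive (RefFinder-style) ranking: combine per-method stability
ranks by geometric mean, and intersect per-method top-k gene lists.

The combiner consumes a ready-made rank matrix and never re-runs the
stability methods internally; the combination rule is therefore explicit
and reproducible, unlike web tools whose internal re-computation is
undocumented.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["rank_by_value", "reffinder_geomean", "topk_intersection"]


def rank_by_value(values: pd.Series | Mapping[str, float], ascending: bool = True) -> pd.Series:
    """Dense ranks: equal values share a rank, the next distinct value adds 1.

    This is the tie convention of published stability tables, where two
    genes can share rank 1 and the next gene still gets rank 2.
    """
    s = pd.Series(values, dtype=float)
    if s.isna().any():
        raise ValueError(f"cannot rank NaN values for {list(s.index[s.isna()])}")
    return s.rank(method="dense", ascending=ascending).astype(int)


def reffinder_geomean(method_ranks: pd.DataFrame) -> pd.DataFrame:
    """Geometric mean of per-method stability ranks, with a dense final rank.

    ``method_ranks`` is a gene x method table of positive integer ranks; a
    missing cell is an error listing every omission (a consensus over
    partial rankings would silently favor the covered genes).
    """
    ranks = pd.DataFrame(method_ranks).astype(float)
    if ranks.isna().any().any():
        missing = [
            f"(gene {ranks.index[i]!r}, method {ranks.columns[j]!r})"
            for i, j in zip(*np.nonzero(ranks.isna().to_numpy()))
        ]
        raise ValueError("missing ranks for: " + ", ".join(missing))
    if (ranks < 1).any().any():
        raise ValueError("ranks must be positive integers starting at 1")
    geo = np.exp(np.log(ranks).mean(axis=1))
    out = ranks.astype(int).copy()
    out["geomean"] = geo
    out["final_rank"] = rank_by_value(geo, ascending=True)
    out.index.name = "gene"
    return out.sort_values(["final_rank", "geomean"], kind="stable")


def _top_k(ordering, k: int) -> set[str]:
    if isinstance(ordering, pd.Series):
        # rank/value series: keep everything tied with the k-th best value
        s = pd.Series(ordering, dtype=float)
        cutoff = s.sort_values(kind="stable").iloc[: min(k, len(s))].max()
        return set(s.index[s <= cutoff])
    ordering = list(ordering)
    if len(ordering) < k:
        raise ValueError(f"ordering with {len(ordering)} genes cannot yield a top {k}")
    return set(ordering[:k])


def topk_intersection(
    rankings: Sequence[Sequence[str] | pd.Series] | Mapping[str, Sequence[str] | pd.Series],
    k: int = 5,
) -> set[str]:
    """Genes in the top k of every method's ranking (the Venn-diagram core).

    Each ranking is either an ordered best-first gene list (first k taken)
    or a gene -> rank/value Series, in which case ties at position k are
    all included.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if isinstance(rankings, Mapping):
        rankings = list(rankings.values())
    if not rankings:
        raise ValueError("need at least one ranking")
    sets = [_top_k(r, k) for r in rankings]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out
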