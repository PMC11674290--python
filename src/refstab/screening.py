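"""Candidate reference-gene screening from an RNA-seq abundance matrix.

A reference-gene candidate should be abundant (so it amplifies early and
reliably) and flat across conditions.  The funnel applied here nominates
candidates from an FPKM-style matrix in fixed stages:

1. keep genes with mean expression strictly above ``min_mean`` (default 150);
2. sort survivors by SD ascending and keep the first ``sd_rank_cutoff``
   (default 350);
3. keep genes with CV strictly below ``max_cv`` (default 0.3);
4. breadth filter: keep genes whose minimum expression across samples is at
   least ``min_breadth_fraction`` of that gene's median (default 0.25) — a
   quantitative proxy for "expressed at high abundance across tissues".
   This proxy replaces a manual curation step and is documented as
   non-replicating in docs/methods.md.

Stage order mean -> SD-rank -> CV is the default; ``order`` can swap the
SD-rank and CV stages, since either reading of the published funnel is
defensible.  All comparisons are strict inequalities; boundary genes drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ExpressionMatrix

__all__ = ["ScreeningCriteria", "ScreeningResult", "summarize_expression", "screen_candidates"]

STAGE_NAMES = ("input", "mean", "sd_rank", "cv", "breadth")


@dataclass(frozen=True)
class ScreeningCriteria:
    """Thresholds for the screening funnel (see module docstring for stages)."""

    min_mean: float = 150.0
    sd_rank_cutoff: int = 350
    max_cv: float = 0.3
    min_breadth_fraction: float = 0.25
    order: str = "mean_sd_cv"  # or "mean_cv_sd"

    def __post_init__(self):
        if self.min_mean < 0:
            raise ValueError("min_mean must be nonnegative")
        if self.sd_rank_cutoff < 1:
            raise ValueError("sd_rank_cutoff must be at least 1")
        if self.max_cv <= 0:
            raise ValueError("max_cv must be positive")
        if not 0 <= self.min_breadth_fraction <= 1:
            raise ValueError("min_breadth_fraction must lie in [0, 1]")
        if self.order not in {"mean_sd_cv", "mean_cv_sd"}:
            raise ValueError("order must be 'mean_sd_cv' or 'mean_cv_sd'")


@dataclass(frozen=True)
class ScreeningResult:
    """Survivors (sorted by SD ascending) with summaries and per-stage counts."""

    table: pd.DataFrame  # per-gene mean/sd/cv/sd_rank + pass flags, all input genes
    survivors: list[str]
    stage_counts: dict[str, int] = field(default_factory=dict)


def summarize_expression(mat: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean, sample SD (n-1) and CV = SD/mean of an abundance matrix.

    CV is NaN (flagged undefined) for all-zero genes, whose mean vanishes.
    """
    if mat.data.shape[1] < 2:
        raise ValueError("summaries need at least 2 samples")
    mean = mat.data.mean(axis=1)
    sd = mat.data.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    out = pd.DataFrame({"mean": mean, "sd": sd, "cv": cv})
    out.index.name = "gene"
    return out


def screen_candidates(
    mat: ExpressionMatrix, criteria: ScreeningCriteria | None = None
) -> ScreeningResult:
    """Apply the screening funnel; an empty survivor set is a valid result.

    Deterministic for fixed input: SD ties at the rank cutoff are broken by
    gene id (lexicographic).  Survivors come back sorted by SD ascending.
    """
    criteria = criteria or ScreeningCriteria()
    table = summarize_expression(mat)

    # SD rank over ALL genes is reported for context; the cutoff itself is
    # applied within the funnel stage below.
    order = table.assign(_g=table.index).sort_values(["sd", "_g"], kind="stable").index
    table["sd_rank"] = pd.Series(np.arange(1, len(table) + 1), index=order)

    counts = {"input": len(table)}
    alive = pd.Series(True, index=table.index)

    def mean_stage(alive):
        return alive & (table["mean"] > criteria.min_mean)

    def sd_stage(alive):
        live = table.loc[alive[alive].index]
        keep_idx = (
            live.assign(_g=live.index)
            .sort_values(["sd", "_g"], kind="stable")
            .index[: criteria.sd_rank_cutoff]
        )
        out = pd.Series(False, index=table.index)
        out[keep_idx] = True
        return alive & out

    def cv_stage(alive):
        cv_ok = table["cv"].notna() & (table["cv"] < criteria.max_cv)
        return alive & cv_ok

    stages = {"mean": mean_stage, "sd_rank": sd_stage, "cv": cv_stage}
    stage_order = (
        ["mean", "sd_rank", "cv"] if criteria.order == "mean_sd_cv" else ["mean", "cv", "sd_rank"]
    )
    for name in stage_order:
        alive = stages[name](alive)
        counts[name] = int(alive.sum())
        table[f"pass_{name}"] = alive

    med = mat.data.median(axis=1)
    breadth_ok = mat.data.min(axis=1) >= criteria.min_breadth_fraction * med
    alive = alive & breadth_ok
    counts["breadth"] = int(alive.sum())
    table["pass_breadth"] = alive

    # counts reported in application order, so they read non-increasing
    counts = {name: counts[name] for name in ["input", *stage_order, "breadth"]}
    survivors = list(
        table.loc[alive].assign(_g=lambda t: t.index).sort_values(["sd", "_g"], kind="stable").index
    )
    table = table.drop(columns=[c for c in table.columns if c == "_g"])
    return ScreeningResult(table=table, survivors=survivors, stage_counts=counts)
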