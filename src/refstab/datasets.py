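"""Bundled example dataset: published stability statistics for 17 Arabidopsis
candidate reference genes assayed by qRT-PCR under high-temperature stress
(control 22C, acute 42C, chronic 32C).

The panel mixes 13 novel candidates (photosynthesis-associated genes such
as the LHCB light-harvesting family, PSBW/PSBX, plus COL4, SCA1, TCTP1,
ARFA1E, PIP1C, CHLM, RBP45B) with 4 traditional references (GAPDH, UBQ5,
ACTIN2, UBQ10).  Raw Ct values were not released, so the dataset carries
the per-gene statistics each tool printed — geNorm M, NormFinder S,
BestKeeper SD/CV — with the published ranks, the published per-method
top-5 lists, and the leading geNorm pairwise-variation value V2 = 0.087.
These suffice to re-derive every rank, threshold verdict and top-5
intersection from scratch.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "arabidopsis_heat_stability",
    "arabidopsis_heat_top5",
    "ARABIDOPSIS_HEAT_V2",
]

ARABIDOPSIS_HEAT_V2 = 0.087  # leading geNorm pairwise variation (V_2)

# gene: (genorm_m, genorm_rank, normfinder_s, normfinder_rank,
#        bestkeeper_sd, bestkeeper_cv, bestkeeper_rank,
#        reffinder_geomean, reffinder_rank)
_STABILITY_ROWS = {
    "PSBW":    (0.317864897, 4, 0.08, 1, 0.448148148, 2.324151973, 7, 1.86, 1),
    "LHCB4.1": (0.276747099, 3, 0.30, 3, 0.325925926, 1.629991850, 5, 2.45, 2),
    "LHCB5":   (0.243791248, 2, 0.58, 5, 0.269629630, 1.370610939, 3, 3.13, 3),
    "PSBX":    (0.546236016, 8, 0.20, 2, 0.749629630, 3.874499895, 11, 3.44, 4),
    "COL4":    (0.390385703, 5, 0.75, 8, 0.045925926, 0.210723086, 1, 3.94, 5),
    "TCTP1":   (0.456361943, 6, 0.67, 6, 0.285185185, 1.385365503, 4, 5.01, 6),
    "SCA1":    (0.180010288, 1, 0.72, 7, 0.431851852, 1.912635533, 6, 5.38, 7),
    "LHCA3":   (0.180010288, 1, 0.57, 4, 0.504444444, 2.275005011, 8, 7.97, 8),
    "ARFA1E":  (0.482993823, 7, 0.81, 9, 0.200000000, 0.691722389, 2, 8.19, 9),
    "PIP1C":   (0.705859587, 10, 0.85, 10, 0.995555556, 4.031677466, 12, 10.17, 10),
    "LHCB6":   (0.610471106, 9, 1.05, 13, 0.748148148, 3.796207551, 10, 11.68, 11),
    "UBQ5":    (0.881314931, 12, 0.95, 11, 1.237037037, 5.394318200, 14, 12.18, 12),
    "CHLM":    (0.789568282, 11, 1.02, 12, 1.126666667, 4.805231732, 13, 12.24, 13),
    "GAPDH":   (0.979666168, 13, 1.72, 16, 0.632592593, 2.999806804, 9, 12.80, 14),
    "ACTIN2":  (1.091030519, 14, 1.55, 14, 1.726666667, 7.180482395, 17, 14.95, 15),
    "RBP45B":  (1.200799573, 15, 1.71, 15, 1.592592593, 6.176297382, 16, 15.74, 16),
    "UBQ10":   (1.294148460, 16, 1.85, 17, 1.560740741, 6.660660376, 15, 16.48, 17),
}

_COLUMNS = [
    "genorm_m", "genorm_rank",
    "normfinder_s", "normfinder_rank",
    "bestkeeper_sd", "bestkeeper_cv", "bestkeeper_rank",
    "reffinder_geomean", "reffinder_rank",
]

# Per-method five most stable genes, best first, as published.
_TOP5 = {
    "deltact": ["PSBW", "PSBX", "LHCB4.1", "LHCB5", "SCA1"],
    "genorm": ["SCA1", "LHCA3", "LHCB5", "LHCB4.1", "PSBW"],
    "normfinder": ["PSBW", "PSBX", "LHCB4.1", "LHCA3", "LHCB5"],
    "bestkeeper": ["COL4", "ARFA1E", "LHCB5", "TCTP1", "LHCB4.1"],
    "reffinder": ["PSBW", "LHCB4.1", "LHCB5", "PSBX", "COL4"],
}


def arabidopsis_heat_stability() -> pd.DataFrame:
    """Per-gene published stability statistics and ranks (17 genes x 9 columns)."""
    df = pd.DataFrame.from_dict(_STABILITY_ROWS, orient="index", columns=_COLUMNS)
    df.index.name = "gene"
    for col in df.columns:
        if col.endswith("_rank"):
            df[col] = df[col].astype(int)
    return df


def arabidopsis_heat_top5() -> dict[str, list[str]]:
    """Published per-method top-5 most-stable gene lists, best first."""
    return {m: list(genes) for m, genes in _TOP5.items()}
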