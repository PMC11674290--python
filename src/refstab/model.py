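"""Shared data model for qPCR cycle-threshold (Ct) analysis.

The central container is :class:`CtMatrix`: a complete gene x sample matrix
of cycle-threshold values together with a group (condition) label per
sample.  All stability statistics in :mod:`refstab.stability` consume either
a ``CtMatrix`` or the :class:`QuantityMatrix` obtained from it by
:func:`ct_to_quantities`, which re-expresses each gene's Ct values as
relative quantities ``Q = E**(Ct_min - Ct)`` (per-gene maximum 1) for a
per-cycle amplification efficiency ``E`` (2.0 for perfect doubling).

Missing or non-numeric Ct values are rejected, never imputed: every
downstream statistic assumes a complete matrix, and silently dropping or
filling cells would change all of them at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "ExpressionMatrix",
    "QuantityMatrix",
    "SimulationTruth",
    "ValidationReport",
    "ct_to_quantities",
    "validate_ct_matrix",
]

# Plausibility band for Ct values in a well-behaved qPCR run; values outside
# it are flagged as soft warnings, not errors.
CT_SOFT_RANGE = (10.0, 40.0)


def _check_axis_unique(index: pd.Index, what: str) -> list[str]:
    problems = []
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        problems.append(f"duplicate {what} ids: {dups}")
    return problems


def _hard_violations(data: pd.DataFrame, groups: pd.Series | None) -> list[str]:
    problems = []
    problems += _check_axis_unique(data.index, "gene")
    problems += _check_axis_unique(data.columns, "sample")
    bad = ~np.isfinite(data.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        for i, j in zip(*np.nonzero(bad)):
            problems.append(
                f"non-finite Ct for gene {data.index[i]!r}, sample {data.columns[j]!r}"
            )
    if groups is not None:
        missing = [s for s in data.columns if s not in groups.index]
        if missing:
            problems.append(f"samples without a group label: {missing}")
        unknown = [s for s in groups.index if s not in data.columns]
        if unknown:
            problems.append(f"group map names unknown samples: {unknown}")
    return problems


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_ct_matrix`: hard violations and soft warnings."""

    hard: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.hard


@dataclass(frozen=True)
class CtMatrix:
    """Complete gene x sample matrix of qPCR cycle-threshold values.

    Parameters
    ----------
    data
        Float DataFrame, genes as rows, samples as columns.  All values
        must be finite; ids on both axes must be unique.
    groups
        Series mapping every sample id to a condition label
        (e.g. ``control`` / ``heat42`` / ``heat32``).
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        data = self.data.astype(float)
        problems = _hard_violations(data, pd.Series(self.groups))
        groups = pd.Series(self.groups).reindex(data.columns)
        if groups.isna().any():
            problems.append(
                f"samples without a group label: {list(groups.index[groups.isna()])}"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "groups", groups if groups.isna().any() else groups.astype(str))
        if data.shape[0] < 2 or data.shape[1] < 2:
            problems.append(f"need at least 2 genes and 2 samples, got {data.shape}")
        if problems:
            raise ValueError("invalid Ct matrix: " + "; ".join(problems))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset(self, genes: Iterable[str]) -> "CtMatrix":
        genes = list(genes)
        return CtMatrix(self.data.loc[genes], self.groups)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative abundance matrix (FPKM-like units), genes x samples/tissues."""

    data: pd.DataFrame

    def __post_init__(self):
        data = self.data.astype(float)
        object.__setattr__(self, "data", data)
        problems = _hard_violations(data, None)
        if (data.to_numpy() < 0).any():
            bad = (data < 0).any(axis=1)
            problems.append(f"negative expression values for genes {list(data.index[bad])}")
        if problems:
            raise ValueError("invalid expression matrix: " + "; ".join(problems))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class QuantityMatrix:
    """Relative quantities ``Q = E**(Ct_min - Ct)``, anchored at each gene's minimum Ct.

    ``0 < Q <= 1`` with at least one ``Q == 1`` per gene row.  ``efficiency``
    is the per-cycle amplification factor (Series, one value per gene).
    """

    data: pd.DataFrame
    efficiency: pd.Series
    groups: pd.Series | None = None

    def __post_init__(self):
        q = self.data.to_numpy(dtype=float)
        if not np.isfinite(q).all() or (q <= 0).any() or (q > 1 + 1e-12).any():
            raise ValueError("relative quantities must lie in (0, 1]")
        if not np.allclose(q.max(axis=1), 1.0):
            raise ValueError("each gene row must attain Q = 1 at its minimum-Ct sample")
        if (self.efficiency <= 1).any():
            raise ValueError("amplification efficiency must exceed 1")

    def log2(self) -> pd.DataFrame:
        """log2-scale quantities; at efficiency 2 these equal ``Ct_min - Ct``."""
        return np.log2(self.data)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth behind a simulated Ct matrix.

    ``baselines`` are per-gene baseline Ct (cycles); ``shifts`` is a
    gene x group matrix of additive condition effects (cycles);
    ``sigmas`` are per-gene replicate noise SDs (cycles).
    """

    baselines: pd.Series
    shifts: pd.DataFrame
    sigmas: pd.Series

    def __post_init__(self):
        if (self.sigmas < 0).any():
            raise ValueError("replicate noise SD must be nonnegative")
        if not self.baselines.index.equals(self.shifts.index) or not self.baselines.index.equals(
            self.sigmas.index
        ):
            raise ValueError("baselines, shifts and sigmas must share one gene index")

    def destabilization_score(self) -> pd.Series:
        """sqrt(sigma^2 + population variance of the per-group shifts), per gene."""
        shift_var = self.shifts.var(axis=1, ddof=0)
        return np.sqrt(self.sigmas**2 + shift_var)

    def true_order(self) -> list[str]:
        """Genes from most to least stable (score ties broken by gene id)."""
        score = self.destabilization_score().sort_index(kind="stable")
        return list(score.sort_values(kind="stable").index)


def _efficiency_series(efficiency, gene_index: pd.Index) -> pd.Series:
    if np.isscalar(efficiency):
        eff = pd.Series(float(efficiency), index=gene_index)
    else:
        eff = pd.Series(efficiency, dtype=float).reindex(gene_index)
        if eff.isna().any():
            raise ValueError(
                f"efficiency missing for genes {list(eff.index[eff.isna()])}"
            )
    if (eff <= 1).any():
        raise ValueError("amplification efficiency must exceed 1")
    return eff


def ct_to_quantities(ct: CtMatrix, efficiency=2.0) -> QuantityMatrix:
    """Convert Ct values to relative quantities anchored at each gene's minimum Ct.

    ``Q[g, s] = E_g ** (min_s' Ct[g, s'] - Ct[g, s])``, so the lowest-Ct
    (highest-expression) sample of every gene gets Q = 1.  The anchor is pure
    numerical hygiene: all downstream stability statistics are invariant to it.

    ``efficiency`` may be a scalar (default 2.0, perfect doubling) or a
    per-gene mapping/Series.
    """
    eff = _efficiency_series(efficiency, ct.data.index)
    delta = ct.data.min(axis=1).to_numpy()[:, None] - ct.data.to_numpy()
    q = np.power(eff.to_numpy()[:, None], delta)
    return QuantityMatrix(
        data=pd.DataFrame(q, index=ct.data.index, columns=ct.data.columns),
        efficiency=eff,
        groups=ct.groups,
    )


def validate_ct_matrix(ct: CtMatrix | pd.DataFrame, groups: pd.Series | None = None) -> ValidationReport:
    """Report hard violations (non-finite cells, duplicate ids) and soft warnings.

    Soft warnings flag Ct values outside the ``[10, 40]`` plausibility band —
    well-behaved candidate reference genes typically sit in the low-to-high
    twenties.  The input is never modified.
    """
    if isinstance(ct, CtMatrix):
        data, groups = ct.data, ct.groups
    else:
        data = pd.DataFrame(ct).astype(float)
    hard = _hard_violations(data, groups)
    lo, hi = CT_SOFT_RANGE
    vals = data.to_numpy(dtype=float)
    warnings = []
    with np.errstate(invalid="ignore"):
        outside = np.isfinite(vals) & ((vals < lo) | (vals > hi))
    for i, j in zip(*np.nonzero(outside)):
        warnings.append(
            f"Ct {vals[i, j]:g} outside [{lo:g}, {hi:g}] for gene "
            f"{data.index[i]!r}, sample {data.columns[j]!r}"
        )
    return ValidationReport(hard=hard, warnings=warnings)
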