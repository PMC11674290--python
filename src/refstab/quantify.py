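"""Comparative 2^-ddCt quantification of a target gene against chosen references.

Given a complete Ct matrix, a target gene, one or more reference genes, a
calibrator group and a treatment group:

* per sample, ``refCt`` is the arithmetic mean of the reference Ct values
  (at efficiency 2 this is the log2 of the geometric mean of reference
  quantities — the standard multi-gene normalization factor);
* ``dCt = Ct_target - refCt`` per sample;
* ``ddCt = mean_treatment(dCt) - mean_calibrator(dCt)``;
* ``fold = E**(-ddCt)``, the treatment/calibrator expression ratio.

The companion diagnostic :func:`reference_shift` measures how far a
reference gene's own mean Ct moves between two conditions; a reference
that shifts by several cycles inflates apparent target fold changes by
2^shift, which is exactly how unstable references mislead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CtMatrix

__all__ = [
    "QuantificationResult",
    "ddct_fold_change",
    "reference_shift",
    "group_comparison_test",
]

SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"))


@dataclass(frozen=True)
class QuantificationResult:
    """Per-sample dCt, group means, ddCt, fold change and a Welch-test verdict."""

    target: str
    refs: list[str]
    calibrator_group: str
    treatment_group: str
    delta_ct: pd.Series  # per sample, cycles
    group_means: pd.Series  # per group mean dCt, cycles
    ddct: float
    fold_change: float
    p_value: float
    tier: str

    def __post_init__(self):
        assert self.fold_change > 0


def _group_samples(ct: CtMatrix, group: str) -> list[str]:
    samples = ct.samples_in(group)
    if not samples:
        raise ValueError(f"group {group!r} has no samples")
    return samples


def significance_tier(p: float) -> str:
    for threshold, mark in SIGNIFICANCE_TIERS:
        if p < threshold:
            return mark
    return ""


def ddct_fold_change(
    ct: CtMatrix,
    target: str,
    refs: Iterable[str],
    calibrator_group: str,
    treatment_group: str,
    efficiency: float = 2.0,
) -> QuantificationResult:
    """Relative expression of ``target`` in treatment vs calibrator via 2^-ddCt."""
    refs = list(refs)
    if not refs:
        raise ValueError("need at least one reference gene")
    if target in refs:
        raise ValueError(f"target {target!r} cannot be its own reference")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    cal = _group_samples(ct, calibrator_group)
    trt = _group_samples(ct, treatment_group)

    ref_ct = ct.data.loc[refs].mean(axis=0)
    dct = ct.data.loc[target] - ref_ct
    group_means = pd.Series(
        {calibrator_group: dct[cal].mean(), treatment_group: dct[trt].mean()}
    )
    ddct = float(group_means[treatment_group] - group_means[calibrator_group])
    fold = float(efficiency ** (-ddct))

    if len(cal) >= 2 and len(trt) >= 2:
        p, tier = group_comparison_test(dct[cal].to_numpy(), dct[trt].to_numpy())
    else:
        p, tier = float("nan"), ""
    return QuantificationResult(
        target=target,
        refs=refs,
        calibrator_group=calibrator_group,
        treatment_group=treatment_group,
        delta_ct=dct,
        group_means=group_means,
        ddct=ddct,
        fold_change=fold,
        p_value=p,
        tier=tier,
    )


def reference_shift(ct: CtMatrix, ref: str, group_a: str, group_b: str) -> float:
    """Absolute displacement (cycles) of a reference gene's mean Ct between groups.

    Near-zero shifts are what qualify a gene as a usable reference; shifts of
    2+ cycles mean a 4x or larger hidden normalization error.
    """
    a = _group_samples(ct, group_a)
    b = _group_samples(ct, group_b)
    return float(abs(ct.data.loc[ref, a].mean() - ct.data.loc[ref, b].mean()))


def group_comparison_test(
    delta_ct_calibrator: Sequence[float], delta_ct_treatment: Sequence[float]
) -> tuple[float, str]:
    """Two-sided Welch t-test on replicate dCt values, with significance tier.

    Tiers follow the usual figure annotation: '**' for p < 0.01 and '***'
    for p < 0.001 (empty string otherwise).
    """
    a = np.asarray(delta_ct_calibrator, dtype=float)
    b = np.asarray(delta_ct_treatment, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates for the t-test")
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return p, significance_tier(p)
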