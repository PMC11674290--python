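"""Synthetic Ct and FPKM data with known ground truth.

The Ct generator follows the standard qPCR error model: each measurement is

    Ct[g, s] = baseline_g + shift_{g, group(s)} + Normal(0, sigma_g^2)

i.e. additive Gaussian noise on the cycle scale, which is multiplicative
noise on expression.  A gene's *destabilization score* is
``sqrt(sigma_g^2 + Var_groups(shift_g))`` — replicate noise plus condition
response — and sorting it ascending gives the true stability order the
stability methods should recover.

The default scenario mirrors a three-condition heat-stress design (control
at 22C, acute 42C, chronic 32C; three samples each) with 15 candidate
genes: 12 stable, one heat-responsive (a 2-cycle shift in one condition)
and two noisy.

The FPKM generator draws each gene log-normally, calibrated so realized
mean and CV converge to their targets as the sample count grows; it feeds
the screening funnel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CtMatrix, ExpressionMatrix, SimulationTruth

__all__ = [
    "simulate_ct",
    "simulate_fpkm",
    "heat_stress_truth",
    "default_group_sizes",
    "recovery_trial",
]

DEFAULT_GROUPS = {"control": 3, "heat42": 3, "heat32": 3}

# Default 15-gene scenario composition
N_STABLE = 12
STABLE_SIGMA = 0.15  # cycles, typical technical replicate scatter
NOISY_SIGMA = 1.0  # cycles
SHIFT_CYCLES = 2.0  # condition response of the destabilized gene
BASELINE_RANGE = (18.0, 28.0)  # typical Ct span of abundant transcripts


def default_group_sizes() -> dict[str, int]:
    return dict(DEFAULT_GROUPS)


def heat_stress_truth(seed: int, *, n_stable: int = N_STABLE) -> SimulationTruth:
    """Ground truth for the default scenario: 12 stable, 1 shifted, 2 noisy genes.

    Baselines are drawn uniformly from the typical Ct range; the seed fixes
    them.  Gene ids encode their role (``stable01``..., ``shifted1``,
    ``noisy1``/``noisy2``) so recovered rankings are self-explanatory.
    """
    rng = np.random.default_rng(seed)
    genes = (
        [f"stable{i:02d}" for i in range(1, n_stable + 1)]
        + ["shifted1"]
        + ["noisy1", "noisy2"]
    )
    baselines = pd.Series(rng.uniform(*BASELINE_RANGE, size=len(genes)), index=genes)
    shifts = pd.DataFrame(0.0, index=genes, columns=list(DEFAULT_GROUPS))
    shifts.loc["shifted1", "heat42"] = SHIFT_CYCLES
    sigmas = pd.Series(STABLE_SIGMA, index=genes)
    sigmas.loc[["noisy1", "noisy2"]] = NOISY_SIGMA
    return SimulationTruth(baselines=baselines, shifts=shifts, sigmas=sigmas)


def simulate_ct(
    truth: SimulationTruth,
    group_sizes: Mapping[str, int] | None = None,
    seed: int | None = None,
) -> tuple[CtMatrix, SimulationTruth]:
    """Draw a replicated Ct matrix from the generative model above.

    Samples are named ``<group>_<i>``; reproducible for a fixed seed.
    """
    if group_sizes is None:
        group_sizes = {g: DEFAULT_GROUPS.get(g, 3) for g in truth.shifts.columns}
    unknown = set(group_sizes) - set(truth.shifts.columns)
    if unknown:
        raise ValueError(f"groups without a shift column: {sorted(unknown)}")
    if any(n < 1 for n in group_sizes.values()):
        raise ValueError("every group needs at least one sample")
    rng = np.random.default_rng(seed)
    genes = list(truth.baselines.index)
    columns, labels = [], []
    blocks = []
    for group, n in group_sizes.items():
        mean = truth.baselines.to_numpy()[:, None] + truth.shifts[group].to_numpy()[:, None]
        noise = rng.normal(0.0, truth.sigmas.to_numpy()[:, None], size=(len(genes), n))
        blocks.append(mean + noise)
        columns += [f"{group}_{i}" for i in range(1, n + 1)]
        labels += [group] * n
    data = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    groups = pd.Series(labels, index=columns)
    return CtMatrix(data=data, groups=groups), truth


def simulate_fpkm(
    means: Sequence[float] | pd.Series,
    cvs: Sequence[float] | pd.Series,
    n_samples: int,
    seed: int | None = None,
    gene_ids: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Log-normal abundance matrix with per-gene target mean and CV.

    For target mean m and CV c the log-normal parameters are
    ``sigma^2 = ln(1 + c^2)`` and ``mu = ln(m) - sigma^2 / 2``, so realized
    moments converge to the targets as ``n_samples`` grows.  CV 0 yields a
    constant gene; mean 0 an all-zero gene.
    """
    means = np.asarray(means, dtype=float)
    cvs = np.asarray(cvs, dtype=float)
    if means.shape != cvs.shape:
        raise ValueError("means and cvs must align")
    if (means < 0).any():
        raise ValueError("means must be nonnegative")
    if (cvs < 0).any():
        raise ValueError("CV targets must be nonnegative")
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(1, len(means) + 1)]
    rng = np.random.default_rng(seed)
    rows = np.empty((len(means), n_samples))
    for i, (m, c) in enumerate(zip(means, cvs)):
        if m == 0:
            rows[i] = 0.0
        elif c == 0:
            rows[i] = m
        else:
            sigma2 = np.log1p(c * c)
            mu = np.log(m) - sigma2 / 2.0
            rows[i] = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_samples)
    data = pd.DataFrame(rows, index=list(gene_ids), columns=[f"s{i}" for i in range(1, n_samples + 1)])
    return ExpressionMatrix(data=data)


def recovery_trial(seed: int) -> dict:
    """One rank-recovery experiment on the default 15-gene scenario.

    Simulates a Ct matrix, runs all four stability methods plus the
    geometric-mean consensus, and reports whether the three destabilized
    genes occupy the three worst consensus ranks and whether each method
    individually ranks the shifted gene worse than every stable gene.
    """
    from .consensus import reffinder_geomean
    from .stability import METHODS, run_all_methods

    truth = heat_stress_truth(seed)
    ct, _ = simulate_ct(truth, seed=seed + 1)
    tables = run_all_methods(ct)
    ranks = pd.DataFrame({m: tables[m]["rank"] for m in METHODS})
    consensus = reffinder_geomean(ranks)

    destabilized = {"shifted1", "noisy1", "noisy2"}
    stable = [g for g in ct.gene_ids if g not in destabilized]
    worst3 = set(consensus.sort_values("geomean", kind="stable").index[-3:])
    shifted_worse = {
        m: bool((tables[m].loc["shifted1", "value"] > tables[m].loc[stable, "value"]).all())
        for m in METHODS
    }
    return {
        "consensus": consensus,
        "tables": tables,
        "truth": truth,
        "destabilized_in_worst3": worst3 == destabilized,
        "shifted_worse_than_all_stable": shifted_worse,
    }
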