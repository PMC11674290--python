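import numpy as np
import pandas as pd
import pytest

from refstab.model import CtMatrix


@pytest.fixture
def toy_ct() -> CtMatrix:
    """Three genes, three samples; A drifts, B is flat, C nearly flat.

    Hand-computed pair SDs: SD(A-B) = 1.0, SD(A-C) = SD(B-C) = 1/sqrt(3).
    """
    data = pd.DataFrame(
        [[20.0, 21.0, 22.0], [25.0, 25.0, 25.0], [30.0, 30.0, 31.0]],
        index=["A", "B", "C"],
        columns=["s1", "s2", "s3"],
    )
    groups = pd.Series({"s1": "control", "s2": "control", "s3": "heat"})
    return CtMatrix(data=data, groups=groups)


@pytest.fixture
def random_ct_factory():
    """Random Ct matrices in the plausible 18-28 cycle band, grouped in halves."""

    def make(n_genes: int, n_samples: int, seed: int) -> CtMatrix:
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            rng.uniform(18, 28, size=(n_genes, n_samples)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        labels = ["a"] * (n_samples // 2) + ["b"] * (n_samples - n_samples // 2)
        return CtMatrix(data=data, groups=pd.Series(labels, index=data.columns))

    return make


def pair_sd_oracle(ct: CtMatrix, g: str, h: str) -> float:
    """Direct loop-free oracle: sample SD of the per-sample Ct difference."""
    diff = ct.data.loc[g] - ct.data.loc[h]
    return float(diff.std(ddof=1))


def genorm_greedy_oracle(ct: CtMatrix) -> tuple[list[str], list[str]]:
    """Naive reference geNorm: plain-python M computation and greedy exclusion.

    Returns (exclusion order, final pair sorted).  Independent of the
    package's vectorized covariance path.
    """
    remaining = list(ct.data.index)
    excluded = []
    while len(remaining) > 2:
        m = {}
        for g in remaining:
            sds = [pair_sd_oracle(ct, g, h) for h in remaining if h != g]
            m[g] = sum(sds) / len(sds)
        worst = max(m.values())
        victim = sorted(g for g in remaining if m[g] == worst)[-1]
        excluded.append(victim)
        remaining.remove(victim)
    return excluded, sorted(remaining)
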