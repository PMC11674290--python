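"""The four reference-gene stability algorithms: comparative ΔCt, geNorm,
NormFinder and BestKeeper.

All four score candidate reference genes on a lower-is-more-stable scale:

* **ΔCt** — for every gene pair, the sample SD of the per-sample Ct
  difference; a gene's score is its mean pairwise SD.
* **geNorm** — the same pairwise machinery expressed on log2 relative
  quantities (at efficiency 2 the pairwise variation ``V_jk`` coincides
  exactly with the ΔCt pair SD).  The M value of a gene is its average
  ``V_jk`` against the rest of the candidate set; the stepwise ranking
  repeatedly drops the worst gene and recomputes, leaving the final two
  genes tied at rank 1.  The V-series ``V_n`` (SD of log-ratios between
  normalization factors built from the n and n+1 best genes) decides how
  many reference genes suffice, with the conventional 0.15 cutoff.
* **NormFinder** — a variance-decomposition model on sample-centered log2
  quantities; grouped mode combines each gene's intergroup expression bias
  with its within-group variance.
* **BestKeeper** — descriptive statistics of the raw Ct values (geometric/
  arithmetic mean, min, max, SD as mean absolute deviation, CV%), with
  genes whose SD exceeds 1.0 cycles deemed unsuitable.

All ranks are dense: tied values share a rank and the next distinct value
increments it by one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CtMatrix, QuantityMatrix
from .consensus import rank_by_value

__all__ = [
    "METHODS",
    "deltact_scores",
    "pairwise_variation_matrix",
    "genorm_m",
    "genorm_ranking",
    "genorm_pairwise_variation",
    "optimal_reference_count",
    "m_threshold_classify",
    "normfinder_stability",
    "bestkeeper_descriptives",
    "bestkeeper_index_correlation",
    "GeNormResult",
    "NormFinderResult",
    "stability_table",
    "run_all_methods",
]

METHODS = ("deltact", "genorm", "normfinder", "bestkeeper")

# geNorm's conventional decision thresholds
DEFAULT_M_THRESHOLD = 1.5
DEFAULT_V_THRESHOLD = 0.15
# BestKeeper's suitability cutoff on the Ct SD, in cycles
DEFAULT_BESTKEEPER_SD_THRESHOLD = 1.0


def stability_table(values: pd.Series, method: str) -> pd.DataFrame:
    """Assemble the canonical per-gene (value, rank) table, dense-ranked ascending."""
    table = pd.DataFrame({"value": values.astype(float)})
    table["rank"] = rank_by_value(table["value"], ascending=True)
    table.index.name = "gene"
    table.attrs["method"] = method
    return table


def _pairwise_diff_sd(rows: np.ndarray) -> np.ndarray:
    """SD over samples of (row_j - row_k) for every pair, via the covariance matrix.

    Var(X_j - X_k) = C_jj + C_kk - 2 C_jk with the n-1 (sample) covariance.
    """
    c = np.cov(rows, ddof=1)
    c = np.atleast_2d(c)
    d = np.diag(c)
    var = d[:, None] + d[None, :] - 2.0 * c
    np.fill_diagonal(var, 0.0)
    return np.sqrt(np.clip(var, 0.0, None))


def deltact_scores(ct: CtMatrix) -> pd.DataFrame:
    """Comparative ΔCt stability scores.

    For each ordered pair (g, h), ``pairSD(g, h)`` is the sample SD over
    samples of ``Ct[g, s] - Ct[h, s]``; a gene's score is the mean pair SD
    against all other genes.  Lower scores mean the gene moves in lockstep
    with the rest of the candidate panel.
    """
    if ct.data.shape[1] < 2:
        raise ValueError("deltact_scores needs at least 2 samples")
    sd = _pairwise_diff_sd(ct.data.to_numpy())
    g = sd.shape[0]
    scores = sd.sum(axis=1) / (g - 1)
    return stability_table(pd.Series(scores, index=ct.data.index), "deltact")


def pairwise_variation_matrix(q: QuantityMatrix) -> pd.DataFrame:
    """geNorm pairwise variation V_jk = SD over samples of log2(Q_j / Q_k).

    Symmetric with an undefined (NaN) diagonal.  At efficiency 2 this equals
    the ΔCt method's pair SD of (Ct_k - Ct_j).
    """
    log_q = q.log2().to_numpy()
    v = _pairwise_diff_sd(log_q)
    np.fill_diagonal(v, np.nan)
    return pd.DataFrame(v, index=q.data.index, columns=q.data.index)


def genorm_m(q: QuantityMatrix, subset: Iterable[str] | None = None) -> pd.Series:
    """Average expression stability M for each gene of ``subset``.

    ``M(j)`` is the mean of ``V_jk`` over the other genes of the subset;
    lower M = more stable.
    """
    genes = list(subset) if subset is not None else list(q.data.index)
    if len(genes) < 2:
        raise ValueError("genorm_m needs at least 2 genes")
    v = pairwise_variation_matrix(
        QuantityMatrix(
            data=q.data.loc[genes],
            efficiency=q.efficiency.loc[genes],
            groups=q.groups,
        )
    )
    return v.mean(axis=1, skipna=True)


@dataclass(frozen=True)
class GeNormResult:
    """Outcome of the stepwise geNorm procedure.

    ``ranking`` orders genes best-first (the two never-excluded genes come
    first, tied at rank 1); ``m_values`` holds each gene's M at the step it
    was excluded (for the final pair, their shared two-gene M);
    ``v_series`` maps n -> V_n for n = 2..G-1; ``optimal_n`` is the smallest
    n with V_n below the threshold, or None.
    """

    ranking: list[str]
    ranks: pd.Series
    m_values: pd.Series
    exclusion_order: list[str]
    v_series: pd.Series
    optimal_n: int | None

    @property
    def table(self) -> pd.DataFrame:
        t = pd.DataFrame({"value": self.m_values, "rank": self.ranks})
        t.index.name = "gene"
        t.attrs["method"] = "genorm"
        return t.loc[self.ranking]


def _genorm_exclusion(q: QuantityMatrix) -> tuple[list[str], pd.Series]:
    """Iteratively drop the least stable gene; ties drop the lexicographically last id."""
    remaining = list(q.data.index)
    excluded: list[str] = []
    m_final: dict[str, float] = {}
    while len(remaining) > 2:
        m = genorm_m(q, remaining)
        worst_m = m.max()
        ties = sorted(m.index[m == worst_m])
        victim = ties[-1]
        m_final[victim] = float(m.loc[victim])
        excluded.append(victim)
        remaining.remove(victim)
    last_m = genorm_m(q, remaining)
    for g in remaining:
        m_final[g] = float(last_m.loc[g])
    return excluded, pd.Series(m_final)


def genorm_ranking(
    q: QuantityMatrix, v_threshold: float = DEFAULT_V_THRESHOLD
) -> GeNormResult:
    """Full stepwise geNorm analysis: exclusion ranking, M values, V-series.

    Needs at least 3 genes.  The two genes never excluded share rank 1; the
    gene excluded at the final step gets rank 2, and so on backwards.
    """
    genes = list(q.data.index)
    if len(genes) < 3:
        raise ValueError("genorm_ranking needs at least 3 genes")
    excluded, m_values = _genorm_exclusion(q)
    survivors = sorted(g for g in genes if g not in excluded)
    ranking = survivors + list(reversed(excluded))
    ranks = pd.Series(0, index=pd.Index(ranking, name="gene"), dtype=int)
    ranks.iloc[:2] = 1
    ranks.iloc[2:] = np.arange(2, len(ranking))
    v_series = genorm_pairwise_variation(q, ranking)
    return GeNormResult(
        ranking=ranking,
        ranks=ranks,
        m_values=m_values.reindex(ranking),
        exclusion_order=excluded,
        v_series=v_series,
        optimal_n=optimal_reference_count(v_series, v_threshold),
    )


def genorm_pairwise_variation(q: QuantityMatrix, ranking: Sequence[str]) -> pd.Series:
    """V-series: V_n = SD over samples of log2(NF_n / NF_{n+1}), n = 2..G-1.

    ``NF_n[s]`` is the geometric mean of the relative quantities of the n
    top-ranked genes at sample s.  A small V_n means adding the (n+1)-th
    gene barely changes the normalization factor.
    """
    ranking = list(ranking)
    g = len(ranking)
    if g < 3:
        return pd.Series(dtype=float, name="V")
    log_q = q.log2().loc[ranking].to_numpy()
    # log2 NF_n = mean of the top-n rows of log2 Q
    cum = np.cumsum(log_q, axis=0)
    out = {}
    for n in range(2, g):
        log_nf_n = cum[n - 1] / n
        log_nf_n1 = cum[n] / (n + 1)
        out[n] = float(np.std(log_nf_n - log_nf_n1, ddof=1))
    return pd.Series(out, name="V")


def optimal_reference_count(
    v_series: pd.Series | Mapping[int, float] | Sequence[float],
    threshold: float = DEFAULT_V_THRESHOLD,
) -> int | None:
    """Smallest n whose pairwise variation V_n falls below ``threshold``.

    A bare sequence is taken to start at n = 2.  Returns None when no n
    qualifies; the caller decides the fallback.
    """
    if isinstance(v_series, pd.Series):
        items = list(v_series.items())
    elif isinstance(v_series, Mapping):
        items = sorted(v_series.items())
    else:
        items = list(enumerate(v_series, start=2))
    if not items:
        raise ValueError("empty V-series")
    for n, v in items:
        if v < threshold:
            return int(n)
    return None


def m_threshold_classify(
    m_values: pd.Series | Mapping[str, float], threshold: float = DEFAULT_M_THRESHOLD
) -> set[str]:
    """Genes whose M value lies strictly below ``threshold`` (suitable candidates)."""
    m = pd.Series(m_values, dtype=float)
    return set(m.index[m < threshold])


@dataclass(frozen=True)
class NormFinderResult:
    """NormFinder stability values, plus per-group decomposition when grouped.

    ``intergroup`` (d) is each gene's group-mean deviation from its overall
    mean; ``intragroup_var`` (v) the within-group variance of the centered
    log2 quantities.  Both are None in ungrouped mode.
    """

    table: pd.DataFrame
    grouped: bool
    intergroup: pd.DataFrame | None = None
    intragroup_var: pd.DataFrame | None = None


def normfinder_stability(
    q: QuantityMatrix, groups: pd.Series | None = None
) -> NormFinderResult:
    """NormFinder expression stability S; lower = more stable.

    Works on sample-centered log2 quantities ``z[g, s]``.  Ungrouped, S is
    simply each gene's sample SD of z.  Grouped, each gene's S combines the
    absolute intergroup difference d with the standard error of its
    within-group variation: ``S(g) = mean_a(|d[g, a]| + sqrt(v[g, a]/n_a))``.
    The intergroup difference carries no shrinkage toward zero.
    """
    if q.data.shape[0] < 3:
        raise ValueError("normfinder_stability needs at least 3 genes")
    x = q.log2()
    z = x - x.mean(axis=0)
    if groups is None:  # pooled mode: no condition structure assumed
        s = z.std(axis=1, ddof=1)
        return NormFinderResult(table=stability_table(s, "normfinder"), grouped=False)

    groups = pd.Series(groups).reindex(z.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label in grouped mode")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        raise ValueError(f"grouped NormFinder needs >= 2 samples per group; too small: {small}")

    group_names = list(dict.fromkeys(groups))
    means = pd.DataFrame(
        {a: z.loc[:, groups[groups == a].index].mean(axis=1) for a in group_names}
    )
    d = means.sub(means.mean(axis=1), axis=0)
    v = pd.DataFrame(
        {a: z.loc[:, groups[groups == a].index].var(axis=1, ddof=1) for a in group_names}
    )
    n_a = pd.Series({a: int(sizes[a]) for a in group_names})
    per_group = d.abs() + np.sqrt(v.div(n_a, axis=1))
    s = per_group.mean(axis=1)
    return NormFinderResult(
        table=stability_table(s, "normfinder"),
        grouped=True,
        intergroup=d,
        intragroup_var=v,
    )


def bestkeeper_descriptives(ct: CtMatrix, *, use_sample_sd: bool = False) -> pd.DataFrame:
    """BestKeeper descriptive statistics of the raw Ct values, per gene.

    ``sd`` ("SD [+-CP]") defaults to the mean absolute deviation from the
    arithmetic mean, the original tool's definition; ``use_sample_sd``
    switches to the n-1 sample SD.  ``cv`` is 100*sd/mean (% CP).  Genes
    with sd <= 1.0 cycles are flagged suitable.  Dense rank ascending by sd.
    """
    if ct.data.shape[1] < 2:
        raise ValueError("bestkeeper_descriptives needs at least 2 samples")
    vals = ct.data
    if (vals.to_numpy() <= 0).any():
        raise ValueError("BestKeeper geometric mean undefined for nonpositive Ct")
    arith = vals.mean(axis=1)
    if use_sample_sd:
        sd = vals.std(axis=1, ddof=1)
    else:
        sd = (vals.sub(arith, axis=0)).abs().mean(axis=1)
    table = pd.DataFrame(
        {
            "n": vals.shape[1],
            "geo_mean": np.exp(np.log(vals).mean(axis=1)),
            "arith_mean": arith,
            "min": vals.min(axis=1),
            "max": vals.max(axis=1),
            "value": sd,
            "cv": 100.0 * sd / arith,
        }
    )
    table["suitable"] = table["value"] <= DEFAULT_BESTKEEPER_SD_THRESHOLD
    table["rank"] = rank_by_value(table["value"], ascending=True)
    table.index.name = "gene"
    table.attrs["method"] = "bestkeeper"
    return table


def bestkeeper_index_correlation(
    ct: CtMatrix, subset: Iterable[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation of each gene's Ct profile with the BestKeeper index.

    The index is the per-sample geometric mean of the subset genes' Ct
    values.  Zero-variance genes get NaN r (flagged undefined) rather than
    an error.
    """
    genes = list(subset) if subset is not None else list(ct.data.index)
    if len(genes) < 2:
        raise ValueError("bestkeeper index needs at least 2 genes")
    sub = ct.data.loc[genes]
    if (sub.to_numpy() <= 0).any():
        raise ValueError("BestKeeper index undefined for nonpositive Ct")
    index = np.exp(np.log(sub).mean(axis=0))
    rows = {}
    for g in ct.data.index:
        y = ct.data.loc[g]
        if y.std(ddof=1) == 0 or index.std(ddof=1) == 0:
            rows[g] = (np.nan, np.nan)
        else:
            r, p = stats.pearsonr(y, index)
            rows[g] = (float(r), float(p))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["r", "p"])
    out.index.name = "gene"
    return out


def run_all_methods(
    ct: CtMatrix,
    *,
    efficiency=2.0,
    methods: Sequence[str] = METHODS,
    grouped_normfinder: bool = True,
    bestkeeper_sample_sd: bool = False,
) -> dict[str, pd.DataFrame]:
    """Run the requested stability methods on one Ct matrix.

    Returns a mapping method -> per-gene (value, rank) table; geNorm's table
    carries its full result object in ``attrs["result"]``.
    """
    from .model import ct_to_quantities

    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown stability methods: {sorted(unknown)}")
    q = ct_to_quantities(ct, efficiency=efficiency)
    out: dict[str, pd.DataFrame] = {}
    for method in methods:
        if method == "deltact":
            out[method] = deltact_scores(ct)
        elif method == "genorm":
            res = genorm_ranking(q)
            table = res.table.reindex(ct.data.index)
            table.attrs["method"] = "genorm"
            table.attrs["result"] = res
            out[method] = table
        elif method == "normfinder":
            res = normfinder_stability(q, ct.groups if grouped_normfinder else None)
            out[method] = res.table
        elif method == "bestkeeper":
            out[method] = bestkeeper_descriptives(ct, use_sample_sd=bestkeeper_sample_sd)
    return out
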