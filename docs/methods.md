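# Methods

## Data model and conventions

All statistics run on a complete gene × sample matrix of cycle-threshold
values (Ct, in PCR cycles) with one condition label per sample. Missing
Ct values are rejected, never imputed: every algorithm below assumes a
complete matrix, and imputation would silently perturb all four
statistics at once. Ct tables are gene-rows × sample-columns (the common
qPCR export layout); a transpose flag on the reader handles the other
orientation. Written tables round-trip to 6 decimals.

Relative quantities are Q[g,s] = E^(min_s' Ct[g,s'] − Ct[g,s]) with
per-cycle amplification efficiency E (default 2.0 — perfect doubling, the
assumption behind 2^−ΔΔCt arithmetic; per-gene efficiencies are accepted
and applied in quantity conversion and fold-change computation only).
Anchoring at the per-gene minimum (so 0 < Q ≤ 1) is numerical hygiene:
every downstream statistic is invariant to the anchor, which is covered
by tests. On the log2 scale at E = 2 all geNorm/NormFinder algebra
reduces to Ct differences, so results can be hand-checked in Ct space.

Everywhere a "sample SD" is named it uses the n−1 denominator. The one
deliberate exception is BestKeeper (below). All rankings are dense: tied
values share a rank and the next distinct value increments by one, which
is the convention that lets two genes share rank 1 while the next gene
takes rank 2.

Validation of a Ct matrix separates hard violations (non-finite cells,
duplicate ids, unlabeled samples — constructor errors) from soft warnings
(Ct outside the [10, 40] plausibility band — reported, never fatal).

## Stability algorithms

**Comparative ΔCt.** pairSD(g,h) = SD_s(Ct[g,s] − Ct[h,s]);
score(g) = mean over h≠g. Computed via the covariance identity
Var(X−Y) = Var X + Var Y − 2 Cov(X,Y) on the gene-wise covariance matrix;
tests compare against a direct per-pair loop.

**geNorm.** V_jk = SD_s(log2 Q_j/Q_k); M(j) is the mean V_jk within the
candidate set. The stepwise ranking removes the gene with the largest M
and recomputes until two remain; those two share rank 1. Tie-break on
removal: the lexicographically last gene id is removed first
(deterministic and documented; any fixed rule would do). Each gene's
reported M is its value at the step of its exclusion (the final pair
report their two-gene M). The V-series uses NF_n[s] = geometric mean of
the n best genes' quantities; V_n = SD_s(log2 NF_n/NF_{n+1}), n = 2..G−1.
The optimal reference count is the smallest n with V_n < 0.15; when no n
qualifies the function returns none and the caller decides. Decision
thresholds (M < 1.5 usable, V < 0.15, BestKeeper SD ≤ 1.0) are arguments
with these conventional defaults. Note the identity tested in the suite:
at E = 2, V_jk equals the ΔCt pair SD exactly, so a single geNorm pass
equals the ΔCt score vector — the two methods differ only through
geNorm's iterative exclusion.

**NormFinder.** x = log2 Q is centered per sample (z = x − mean over
genes), removing sample-wide scale effects. Pooled mode: S(g) = SD_s of
z[g,·]. Grouped mode: for each condition a with n_a samples,
d[g,a] = group mean of z minus the gene's grand mean of group means, and
v[g,a] = within-group sample variance; S(g) = mean_a(|d[g,a]| +
√(v[g,a]/n_a)). This follows the published variance-decomposition idea
but applies **no shrinkage** to d — a deliberate simplification, so S
values are not numerically comparable to the legacy add-in's output;
rank order is what the package relies on and what its tests assert.
Grouped mode requires ≥ 2 samples per group (a singleton group has no
within-group variance); both modes are exposed because published studies
rarely state which one they ran.

**BestKeeper.** Per-gene descriptives of the raw Ct values: n, geometric
mean, arithmetic mean, min, max, SD, CV% = 100·SD/mean, suitability flag
SD ≤ 1.0. "SD" here defaults to the **mean absolute deviation** from the
arithmetic mean, the original tool's definition; a switch selects the
n−1 sample SD. Published tables with a handful of decimals cannot
adjudicate the two definitions, so both are offered and the default
follows the original tool. The optional index correlation computes
Pearson r (and two-sided p, via scipy) of each gene against the
per-sample geometric mean of a chosen subset; a zero-variance gene gets
NaN rather than an error.

## Consensus

The combiner consumes a gene × method table of dense ranks and returns
the geometric mean per gene with a dense final rank. It deliberately does
**not** re-run the methods internally: web tools that do so are not
reproducible because their internal re-computation is undocumented, and
published geometric means are accordingly not usable as numeric oracles —
the package treats its explicit combination rule as the definition. The
top-k intersection accepts either ordered lists (first k taken) or rank
series (ties at position k included) and is monotone in k.

## Screening funnel

Stage order: mean filter (> 150 FPKM) → SD-rank cut (keep the 350
lowest-SD survivors) → CV filter (< 0.3) → breadth filter. The sentence
describing the original funnel admits a second reading (CV before the
SD cut), so the order is a config knob; the default is the first reading.
All inequalities are strict. The final published step — manual curation
by tissue-expression distribution — is inherently irreproducible and is
replaced by a quantitative proxy: keep genes whose minimum expression is
at least a fraction (default 0.25) of their median. The proxy is labeled
non-replicating: it emulates "broadly expressed", not the original
curator's judgment. An empty survivor set at any stage is a valid result
with stage counts, not an error.

## Quantification

refCt[s] = arithmetic mean of the reference genes' Ct at sample s (the
geometric mean of their quantities at E = 2 — the standard multi-gene
normalization factor; the combination rule is stated because studies
often omit it). ΔCt = Ct_target − refCt per sample; ΔΔCt is the
difference of *group means* of ΔCt (treatment minus calibrator) — not
per-sample pairing, since replicate pairing across groups is rarely
stated; fold = E^−ΔΔCt. Significance uses Welch's unequal-variance
t-test on replicate ΔCt values ("t-test" in the literature rarely says
which; Welch is the safer default), two-sided, with tiers ** (p < 0.01)
and *** (p < 0.001). With fewer than 2 replicates per group the p-value
is NaN and untiered rather than an error, so single-sample pilot data
still yields a fold change.

## Synthetic data

Ct model: Ct[g,s] = baseline_g + shift_{g,group(s)} + N(0, σ_g²) —
Gaussian noise on the cycle scale, i.e. multiplicative on expression,
the standard qPCR error model. Ground-truth stability is defined as the
destabilization score √(σ_g² + Var_groups(shift_g)) (population variance
over groups), a modeling choice: the literature defines stability only
operationally through the four methods, so the generator needs its own
definition to make "recovery" measurable.

The default scenario emulates a three-condition heat-stress design
(control 22 °C, acute 42 °C, chronic 32 °C; 3 samples each) with 15
genes: 12 stable (σ = 0.15 cycles, a typical technical-replicate
scatter), one shifted (+2 cycles in the acute condition, σ = 0.15) and
two noisy (σ = 1.0). Baselines are uniform on [18, 28] cycles, the span
typical of abundant transcripts.

FPKM model: per-gene log-normal with σ² = ln(1 + CV²),
μ = ln(mean) − σ²/2, so realized mean and CV converge to their targets;
CV 0 yields a constant gene, mean 0 an all-zero gene. The screening
recovery experiments use 48 samples per matrix: a CV estimated from n
samples has standard error ≈ CV/√(2n), and separating a target CV of 0.5
from the 0.3 cutoff reliably needs that error well under the 0.2 gap —
48 samples (≈ 0.05) achieves it and matches the size of a multi-condition
public RNA-seq series.

What the generator does **not** emulate: amplification-efficiency
variation between genes and runs, plate/batch effects, correlated
biological replicates, heavy-tailed outliers from pipetting errors, and
RNA-seq count noise at low abundance. Passing recovery tests therefore
show the algorithms recover the intended signal under clean Gaussian
conditions — not that they are robust to every real-world artifact.

## Numerical choices and degenerate inputs

Pairwise SDs come from the covariance identity with negative round-off
clipped at zero; tolerances in tests are 1e-9 absolute where exactness is
algebraic. Zero-variance genes are legal everywhere except the BestKeeper
index correlation (NaN r) and the geometric means, which require positive
Ct. A gene row with identical values anchors Q = 1 everywhere. geNorm
needs ≥ 3 genes (with exactly 2 there is nothing to exclude); NormFinder
≥ 3 genes (with 2, centering makes the rows exact mirror images and the
statistic degenerates); all methods need ≥ 2 samples.

## Bundled published panel

`refstab.datasets` ships the per-gene stability statistics published for
a 17-gene Arabidopsis heat-stress reference panel (geNorm M, NormFinder
S, BestKeeper SD/CV, with ranks), the five per-method top-5 lists and
the leading pairwise variation V2 = 0.087. The raw Ct measurements behind
that panel were never released, so the package's acceptance checks work
at the level these numbers allow: re-deriving dense ranks from the
printed statistic columns, applying the threshold rules, and intersecting
the top-5 lists. Published consensus geometric means are *not* used as
oracles (see Consensus above); published fold changes are likewise
unreproducible without the raw Ct data and serve only to motivate the
reference-shift diagnostic.

## Known limitations

* No amplification-efficiency estimation from dilution curves; E is a
  user-supplied scalar or per-gene constant.
* The NormFinder S values deviate numerically from the legacy add-in
  (no shrinkage); use ranks for cross-tool comparison.
* The screening breadth proxy approximates, but cannot replicate, manual
  tissue-distribution curation.
* No instrument-native file parsing and no plotting; outputs are tidy
  TSV/JSON for downstream tools.
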