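# refstab

Reference-gene stability analysis for qRT-PCR experiments.

Quantitative real-time PCR measures a target gene's expression relative to
one or more *reference* (housekeeping) genes, via the comparative
2^−ΔΔCt method. The whole construction stands or falls on the references
actually being stable across the experimental conditions — a reference
whose own Ct shifts by *s* cycles between conditions silently multiplies
every reported fold change by 2^*s*. `refstab` is for researchers choosing
and defending reference genes for a condition of interest (heat stress,
drought, a tissue panel, …): it screens candidates from RNA-seq abundance
matrices, scores them with the four standard stability algorithms,
combines the verdicts into a consensus, and validates the chosen
references on a target gene.

## What it computes

Given a complete gene × sample matrix of cycle-threshold values Ct[g, s]
with a condition label per sample (relative quantities are
Q = E^(Ct_min − Ct) at amplification efficiency E, default 2):

* **Comparative ΔCt** — score(g) = mean over partners h of
  SD_s(Ct[g,s] − Ct[h,s]): how much g moves against every other candidate.
* **geNorm** — pairwise variation V_jk = SD_s(log2 Q_j/Q_k); M(j) = mean_k V_jk;
  stepwise exclusion of the worst gene yields the ranking (final two genes
  tied at rank 1, as tradition demands); the V-series
  V_n = SD_s(log2 NF_n/NF_{n+1}) with NF_n the geometric-mean normalization
  factor of the n best genes decides how many references to use
  (V_n < 0.15 ⇒ n suffice). Genes with M < 1.5 count as usable.
  At E = 2, V_jk equals the ΔCt pair SD exactly — the package tests this
  identity rather than assuming it.
* **NormFinder** — on sample-centered log quantities z, either the plain
  residual SD (pooled mode) or the grouped decomposition
  S(g) = mean_a(|d[g,a]| + √(v[g,a]/n_a)) combining intergroup bias d and
  within-group variance v.
* **BestKeeper** — descriptive dispersion of the raw Ct values (SD as mean
  absolute deviation, CV% = 100·SD/mean); SD > 1.0 cycles disqualifies a
  candidate; optional Pearson correlation against the per-sample
  geometric-mean index.
* **Consensus** — geometric mean of the per-method dense ranks
  (RefFinder-style), plus the top-k intersection across methods.
* **Validation** — 2^−ΔΔCt fold change of a target against one or several
  references (multi-reference normalization = arithmetic mean of reference
  Ct = geometric mean of quantities), the reference-shift diagnostic, and a
  two-sided Welch t-test on replicate ΔCt values (`**` p < 0.01,
  `***` p < 0.001).

A synthetic-data module generates Ct matrices
(baseline + condition shift + Gaussian cycle noise) and FPKM matrices
(log-normal with target mean/CV) with known ground truth, so every stage
is testable end to end without any downloads.

## Worked example

```python
import pandas as pd
from refstab import simulate_ct, heat_stress_truth, run_all_methods, reffinder_geomean

truth = heat_stress_truth(seed=7)          # 12 stable, 1 shifted, 2 noisy genes
ct, _ = simulate_ct(truth, seed=8)         # 15 genes x 9 samples, 3 conditions
tables = run_all_methods(ct)               # deltact/genorm/normfinder/bestkeeper
ranks = pd.DataFrame({m: tables[m]["rank"] for m in tables})
print(reffinder_geomean(ranks).tail(3).round(3))
```

prints

```
          deltact  genorm  normfinder  bestkeeper  geomean  final_rank
gene
noisy2         13      12          13          13   12.742          13
shifted1       14      13          14          15   13.982          14
noisy1         15      14          15          14   14.491          15
```

— the three genes simulated as unstable (one shifted 2 cycles under acute
heat, two with 1-cycle replicate noise) occupy the three worst consensus
ranks; the twelve stable genes fill ranks 1–12. The scripts in
`examples/` walk through screening, stability ranking, the bundled
published 17-gene Arabidopsis heat-stress panel, and why an unstable
reference corrupts 2^−ΔΔCt estimates.

A thin CLI mirrors the stages
(`refstab simulate|screen|stability|consensus|quantify|run`); `refstab
run --config config.yaml` chains them and writes TSV tables plus a JSON
run-metadata file.

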