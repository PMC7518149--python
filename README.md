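# milkorder

Unsupervised analysis of dairy **milking order** — the sequence in which
cows enter the milking parlor each morning. Milking order is logged by
every RFID-equipped parlor yet rarely analysed, partly because the
records are ordinal, heteroscedastic, non-independent between animals
and non-stationary in time. `milkorder` provides a tested pipeline of
model-free tools for exactly this kind of data, together with a
synthetic herd generator so every stage can be validated end-to-end:

* **Entry-quantile wrangling** — ordinal positions are normalised by the
  daily herd count to quantiles in (0, 1] (1 = last), then filtered
  (warm-up days, management-transition windows, <75% daily coverage,
  <50% cow attendance).
* **Stochasticity quantification** — Shannon entropy of cow identity
  within each of 20 queue segments, H_q = −Σ_c (n_c|q/N_q) log₂(n_c|q/N_q),
  and of segment membership per cow, H_c = −Σ_q (n_q|c/N_c) log₂(n_q|c/N_c),
  alongside per-cow variance, with one-sided p-values from within-day
  permutation nulls. Entropy is scale-free, outlier-robust and detects
  multimodal queueing that variance cannot.
* **Inter-animal embeddings** — PCA on the pairwise-complete day–day
  correlation matrix, and a diffusion-map-style spectral embedding
  (missingness-scaled Euclidean distances → inverted similarities →
  k = 10 nearest-neighbour graph → normalised graph-Laplacian
  eigenvectors), with path-graph harmonic reference curves to recognise
  the cosine artifact that spectral embeddings imprint on chain-like data.
* **Data Mechanics co-clustering** — alternating Ward (D2) clustering of
  cows and days, each axis re-represented in the other's cluster-mean
  space, iterated until the row×column cells are maximally homogeneous;
  run on a 1–10 × 1–10 grid to expose subgroup-specific temporal shifts
  and to flag whole-herd outlier days that persist in tiny column
  clusters.
* **Mutual conditional entropy (MCE) tests** — association between a
  queue-derived clustering and cow attributes or hourly accelerometer
  time budgets: MCE = ½(H(A|B) + H(B|A)) on the contingency table of two
  Ward-tree clusterings, permutation p-values, and metaparameter grid
  selection by minimal average marginal rank, reported as p₍ka,kb₎.

## Worked example

```python
import milkorder as mo

cfg = mo.SimConfig(n_cows=60, n_days=40, pen_days=15, seed=3, outlier_days=(20, 22))
profiles = mo.draw_herd(cfg)
log = mo.simulate_milkings(profiles, cfg)
qm = mo.filter_cows(mo.filter_days(mo.to_quantiles(log), warmup=0, drop_windows=[]))

res = mo.QueueStochasticity(qm).fit(B=1000, seed=1)
print(res.summary())
print(mo.subperiod_consistency(qm).summary())
```

prints

```
Queue stochasticity
===================
cows: 60   segments: 20   permutations: 1000
max H_c = log2(20) = 4.32 bits; max H_q = log2(60) = 5.91 bits
median H_c: 3.383   median variance: 0.0287
cows rejecting randomness (entropy, alpha=0.05): 52 / 60
cows rejecting randomness (variance, alpha=0.05): 60 / 60
Subperiod consistency (pen vs. pasture median entry quantile)
cows with both medians: 60
Pearson R = 0.913 (p = 3.29e-24)
Kendall tau = 0.781 (p = 1.26e-18)
```

Nearly every cow is significantly less stochastic than a random queue
(their entropy falls below all but a handful of the 1,000 within-day
permutation draws), and per-cow median positions agree strongly across
the two overnight-housing subperiods — the same qualitative picture the
method suite is designed to surface in real herds. Embeddings,
co-clustering and MCE tests follow the same pattern:

```python
emb = mo.DiffusionMap(qm).fit()        # spectral embedding + eigenvalues
grid = mo.DataMechanics(qm).fit_grid() # 10x10 co-clustering scan
print(grid.outlier_days)               # e.g. [20, 22] - the planted days
```

A `milkorder` command-line interface mirrors the pipeline
(`simulate | wrangle | stochastic | embed | comech | mce | report | all`,
each with `--config/--seed/--outdir`).

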