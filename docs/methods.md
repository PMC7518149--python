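# Methods

## The data and its model

The observational unit is one morning milking: an ordinal list of the
cows that passed through the parlor, logged by RFID. Ordinal positions
are normalised to **entry quantiles** q = position / N_d, where N_d is
the number of cows recorded that day, giving every cow-day a value in
(0, 1] with 1 = last. Normalisation removes the uncontrolled daily
variation in herd size: a cow that always enters last scores exactly 1
regardless of how many herdmates were milked.

The pipeline makes no distributional assumptions about queue
formation. Its four analysis stages ask, in order: is the queue
non-random at all (entropy/variance + permutation nulls); what is the
geometry of the inter-animal relationships (PCA, spectral embedding);
how does the structure move in time (subperiod agreement, Data
Mechanics co-clustering, outlier days); and what does queue position
associate with (MCE tests against attributes and sensor budgets).

## Synthetic herd generator

Because parlor logs from commercial herds are rarely public, the
package ships a generator whose defaults encode the study design the
methods target: **200 mixed-parity cows observed for 80 days**, the
first 26 with overnight pen housing and the remaining 54 on pasture.
Queue formation is modelled as *score-and-rank*: cow c on day d draws

    s_cd = mu_c + shift_c * 1[d >= pen_days] + Normal(0, sigma_c)

and the day's queue is the ascending sort of scores (ties broken by cow
id, as real RFID read times are unique). This is one consistent choice
for a system whose true mechanism — individual preference versus
jockeying — is unknown; everything downstream only sees the ranks.

Parameter defaults, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| `n_cows`, `n_days`, `pen_days` | 200, 80, 26 | study dimensions |
| `mu` | Uniform(0, 1) | latent preferred entry quantile |
| `sigma_min`, `sigma_max` | 0.03, 0.22 | daily positional noise SD at the queue extremes / center |
| `missing_rate` | 0.05 | per-cow-day probability of no record (illness, RFID misread) |
| `outlier_days` | 4 days mid-pasture | whole-herd disrupted days |
| `shift_fraction`, `shift_magnitude` | 0.10, 0.30 | mid-queue subgroup with a pen-to-pasture preference shift |
| `attr_rho` | 0.70 | correlation of age (days) and peak yield (kg) |
| `health_rate` | 0.36 | probability of >= 1 recorded health event |
| `sensor_effect` | 5.0 min/h | planted rear-group lounging activity offset |

Noise follows the parabola `sigma(mu) = sigma_min + (sigma_max -
sigma_min) * (1 - 4 (mu - 0.5)^2)`, so consistency is highest at the
front and rear of the queue — the U-shaped heterogeneity repeatedly
reported for real milking orders. The bounds 0.03/0.22 put extreme cows
far below, and mid-queue cows meaningfully below, the SD of a uniform
quantile (~0.29): even the least consistent cows carry some signal,
matching the observation that nearly all animals in a real herd beat
the randomness null.

On **outlier days** scores pass through a measure-preserving swap of
queue extremes and center before ranking; alternate outlier days use
`s' = 1 - 2|s - 0.5|` and its mirror `2|s - 0.5|` so that disrupted
days differ from one another (real anomalous days isolate into column
clusters of size 1–2, not one self-similar block).

**Sensor records** are hourly 60-minute budgets over five behaviours
(eating, rumination, non-activity, activity, high activity) drawn as
60 × Dirichlet(concentration × p_hour), where p_hour encodes hour-block
baselines (feeding after each of three daily milkings,
rumination-heavy nights). Budgets therefore sum to exactly 60 within
every cow-hour. The planted effect shifts the Dirichlet *mean*
(activity + effect/60, non-activity − effect/60) for cows with
mu > 0.75 during lounging hours, so the planted mean offset equals
`sensor_effect` exactly. Lounging windows default to 07–12, 13–19 and
21–04 (wrapping midnight); these are plausible inter-milking intervals,
not values from any particular farm, and are configurable. Temperature
is a sinusoidal diurnal curve plus a per-cow offset.

What the generator does **not** emulate: social cohesion (scores are
independent across cows given mu), autocorrelated day-to-day drift
within a subperiod, health-event effects on queueing (independent by
default; a coupling knob exists for power studies), and treatment
effects. Passing recovery tests therefore demonstrates that each
method detects the structure it claims to detect — not that real herds
contain that structure.

## Stochasticity quantification

Entry quantiles are discretised into K = 20 half-open segments
((j−1)/K, j/K]; quantiles are strictly positive and reach 1, so this
covers the range with no empty edge bin (boundary values such as 0.05
land in segment 1; a 1e−9 tolerance guards the float arithmetic of
i/N × K products). Both conditional entropies use log base 2 with the
0·log 0 ≡ 0 convention, so H_q is bounded by log₂(#cows in the
segment) and H_c by log₂(20) ≈ 4.32 bits.

Significance comes from permuting quantiles **within each observation
day** (preserving each day's value multiset and the missingness
pattern) and recomputing the statistic B = 5,000 times by default. Each
cow is compared to her own permutation null — attendance patterns
differ between cows, so a shared null would mis-calibrate — and the
per-segment null shares the same permutation stream. P-values use the
add-one correction p = (1 + #{null ≤ observed}) / (B + 1), one-sided
with small = less stochastic than random; ties count as ≤
(conservative).

Entropy's advantage over variance is multimodality: a cow entering
first or last on alternating days has near-maximal variance (looks
random) but only 1 bit of entropy (clearly non-random). The test suite
plants exactly this cow and checks the two tests disagree in the
documented direction.

## Embeddings

**PCA** treats days as variables and cows as observations. The day–day
correlation matrix uses all pairwise-complete cow pairs; undefined
entries (disjoint pairs) are set to 0, zero-variance days are dropped
with a warning. Scores are the per-day standardised data (missing → day
mean, i.e. 0) projected on the eigenvectors. Kaiser's rule (eigenvalue
> 1) suggests a dimensionality; the full scree is exported because the
rule is only a default.

**Spectral embedding** uses the missingness-scaled distance
d_ij = sqrt((T/|S_ij|) Σ_{t∈S_ij} (q_it − q_jt)²) — the T/|S| factor
exactly compensates masking days of a constant-difference pair — with
pairs below 10 shared days raising an explicit error. Similarities are
1/d; a zero distance between distinct cows maps to 10× the largest
finite similarity (a regularised stand-in for infinity — the factor is
a pragmatic cap, not a tuned value). The k = 10 nearest-neighbour graph
is union-symmetrised (every degree ≥ k), and the **symmetric
normalised Laplacian** L = I − D^{−1/2} W D^{−1/2} is eigendecomposed.
Unnormalised and random-walk Laplacians are available behind a switch,
and the recovery of a 1-D latent herd is tested under all three — the
geometry claim should not depend on the convention. One near-zero
eigenpair per connected component is excluded as trivial; the number of
"significant" dimensions is the position of the largest *relative*
eigengap among the leading non-trivial eigenvalues, with the full
spectrum exported for manual audit. Each retained eigenvector is
sign-oriented to correlate non-negatively with median entry quantile
(plot stability only).

Spectral embeddings of chain-like ("rope") data imprint a cosine
harmonic series on every axis. `harmonic_reference` returns the
path-graph Laplacian eigenvectors v_k(j) = cos(πk(j+½)/n) — verified
against direct eigendecomposition of the tridiagonal path Laplacian —
for overlay on embeddings sorted by their first coordinate, so the
artifact can be recognised rather than interpreted as data structure.

The permuted-data control uses the same relative-eigengap statistic:
on within-day-permuted data the maximum relative gap stays far below
the structured value (measured ≲ 0.13 versus ≳ 3 on a rope herd), and
the first coordinate carries no information about the latent order. An
absolute max-gap/median-gap criterion was evaluated and discarded: its
null distribution overlaps the structured value.

## Data Mechanics co-clustering

Rows (cows) and columns (days) are clustered alternately: scaled
Euclidean distances → Ward (D2) trees cut at (r, c) → each day
re-represented by its r-vector of within-cow-cluster means and each cow
by its c-vector of within-day-cluster means → distances recomputed in
the reduced space, iterated until both label vectors repeat (max 20).
The cross-axis update realised as distance-in-cluster-mean-space is
this module's central interpretation of "using the clustering structure
between cows to create a weighted distance matrix between days and
vice versa"; it is isolated behind `cross_update` so alternatives can
be swapped, and disabling it reduces the algorithm exactly to two
independent Ward clusterings (a regression test).

scipy's Ward linkage on raw Euclidean distances reproduces R
`hclust(…, "ward.D2")` merge heights exactly (frozen oracle test);
tie-breaking follows scipy's deterministic nearest-neighbour chain.
The **energy** of a co-clustering is the sum of within-cell population
variances, missing cells excluded (an empty cell contributes zero with
a warning). Convergence is judged on label equality, not energy; if
labels oscillate past `max_iter` the minimum-energy iterate is
returned flagged unconverged.

No automated choice of (r, c) is made — granularity is a visual
decision — but the 1–10 × 1–10 grid is summarised per cell (final
energy, smallest column-cluster size, subperiod purity) to guide the
scan. **Outlier days** are flagged when they fall in a column cluster
of size ≤ 2 in at least 80% of grid cells with c ≥ 6, across all row
granularities: genuine whole-herd disruptions stay isolated no matter
how the social axis is stratified, which separates them from ordinary
cluster-boundary churn.

## MCE association tests

Each variable is discretised by cutting a Ward tree at k clusters
(absolute difference for univariate attributes; the same
missingness-scaled distance as the embeddings for sensor matrices).
The statistic is MCE = ½(H(A|B) + H(B|A)) in bits on the contingency
table — 0 for deterministically related clusterings, rising toward the
independence value as association weakens. Significance permutes one
labelling across cows (B = 2,000 default), p = (1 + #{MCE_perm ≤
MCE_obs})/(B + 1), ties ≤.

Because tree depth is a metaparameter, the test runs on a (k_a, k_b)
grid (2–10 by default) and the reported cell minimises the average of
its p-value's rank within its grid row and column (ties → smallest
k_a + k_b, then k_a); ranking on the raw MCE instead is available
behind a flag. Results are quoted p₍ka,kb₎. No multiple-testing
adjustment is applied across channels/subsets — the reports are
exploratory — but a Benjamini–Hochberg helper is provided. MCE cannot
adjust for confounders; that is a known limitation of the approach,
not of the implementation.

## Study sizes used by the validation suite

The tests and `scripts/acceptance.py` run the full pipeline at sizes
chosen to exercise every property at comfortable statistical margins:
permutation calibration on 500 exchangeable cows × 80 days at
B = 1,000; U-shape recovery on the full default herd (200 × 80,
B = 1,000); latent-order recovery on an 80-cow rope herd; co-clustering
recovery on 120 × 60 herds (outlier-day study: 50 replicates in the
test suite, 20 in the script); MCE null calibration on 500 replicates
(300 in the script) of 50-cow herds at B = 199; sensor studies on
60-cow, 6-day herds. Larger sizes change none of the conclusions; these
were chosen so the whole suite runs in minutes on one CPU.

## Known limitations

* The score-and-rank generator cannot express social cohesion, so the
  embeddings' "no clustering" property is only validated against
  cohesion-free data.
* The Data Mechanics cross-axis update is one concrete realisation of
  the cluster-information-sharing idea; other weightings may converge
  differently on real data.
* Grid-selected MCE p-values are reported unadjusted for the selection
  itself; the type-I error control is verified at fixed (k_a, k_b).
* The coverage filter's denominator is the enrolled-herd count the
  generator supplies; real logs need a roster file (supported via
  `MilkLog.enrolled`), and whether hospital-pen cows should count is a
  farm-specific decision left configurable.
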