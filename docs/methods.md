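# Methods

## Model

Each gene in each study is modelled as an equal-weight mixture over the K
shared classes, `X ~ (1/K) sum_k N(mu_Xk, sigma2_Xk)`, with classes
independent between studies given the pattern. Per-class moments are
estimated by maximum likelihood (variance divisor `n_k`, no Bessel
correction), so a single-sample class has variance exactly 0. Equal class
weights are the default even when observed class sizes differ — concordance
should reflect the class-mean *pattern*, not the sampling design; an
`observed` option uses pooled per-pair class proportions instead (a common
weight vector per pair is what keeps the Cauchy–Schwarz bound |MCC| ≤ 1).

The pairwise multi-class correlation (MCC) is the covariance of class-mean
patterns over the product of mixture standard deviations; within-class
variance only inflates the denominator, so |MCC| ≤ 1 always holds for the
plug-in estimates. The multi-study statistics are computed in correlation
form: because the covariance `Sigma` carries `sigma_s^2` on its diagonal,

    gMI  = -1/2 (log|Sigma|  - sum_s log sigma_s^2) = -1/2 log|R|
    gMI+ = -1/2 (log|Sigma+| - sum_s log sigma_s^2) = -1/2 log|R+|

where `R` is the MCC matrix and `R+` zeroes its negative off-diagonal
entries. The identity is exact and makes the statistics manifestly
invariant under per-study rescaling.

## Inference

Stage 1 tests, per gene, H0 `all rho_ij <= 0` against HA `some rho_ij > 0`
using gMI+. Class labels are permuted within each study; since labels are
shared by all genes of a study, one shuffle re-labels every gene at once and
gene–gene dependence is preserved. P-values use the pooled-null formula
`p = (1 + #{theta_gb >= theta}) / (1 + G·B)` with inclusive ties, giving
resolution `1/(1+G·B)`; a per-gene option (`pooled=False`) ranks each gene
only against its own B permutations, for inputs whose genes are not on a
comparable scale. Benjamini–Hochberg q-values are computed by the step-up
rule `q_i = min{min_{j>=i} G p_(j)/j, 1}`.

Stage 2 tests every study pair with MI+ on **fresh** permutations (a second
child stream of the master seed; a `reuse_permutations` flag shares stage
1's stream instead — the two-stage structure does not require independence,
but fresh draws avoid reusing the same Monte-Carlo error in both decisions).
The pooled denominator of stage 2 counts the genes actually entering that
stage (the stage-1 rejections by default; `posthoc_scope="all"` tests every
gene). Concordant modules are the maximal cliques of the graph with an edge
`i–j` when `p_ij < alpha_posthoc` (default 0.05; the single-cell screening
application motivates the stricter 0.001, exposed as a flag). All maximal
cliques of size ≥ 2 are reported, ordered by size then lexicographically;
the canonical module label uses the first, so multi-clique genes keep both
views. No multiplicity correction is applied across the S(S−1)/2 pairs: the
pairwise thresholds are screening rules, not confirmatory tests, and are
applied raw.

The `discordant_filter` screen keeps genes whose pairwise p-values within a
designated study set (e.g. immune cell types) are all below `p_lo` while
every p-value between the set and a target study (e.g. tumor) exceeds
`p_hi` (defaults 0.001 / 0.5). Note that `p > 0.5` effectively demands a
non-positive observed correlation with the target — a truly independent
target yields roughly uniform p and passes only about half the time, while
an opposite trend gives MI+ = 0 and p ≈ 1 deterministically.

## Synthetic data

The generator draws, per gene and concordance block, a latent pattern
`z_block ~ N(0, I_K)` and sets study s's class means to
`tau * (sqrt(rho_mean) z_block + sqrt(1 - rho_mean) z_s)`, which gives any
two studies of a block class-mean correlation exactly `rho_mean` and
marginal spread `tau`. Observations add iid `N(0, noise_sd^2)` noise with
`n_per_class` replicates per class. Archetypes: type I — one block covering
all S studies; type II — a block of the first S−1 studies, the last study
with its own independent pattern; type III — disjoint consecutive pairs of
studies (defined for S ≥ 4; an odd leftover study is independent); type IV —
all class means equal (pure noise). Defaults are S = 4, K = 3,
n_per_class = 10, tau = 1, noise_sd = 1, rho_mean = 1, 500 replicate runs
and B = 500 permutations, with 500 genes per type in genome-wide datasets.
tau = noise_sd = 1 puts the expected between-class variance
(`tau^2 (K-1)/K = 2/3`) on the order of the within-class variance — a
moderate, realistic signal; because the class means are redrawn per gene,
per-gene signal strength is chi-square-dispersed, so power is strictly
below 1 even at rho_mean = 1.

What the generator does *not* emulate: heavy-tailed or count-distributed
expression, gene–gene correlation (genes are independent draws; the
permutation scheme would preserve such correlation, but the calibration
tests here do not probe it), per-study scale differences, batch effects, or
unbalanced class sizes. Passing tests therefore certify the statistics,
their calibration under exchangeability, and subset recovery — not
robustness to those real-data features, whose handling (normalization,
batch correction) is assumed upstream.

## Evaluation

The power study stacks the R single-gene replicates of one archetype as R
independent "genes" sharing a single permutation stream: each replicate's
statistic depends only on its own data and the current shuffle, so
replicates remain mutually independent and each per-replicate p-value
(per-gene null, the pooled formula at G = 1) is valid. Detection uses
`p <= alpha`: permutation p-values live on the grid `k/(1+B)`, so this
coincides with `p < alpha` at conventional thresholds (0.05 with B = 500)
while keeping `alpha = 1` exhaustive. Genome-wide metrics rank genes by
p-value for the ROC/AUC (types I–III positive, type IV negative) and apply
the q < 0.05 cutoff for sensitivity, specificity, F1 and the type-I error
(the fraction of type-IV genes called).

Problem sizes in the shipped evaluation (`scripts/acceptance.py`): 500
replicate runs with B = 500 for calibration and power; ten 2000-gene
datasets with B = 200 for the genome-wide metrics — B = 200 leaves the
pooled-null resolution at `1/400001`, far below the q < 0.05 operating
point, so the metrics are insensitive to the reduction.

## Numerical choices

- Correlations outside `[-1-1e-8, 1+1e-8]` raise; inside, they are clipped
  to [−1, 1].
- `MI+` clamps `(rho+)^2` at `1 - 1e-12`, so boundary correlations give a
  large (≈13.8 nats) finite statistic that still outranks interior values.
- Zeroing negative entries can cost `R+` positive definiteness: eigenvalues
  below `1e-8 ×` the largest are floored there before the log-determinant
  (the smallest intervention that keeps the statistic defined and
  order-preserving); repairs are counted and logged. A duplicated study
  makes `R+` singular and the statistic correspondingly huge — still
  monotone, which is the behaviour the ranking needs.
- A study with zero mixture variance has undefined MCC; its pairwise values
  are set to 0 with a warning, which makes it drop out of `R+` exactly as
  an independent study would. Two-sided `gMI` refuses such inputs instead,
  since its determinant identity needs `sigma_s > 0`.
- Reproducibility: one master seed spawns numpy `SeedSequence` children
  (stage 1, stage 2), so full pipelines are bit-identical across runs and
  machines and do not depend on any parallelism setting.

## Known limitations

- Negative concordance is deliberately not detected (one-sided statistics);
  a gene anti-regulated between studies scores 0.
- Permutation p-values are bounded below by `1/(1+G·B)`; with small G·B,
  BH at stringent thresholds is quantization-limited.
- The pooled null assumes genes share a null scale; MCC's scale-freeness
  makes this mild, but heterogeneous designs can use the per-gene option at
  the cost of resolution.
- Power/operating-characteristic figures reported by the evaluation are
  conditional on the generator's effect sizes above; real-data performance
  depends on the actual signal-to-noise of the studies integrated.
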