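# Methods

## Two-stage design engine

**Conventions.** A design is stored as `(r1, n1, r, n)`: stop for futility
when stage-1 responses `X1 ≤ r1`; declare positive when total responses reach
`r + 1`. A protocol phrased as "≥ 4 responses to continue among 17" therefore
maps to `r1 = 3, n1 = 17`. All probabilities are exact binomial sums and
convolutions; nothing in the design engine is simulated.

**Search.** `simon_search` enumerates every `(r1, n1, r, n)` with `n ≤ n_max`
(default 100). For fixed `(n1, n2, r1)` the distribution of the total response
count over continuing paths is one convolution, and because the rejection
probability is decreasing in `r` at any `p`, only the smallest `r` meeting the
type-I constraint can also meet the power constraint — so one candidate per
`(n1, n2, r1)` suffices. Branches with `Pr[X1 ≤ r1; n1, p1] > β` are pruned
since power cannot exceed the continuation probability under the alternative.
The optimal design minimizes `EN(p0)`; the minimax design minimizes `n` then
`EN(p0)`; remaining ties break by smaller `n` then smaller `n1` so output is
deterministic.

**Conditional-error recalibration.** After observing `s1 > r1` stage-1
responses, the type-I error still spendable is `A(s1) = Pr[X2 ≥ r+1−s1;
n−n1, p0]` (0 below the futility bound, 1 once the original boundary is
already crossed). For an attained second-stage size `n2*` the recalibrated
boundary is the smallest total `m` with `Pr[X2* ≥ m−s1; n2*, p0] ≤ A(s1)`.
Because each stage-1 outcome's conditional error never increases, the
unconditional type-I error of the recalibrated rule is bounded by the original
design's exact α; the test suite checks this over a design × `s1` × `n2*`
grid to 1e-12. When no attainable total can satisfy the bound (e.g. `n2* = 0`
with `A(s1) < 1`) a `CannotRejectError` is raised rather than a value
returned.

**Design-consistent inference.** The one-sided p-value under the stagewise
ordering is `Σ_{m1=r1+1}^{n1} b(m1; n1, p) · Pr[X2* ≥ s_total−m1; n2*, p]`,
with the tail set to 1 when the stage-1 count alone reaches `s_total`; the
stage-1 law is never modified, only the second-stage tail is evaluated at the
attained size. Confidence limits invert this p-value in `p` by Brent root
finding (tolerance 1e-8 on `p`): the lower limit solves `p-value = (1−level)/2`
and the upper limit solves `p-value = 1−(1−level)/2`, both at the observed
`s_total`. This symmetric convention is the one that reproduces the
established two-stage inference implementations; the p-value is strictly
increasing in `p`, so each root is unique and no grid is needed. Point
estimate is the attained-sample proportion. Stage-1 enrollment deviations are
rejected with an explicit error: the machinery assumes the stage-1 size was
met.

Clinical-benefit rates, which are plain binomial proportions, get exact
Clopper–Pearson intervals from beta quantiles. Tumor mutational burden is the
filtered non-synonymous mutation count divided by the effective capture size
in megabases (the upstream variant calling itself is out of scope).

## Gene ranking

Ranking between benefit groups uses a moderated two-sample t on logCPM
(`log2((count + prior) / (libsize + 2·prior) · 1e6)`, prior 1). Gene-wise
residual variances `s_g²` (pooled within groups, `d_g = n − 2` df) are shrunk
toward a prior `s0²` with `d0` prior df estimated by moments from
`log s_g²`: the excess of its variance over `trigamma(d_g/2)` identifies
`trigamma(d0/2)`, inverted by Newton; non-positive excess gives `d0 = ∞`
(all genes share `s0²`). The statistic is `t = Δmean / (s̃_g √(1/n_a + 1/n_b))`
with `s̃_g² = (d0 s0² + d_g s_g²)/(d0 + d_g)` and two-sided p on `d0 + d_g`
df; BH adjustment across genes. A `prior_df` override exists: 0 disables
shrinkage (ordinary pooled t, used by the oracle test), `∞` forces complete
shrinkage. **Divergence from the platform pipeline this emulates:** the
voom-style mean–variance precision weights are not applied, so genes at the
extremes of the expression range are weighted slightly differently than a
limma-voom analysis would weight them; with ~30-sample arms the ranking is
close but not identical. Ties in the ranking break lexicographically by gene
identifier for determinism.

## Preranked enrichment

The running sum adds `|t|^w / Σ_hits |t|^w` at member genes and subtracts
`1/(N − n_hits)` elsewhere; the enrichment score is the extremum by absolute
value (positive preferred on exact ties). `w = 1` by default; `w = 0` is the
classic unweighted KS statistic. If all member statistics are exactly zero
the hit increments fall back to equal steps. Significance uses gene-label
permutations (default 1000, seed required): NES divides the observed score by
the mean magnitude of same-sign permutation scores; the p-value is
`(1 + #{|perm| ≥ |obs|, same sign}) / (1 + #same-sign)`. Sets with no
same-sign permutation score get NES and p reported as missing and are
excluded from the BH adjustment. Sets intersecting the ranking in fewer than
`min_size` (5) or more than `max_size` (2000) genes are skipped with a
warning, not an error. The leading edge is the member prefix at or before the
running-sum peak (suffix at or after the trough for negative scores). The
cross-arm signature is the union of the named pathways' leading edges within
each arm, intersected across arms, sorted.

Permutation mode is gene-label permutation: it is the only scheme consistent
with enrichment over a single preranked list, and it is what the seed
controls; two runs with the same inputs and seed are byte-identical.

## Single-sample scoring and association

The rank score ranks all `N` measured genes within a sample (ascending,
average ties), takes the mean rank of the `n_up` signature genes over `N`,
rescales by the theoretical bounds `(n_up+1)/(2N)` and `(2N−n_up+1)/(2N)`,
and subtracts 0.5; scores live in `[−0.5, 0.5]`, hit the bounds exactly when
the signature occupies the extreme ranks, and are invariant to monotone
transforms of a sample's values. The z-mean score (for variance-stabilized
external data) z-scores each signature gene across samples with the sample
(n−1) standard deviation and averages; zero-variance genes are excluded with
a warning.

AUC uses the Mann–Whitney identity with midrank ties; the optional flip
(`1 − AUC`) is for resistance-oriented signatures evaluated as predictors of
non-benefit, applied only on request. Wilcoxon tests use the exact null
distribution for tie-free samples up to n = 25 per group, otherwise the
tie-corrected normal approximation; all-zero paired differences return p = 1
with a warning. Spearman correlation against PFS uses observed times as-is,
censoring ignored — mirroring the analysis style it reproduces; a
censoring-aware association is deliberately out of scope. Survival
comparison: Kaplan–Meier curves per group, log-rank p, and a hazard ratio
from a single-covariate Cox fit with Efron tie handling (lifelines, Newton
precision 1e-9; an independent Efron partial-likelihood maximizer in the test
suite agrees to 1e-6). Score dichotomization defaults to a median split
(strictly-above → "high"), configurable; the HR is reported for high vs low.

Benefit labels: CB is a confirmed or unconfirmed response (CR/PR) or stable
disease lasting ≥ 4 months (boundary inclusive); NCB is progressive disease
or shorter stable disease; response dominates PFS. Exceptional responders
have PFS ≥ 12 months. Both thresholds are configurable.

## Synthetic cohorts

The expression generator emulates a small two-arm biopsy cohort: 15 + 15
samples per arm by default (matching the scale of benefit/non-benefit groups
in a single-center phase-II arm), 1000 genes for enrichment-scale tests,
baseline log2 mean counts uniform on (3, 9), per-gene NB dispersions uniform
on (0.05, 0.4) (variance `μ + αμ²`, the bulk RNA-seq convention), lognormal
size factors (σ = 0.15). Planted programs add a log2 fold-change (default
checks use 1.0 on a 20-gene set) in one group. Survival: each sample's true
score is its planted shift, standardized; PFS is exponential with rate
`λ0 · exp(θ·z)` (defaults λ0 = 0.2/month, θ = 0.8 — a ~5-fold hazard spread
between groups, in the range a strong resistance signature shows), censored
at 24 months. Response categories follow a documented arbitrary rule
(responders = low-risk quartile with PFS ≥ 2; PD below 2 months; SD
otherwise) sufficient to exercise benefit labelling; derived labels therefore
agree with, but do not equal, the planted grouping. Recovery tests rank
against the planted grouping — the generator's ground truth — while the
label-derivation rule is tested separately.

What the generator does **not** emulate: batch effects, tumor purity,
library-preparation artifacts, correlated gene modules beyond the planted
sets, non-proportional hazards, and informative censoring. Passing recovery
tests therefore demonstrate the machinery's correctness and power under
clean NB signal, not performance on real biopsies.

All generators are pure functions of (config, seed); the single seed spawns
per-component substreams so expression, survival and nuisance draws can be
varied independently.

## Problem sizes in tests

The brute-force design-search oracle runs at `n_max = 25` over a three-point
hypothesis grid (feasible designs exist well inside that bound for all grid
points); Monte-Carlo trial calibration uses 100,000 replicates; planted-signal
recovery uses 20 two-arm replicates at 1000 genes; null-uniformity checks use
2000 replicates. These sizes are the package's own verification scale —
larger runs reproduce the same conclusions.

## Known limitations

- Stage-1 under-enrollment is not supported (explicit error); only the
  second stage may deviate from plan.
- The moderated-t ranking omits voom precision weights (see above).
- NES normalization by same-sign permutation mean follows the original GSEA
  convention; with few permutations NES is noisy even when ES is exact.
- The multivariate logistic adjustment for platinum status is not part of the
  association surface; platinum stratification is a row filter followed by
  the same operations.
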