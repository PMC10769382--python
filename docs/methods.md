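# Methods

## Model and estimation

Each trait is modeled as `y = X0 b0 + g bj + e` with
`e ~ N(0, sg2 K + se2 I)`: a fixed covariate part (intercept by default),
one tested marker, a polygenic random effect whose covariance is
proportional to the kinship matrix `K`, and i.i.d. noise.  The variance
components are re-parameterized as the heritability
`h2 = sg2/(sg2 + se2) ∈ [0, 1)` and `se2`, with the variance ratio
`d = h2/(1 − h2)`.

With the spectral decomposition `K = U D Uᵀ`, rotation by `Uᵀ` makes the
observations independent with marginal variances `se2 (d·li + 1)`.  Given
h2, the weighted-least-squares estimates are closed-form,

```
b-hat  = (XᵀW⁻¹X)⁻¹ XᵀW⁻¹y,      W = diag(d·li + 1)
se2-ml = WRSS / n,               WRSS = (y − Xb)ᵀW⁻¹(y − Xb)
```

and the profiled log-likelihood is a function of h2 alone.  Weighted fits
are computed by scaling rows by `1/sqrt(wi)` and solving with a
rank-revealing least-squares factorization; no matrix is explicitly
inverted.  The log-likelihood retains its `−(n/2)·log(2π)` constant so
that the rotated-basis value equals the multivariate-normal log-density
of the unrotated data (a test asserts this against brute-force covariance
inversion).

Three objective kinds:

* **ML** — the profiled likelihood above.
* **REML** (scan default) — the standard restricted likelihood:
  `−½{(n−q)·log(2π·se2) + Σ log wi + log|XᵀW⁻¹X| + WRSS/se2}` with
  `se2 = WRSS/(n−q)`.  REML is the usual choice for variance components
  because it accounts for the fixed-effect degrees of freedom.
* **MAP** — ML with a Scaled-Inverse-χ²(ν0, τ0²) prior on se2.  By
  Inverse-χ²–Normal conjugacy the posterior is
  Scaled-Inv-χ²(ν0 + n, (ν0τ0² + WRSS)/(ν0 + n)), with mode
  `(ν0τ0² + WRSS)/(ν0 + n + 2)`; the objective is the log-posterior at
  that mode, with all normalization constants kept so the argmax is
  well-defined.  ν0 = 0 switches the prior off and recovers ML exactly.
  The conjugate mode is cross-checked in tests against direct numerical
  maximization of prior × likelihood.

### Heritability optimization

`optimize_h2_brent` maximizes the profiled objective with bounded Brent
iterations on `[0, 1 − 1e−6]` (h2 = 1 is excluded; the unprioritized
objective can diverge there), convergence tolerance 1e−6 on h2.  Because
Brent's method can be trapped by multimodal objectives, the interval may
be split into `s` equal sub-intervals with one Brent run each; the best
sub-interval optimum (also comparing the boundary points) wins.  Default
`s = 1`.

`grid_loglik` evaluates the objective for every trait at every grid value
with one batched weighted regression per value (a single QR of the
weighted design projected against all trait columns).  Grid ties break
toward the smaller h2 — the more conservative variance model — making the
argmax deterministic.  The default grid is 0.0 to 0.9 in steps of 0.1.

### LOD scores

For a 1-df test, `LOD = (n/2)·log10(RSS0/RSS1) = −(n/2)·log10(1 − r²)`
where `r` is the correlation between the residualized trait and marker.
After reweighting by `W^{−1/2}`, both traits and markers are residualized
against the reweighted covariates (with q > 1 covariates plain centering
would not reproduce the RSS identity) and scaled to unit norm **without
re-centering**; the full m×p correlation panel is then one matrix
product, `r = Ysᵀ Gs` with no `1/n` factor — the only convention under
which |r| ≤ 1 and the per-pair regression identity holds exactly (a test
verifies it fit-by-fit).  `|r|` is clipped at `1 − 1e−12` so collinear
pairs give a large finite LOD instead of infinity.  The `n` in the
exponent is the number of individuals, not `n − q`.

### Scan algorithms

* **null-exact** — per trait: Brent-optimize the null-model h2, reweight,
  one matrix product against all markers.  The null h2 is reused at every
  marker, so the matrix-product LOD equals the explicit likelihood-ratio
  LOD exactly (machine precision in tests).
* **null-grid** — grid-search the null h2 for all traits at once, batch
  traits sharing a winning grid value, one matrix product per batch.
* **alt-grid** — for each grid value compute the pseudo-LOD panel and the
  (marker-independent) null log-likelihoods, recover
  `l1 = l0 + log(10)·LOD`, then maximize `l0` per trait and `l1` per
  (trait, marker) over the grid.  The recovery identity holds exactly
  only for the ML likelihood (REML's design-determinant term depends on
  the tested marker), so this scan always uses ML panels internally.
  By construction its LOD dominates the null-grid LOD on the same grid.
* **lm** — unit weights, no kinship: the baseline showing what
  relatedness adjustment changes.  With `K = I` every LMM scan reduces to
  it exactly.

Zero-variance (monomorphic) markers are excluded from kinship estimation
and receive LOD = 0 in scans (their correlation with any trait is
undefined); their IDs are recorded.  Markers may be processed in column
blocks to bound memory; traits or batches may be processed by worker
threads — assembly order is fixed, so results are bit-identical for any
worker count or block size (tested).

### Permutation thresholds

For one trait: estimate the null h2 once, form
`y† = W^{−1/2}Uᵀy`, regress out the reweighted covariates to get
residuals `r0` that are i.i.d. `N(0, se2 I)` under the null, permute
`r0` `n_perm` times, and compute every permuted LOD curve in one matrix
product (each permuted column is re-residualized, since permutation
breaks orthogonality to the covariates).  The threshold at level α is
the empirical (1 − α) quantile (linear interpolation, the common
genome-scan convention) of the per-permutation **genome-wide maximum**
LOD — the standard family-wise control for a single trait; the choice of
statistic is recorded in the output metadata.  h2 is not re-estimated per
permutation.  Measured on 1000 simulated null traits (n = 100, p = 200,
h2 = 0.5, a fresh population per trait) the 95% threshold rejected 4.4%
of the time — the scheme is slightly conservative because the estimated
null h2 absorbs some marker-correlated polygenic structure.

### Boundary avoidance

If a kinship zero-eigendirection carries no trait residual — as when an
individual's genotype row and trait value are both duplicated, e.g.
strain means with replicated genotypes — the ML residual-variance
estimate collapses to zero as h2 → 1 and the profiled objective diverges
at the boundary, stranding the h2 estimate at 1.  (A zero eigenvalue
alone is not sufficient: with i.i.d. individual noise the null-space
residual stays positive and the objective is bounded.)  The weak default
prior (ν0 = 0.1, τ0² = var(y)) bounds `se2` away from zero and restores
an interior maximum; on the package's duplicated-individual fixture the
MAP estimate lands near 0.98 while ML diverges.

## Synthetic data

The generator emulates a replicated inbred panel: strain haplotypes in
{0, 1} follow a Markov chain along markers (flip probability 0.1 by
default, giving block-like linkage disequilibrium; 0.5 gives independent
markers), replicated across individuals within strain.  Kinship is the
centered-and-scaled cross-product `ZZᵀ/p` over polymorphic markers
(population-variance standardization so the diagonal averages 1); any
user-supplied kinship bypasses this estimator, and heritability values
are only comparable across kinship scalings qualitatively.  Traits are
polygenic + noise with the background variance split at the configured
h2, plus optional fixed QTL effects expressed in background-SD units and
added **on top** of the background (so h2 refers to the QTL-free
decomposition and recovery tests are well-posed).  All draws descend
deterministically from one seed.

What the generator does *not* emulate: coalescent LD patterns, allele
frequency spectra, dominance, missing data, mean–variance coupling
(count or binary traits).  Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated model,
not robustness to those real-data features.

## Problem sizes and numerical tolerances

The test and acceptance workloads use: oracle comparisons at n = 60,
m = 5, p = 40; grid-convergence at n = 60, m = 30, p = 80 over grid
steps {0.2, 0.1, 0.05, 0.01}; heritability recovery over 200 traits at
n = 500; permutation calibration over 500 null traits at n = 100,
p = 200 with 1000 permutations each.  These sizes give sub-minute runs
while leaving Monte-Carlo error well inside the asserted bands.

Key tolerances: kinship symmetry 1e−10; eigenvalues within
−1e−8·λmax clamped to zero, below −1e−6·λmax an error; Brent tolerance
1e−6 on h2; correlation clip 1e−12; a weighted fit whose WRSS falls
below 1e−12 of the weighted trait sum of squares is treated as degenerate
(no information about se2) unless a prior is active.

## Additional features and limitations

Per-observation user weights (unequal residual variances, e.g. strain
means over unequal replicate counts) are supported by pre-scaling y, X
and K by the square roots of the weights before eigendecomposition,
which reduces the weighted LMM to the standard one; off by default.

Out of scope: multivariate LMMs, multiple kinship matrices, tests with
more than 1 df, missing-data imputation, VCF/PLINK parsing, and
low-rank kinship shortcuts.  Inputs must be complete; phenotype,
genotype and kinship files must share identical individual IDs (rows are
reordered by ID match and mismatches are errors, since silent
misalignment is the classic mixed-model bug).
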