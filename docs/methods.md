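# Methods

## Model

For each cis gene–SNP pair λ and tissue k, let r_λ(k) be the
(covariate-corrected) Pearson correlation between the gene's expression
and the SNP's minor-allele dosage in the n_k subjects of tissue k. The
variance-stabilized statistic is

    Z_λ(k) = atanh(r_λ(k)) · sqrt(d_k),   d_k = n_k − n_cov_k − 3,

so a null pair has Z_λ(k) ≈ N(0, 1). Across K tissues the vector Z_λ is
modeled as a Gaussian mixture over latent eQTL configurations
γ ∈ {0,1}^K:

    Z_λ ~ Σ_γ p(γ) · N_K(0, Δ + Σ ∘ γγ′),

where ∘ is the elementwise product, Δ is a correlation matrix describing
the null dependence between tissues (driven by subject overlap), Σ is
the covariance of true effect sizes on the z scale, and p(·) is the
prior over configurations. The mean is fixed at zero: minor alleles are
a priori equally likely to raise or lower expression. The likelihood
over pairs is a pseudo-likelihood — rows are treated as independent,
ignoring linkage disequilibrium, which affects efficiency but not the
marginal model being estimated.

The model is *marginally compatible*: restricting to a tissue subset
gives a model of the same form whose parameters are the restrictions of
(p, Δ, Σ), with the prior summed over removed coordinates
(`marginalize_model`). This is what makes the estimation strategy below
coherent.

## Estimation: pairwise fits, then assembly

Fitting the K-tissue mixture directly costs time exponential in K. This
package only ever fits the K(K−1)/2 two-tissue sub-models (4-component
bivariate mixtures) and the K one-tissue sub-models (2-component scalar
mixtures), then assembles them.

### Two-tissue EM

E-step: responsibilities w_λγ ∝ p(γ)·φ₂(z_λ; 0, Δ+Σ∘γγ′). M-step:

* p(γ) = mean_λ w_λγ, floored at 1e-12 and renormalized;
* δ (the null correlation) = off-diagonal of the w₀₀-weighted second
  moment of z, rescaled to unit diagonal;
* σ_kk = weighted second moment of z_k over the components where tissue
  k is active, minus the unit null variance;
* σ₁₂ = w₁₁-weighted cross moment minus δ, clipped so Σ stays positive
  semi-definite.

Each weighted moment estimates the corresponding conditional moment
(tower property), so the generating parameters are a fixed point of the
updates; recovery is verified by simulation in the test suite.

Two design choices deserve comment, both responses to a classic
degeneracy of this mixture. If an effect variance σ_kk tends to zero,
the "eQTL in tissue k" components become exact clones of the null
component, the likelihood becomes flat in the corresponding weights, and
EM stalls wherever the weights started. We therefore (a) floor the
effect variances at `min_sigma = 0.5` — an eQTL whose squared effect on
the z scale is below 0.5 is not meaningfully distinguishable from noise
at these sample sizes, and real-data fits put σ_kk well above this — and
(b) run weight-only EM refinement passes (up to `n_inner = 50`) after
each covariance update. The inner passes reuse the already-computed
component densities, are exact ascent steps for fixed components, and
let the weights drain off clone-like components at negligible cost; with
them, a fit on pure-null data correctly reports p₀₀ ≈ 1 instead of its
initialization value.

Because the covariance updates are moment matching rather than exact
maximizers of the EM surrogate, they are not a provable ascent step; at
small sample sizes they can occasionally overshoot. Each covariance
proposal is therefore accepted only if it does not lower the
pseudo-likelihood (a generalized-EM safeguard; the weight updates are
exact ascent steps and need no guard), which makes the trace
non-decreasing by construction. A sentinel still raises if the trace
ever drops beyond 1e-6·|loglik|, converting any numerical defect into a
loud failure.

Initialization: p = (0.90, 0.02, 0.02, 0.06); δ = sample correlation of
rows with both |z| < 2; Σ diagonal = max(var(z) − 1, 0.5) with effect
correlation 0.7. Convergence: relative pseudo-log-likelihood change
< 1e-6 (max 500 iterations). The EM is deterministic given data;
parallel execution over pairs cannot change results.

### Assembly

* **Δ**: off-diagonal (i,j) ← δ̂^ij; ones on the diagonal. If the result
  is indefinite, eigenvalues are clipped at zero and the matrix rescaled
  to unit diagonal (`nearest_correlation`).
* **Σ**: each σ_kk is the *minimum* of its K−1 pairwise estimates —
  heavy-tailed z columns inflate pairwise variance estimates, and the
  minimum counteracts that inflation. The correlation part is assembled
  from σ̂₁₂/√(σ̂₁₁σ̂₂₂) like Δ, then rescaled by the diagonal.
* **p(·)**: each pairwise table p^ij is matched exactly by a bivariate
  Probit: τ₁ = Φ⁻¹(p₀₀+p₀₁), τ₂ = Φ⁻¹(p₀₀+p₁₀), and ω solved by Brent's
  method so the upper orthant equals p₁₁ (residual < 1e-8; the orthant
  is evaluated by a deterministic 1-d quadrature accurate to ~1e-12).
  ω = 0 is admitted to represent exact independence; if p₁₁ lies outside
  the feasible range for ω ∈ [0, 1), it is clamped to the nearest
  endpoint with a warning. Per tissue, the aggregate threshold τ_j is
  the minimum over its pairwise thresholds (pairwise fits occasionally
  overestimate the null mass; the minimum is the conservative
  aggregation), with a diagnostic warning when thresholds for one tissue
  disagree by more than 0.5. The ω matrix is projected to a correlation
  matrix Ω, and the K-tissue prior is the orthant mass

      p(γ) = P( X_k > τ_k iff γ_k = 1 ),  X ~ N_K(0, Ω).

* **Truncation**: configurations with p(γ) < 1e-5 (configurable) are
  dropped and the survivors renormalized; this keeps the support at a
  manageable size for inference.

### Orthant computation

For K ≤ 15 ("exact" method) the 2^K marginal-subset CDFs
F(T) = P(X_k ≤ τ_k, k ∈ T) are evaluated once each (scipy's Genz
quadrature with a fixed internal rng, so results are reproducible), and
all configuration masses are obtained by a signed difference transform
along each coordinate. Because every mass is a signed combination of the
*same* shared CDF values, the 2^K masses telescope to exactly 1 — the
partition of unity holds by construction, to floating-point rounding,
independent of the quadrature error in any individual CDF. Individual
masses inherit the CDF accuracy (~1e-8 per term, amplified by
cancellation for configurations with many active tissues; tiny negative
values can occur far below the truncation level and are removed by it).

For larger K, one quasi-Monte-Carlo sweep (scrambled Sobol, default 1e7
draws, mandatory seed) tallies all configuration masses simultaneously;
1e7 draws resolve masses at the 1e-5 truncation level with relative
error of a few percent.

## Inference

For a configuration set S (any / common / tissue-specific / in-tissue-k
/ explicit), the local false discovery rate of a pair is

    η_S(z) = Σ_{γ ∈ S^c} p(γ) f_γ(z) / Σ_γ p(γ) f_γ(z),

with sums over the truncated support (zero-prior configurations
contribute nothing to either sum) and f_γ the mixture component density.
One Cholesky factor per supported configuration is computed and reused
across all rows; evaluation is in log space and stable to |z| ≈ 40.

The adaptive procedure sorts the η values ascending and rejects the
largest prefix whose running mean is strictly below the nominal level α
(ties at the boundary resolved by stable sort order, i.e. by pair
index). When the model is correctly specified this controls the FDR at
α; the test suite verifies the realized false discovery proportion on
simulated data.

Model summaries: Hamming-class masses (total prior mass on
configurations with m active tissues) and single-linkage tissue
clustering using d(i,j) = 1 − σ_ij/√(σ_ii σ_jj). The correlation induced
by Σ is a similarity, so its complement is used as the dissimilarity;
merge heights are reported on that scale and trees can be exported as
Newick.

## Synthetic data generator

`synthetic_model(K=9)` is the package's reference study condition: prior
mass 0.80 on the null configuration, 0.10 on the all-tissues
configuration, 0.05 spread uniformly over single-tissue configurations
and 0.05 over all-but-one configurations; Δ equicorrelated at 0.2; Σ
with diagonal 6 and effect correlation 0.8. These values reproduce the
qualitative structure reported for real multi-tissue eQTL data — most
pairs are an eQTL nowhere or everywhere, a parabolic Hamming-mass
profile on the log scale, moderate null correlation from subject
overlap, and strongly correlated effect sizes — without requiring any
external download. `simulate_dataset` draws γ_λ i.i.d. from the prior
and z_λ | γ_λ ~ N(0, Δ+Σ∘γγ′), bitwise reproducible given a seed.

What the generator does *not* emulate: linkage disequilibrium between
nearby SNPs (rows are exchangeable), heavy tails or residual
non-normality of real z-statistics, missing tissues per donor, and
effect-size heterogeneity beyond a single Gaussian per configuration.
Passing tests therefore demonstrate correctness of the algorithms under
the model's own assumptions, not robustness to their violation on real
data.

## Numerical choices and problem sizes

* Pairwise EM: tol 1e-6 (relative), max 500 iterations, probability
  floor 1e-12, effect-variance floor 0.5.
* Probit inversion: Brent on [0, 1−1e-6], orthant residual < 1e-8.
* Exact orthants: per-CDF tolerance 1e-9 with 2e5 quadrature points and
  a fixed rng; correlations |r| ≥ 1−1e-12 clamped before atanh with a
  warning (duplicated columns yield extreme but finite evidence).
* Simulation studies in the tests use 1e5 pairs (2e5 for the two-tissue
  recovery study), 9 tissues, and 5 replicates for FDR control —
  problem sizes at which Monte-Carlo error is small relative to the
  tolerances being asserted while the whole suite stays fast.
* Incomplete z rows are dropped by default for full-panel inference;
  alternatively a row observed on a tissue subset can be scored under
  the marginalized model for that subset.

## Known limitations

* The pairwise M-step is moment matching, not a provable ascent; the
  monotonicity sentinel guards it empirically.
* The Σ diagonal's minimum-aggregation is a bias correction, not an
  unbiased estimator; its behavior is validated by simulation only.
* For K > 15 the prior is Monte-Carlo; masses near the truncation level
  carry a few percent relative error.
* Real-data preprocessing (expression normalization, covariate/factor
  estimation, cis-window construction) is out of scope: the package
  consumes expression/genotype matrices plus a pair list, or a
  precomputed z-matrix.
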