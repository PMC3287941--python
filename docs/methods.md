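# Methods

## Model and sampler

The package fits the sparse linear model

    y = μ1 + X(θ ∘ α) + ε,  ε ~ N(0, σ²ε I)

to a quantitative phenotype y over an n × p dosage matrix X (0/1/2;
mean-imputed where missing). Each SNP j carries an inclusion indicator
θ_j ~ Bernoulli(π) and a slab effect α_j ~ N(0, σ²α). Conjugate priors —
scaled inverse chi-square on both variances, Beta(a₀, b₀) on π, flat on μ —
make every full conditional standard, and one Gibbs sweep updates, in fixed
order: σ²ε, μ, each (θ_j, α_j) pair for j = 1…p in ascending column order,
σ²α, π.

The (θ_j, α_j) update is **partially collapsed**. Writing r₋ⱼ for the
residual with SNP j's contribution removed, the sufficient scalar
u_j = x_j′r₋ⱼ has marginal law N(0, c_jj σ²ε) when SNP j is excluded and —
with α_j integrated over its slab — N(0, c_jj σ²ε + c_jj² σ²α) when
included, where c_jj = x_j′x_j. θ_j is drawn from the resulting Bernoulli
(computed in log space through the log-odds, so extreme evidence cannot
overflow), and only if θ_j = 1 is α_j then drawn from
N(u_j/c_j, σ²ε/c_j) with c_j = c_jj + σ²ε/σ²α. Excluded effects are exact
zeros: they contribute nothing to the model, to the posterior-mean
coefficient, or to the slab-variance update, and no prior draw is stored
for them. Collapsing α_j out of the indicator draw is what lets the chain
move SNPs in and out of the model in one step; the enumeration oracle
(below) confirms the update targets the intended posterior.

Two slab parameterisations are available. The default shares one σ²α
across all included effects, updated from
ScaledInv-χ²(v_α + k, (v_α S_α + Σ_{θ_j=1} α_j²)/(v_α + k)) — pooling
strength across SNPs, which stabilises the slab scale when few SNPs are
included. `per_locus_slab=True` instead gives every SNP its own σ²αⱼ
(updated from its single effect when included, refreshed from the prior
when excluded), which lets effect-size heterogeneity express itself at the
cost of slower mixing; it is not the default because the pooled form is
the simpler model and the one the rest of the package is validated
against.

### Defaults and their rationale

| parameter | default | why |
|---|---|---|
| n_iter / burn_in | 15,000 / 1,000 | canonical schedule for this analysis; PPA = post-burn-in inclusion proportion |
| v_ε, S_ε | 10, var(y)/2 | weakly informative, centred on "half the phenotype variance is noise" |
| v_α, S_α | 4, var(y)/(2·expected_k) | slab sized so ~expected_k SNPs could jointly explain half of var(y) |
| expected_k | 10 | prior guess at the associated-SNP count; only scales S_α |
| a₀, b₀ | 1, 1 | uniform prior on π (unstated upstream; the Beta posterior is dominated by (k, p−k) for realistic p) |
| thin | 1 | retained draws are cheap; thinning only discards information |

All units follow the trait: effects are trait-units per dosage unit, σ²ε
trait-units², S_α (trait/dosage)².

Initialisation is neutral: μ ← mean(y), θ ← 0, α ← 0, σ²ε ← var(y),
σ²α ← S_α, π ← a₀/(a₀+b₀). Fixed-value hooks (`fix_sigma2_eps`,
`fix_sigma2_alpha`, `fix_pi`, `fix_mu`) disable individual updates; they
exist for validation (the enumeration oracle holds these quantities fixed)
and for sensitivity analyses such as pinning π.

### Numerical choices

- The sampler maintains the residual r and z = X′r incrementally; a SNP
  that stays excluded costs O(1) per sweep, so a sweep costs
  O(p + changed·(n+p)) rather than O(np). Both vectors are rebuilt from
  scratch every `recompute_resid_every` = 1,000 sweeps; the observed drift
  stays far below the asserted 1e−6 relative tolerance.
- One seeded random stream per chain, consumed in a fixed documented order,
  makes runs bit-reproducible; per-replicate seeds are derived from the
  master seed by a fixed affine offset.
- Monomorphic columns (x_j′x_j = 0) are excluded from updates and reported
  with PPA 0. A fully monomorphic matrix is refused.
- k's point estimate is the posterior mode of the retained model sizes,
  ties broken toward the smaller k (parsimony).
- Rank ties (identical averaged scores) break by ascending SNP index.
- ROC cutoffs are the distinct observed scores plus a sentinel above the
  maximum, guaranteeing the (0,0) point; the trapezoidal AUC then equals
  the causal/non-causal concordance probability with ties counted ½ (an
  identity the tests assert exactly).

## Exact oracle

For p ≤ 14 and fixed (σ²ε, σ²α, π), with y centred and μ treated as 0, the
marginal likelihood of every model γ ∈ {0,1}^p is Gaussian:
y ~ N(0, σ²ε I + σ²α X_γX_γ′). Enumeration with log-sum-exp normalisation
gives exact PPAs and the exact model-size distribution. Determinants and
quadratic forms go through the matrix-inversion lemma on the |γ| × |γ|
inner matrix, so large n is cheap. Centring y instead of integrating μ
under a flat prior keeps the oracle exact and matches the sampler's
`fix_mu=0` hook. The headline validation asserts max |Gibbs PPA − exact
PPA| ≤ 0.02 after 50,000 sweeps on an n=100, p=8 instance.

## Simulator

The simulator emulates the GAW17 mini-exome structure: one fixed genotype
matrix (default 697 unrelated individuals, 24,487 SNPs), MAFs log-uniform
over [0.0717%, 49.9283%] with half the SNPs forced below 1% (log-uniform
rather than uniform so the rare tail is well populated), dosages
Binomial(2, MAF) under Hardy-Weinberg, SNPs partitioned into contiguous
gene blocks (default ~8 SNPs per gene), and many phenotype replicates over
the fixed genotypes. Presets: `q1` (39 causal SNPs in 9 genes), `q2` (72
in 13), `q4` (null). Causal effects default to inverse-MAF scaling
(|β| ∝ 1/√(2·MAF·(1−MAF))), so each causal SNP explains an equal variance
share and rare variants get larger per-allele effects; a log-uniform
effect mode is available. Effects are rescaled so Var(Xβ) = h² and the
noise variance is 1 − h², giving unit phenotypic variance in expectation;
h² defaults to 0.4 as a package choice (the upstream trait heritabilities
are not published).

What the simulator deliberately does **not** model: linkage
disequilibrium between columns (independent SNPs; a duplicate-column
injector creates the perfect-LD false-positive scenario on demand),
population structure or relatedness, genomic coordinates and annotation,
and non-Gaussian phenotype noise or outliers. Passing tests therefore
demonstrate correctness of the sampler and evaluation machinery under the
model's own assumptions — they do not certify performance under LD,
stratification, or heavy-tailed traits.

## Evaluation

Per replicate, a chain yields per-SNP posterior-mean coefficients and
PPAs plus a point estimate of k. Across replicates the package averages
|coefficient| and PPA per SNP, ranks each averaged score in decreasing
order, and calls a SNP associated when its rank is within the maximum of
the per-replicate k range under both rankings (the conjunction being the
stricter reading of reporting both ranks; single-score calling is a flag).
ROC/AUC are computed by cutoff sweep, on all SNPs and on the MAF < 1%
subset, with within-subset denominators for the rare-only curve.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to exercise the same
regimes at a fraction of the full-exome cost: oracle agreement at n=100,
p=8 (50,000 sweeps); conjugate limit at n=50 with 20,000 retained draws;
recovery studies at n=500, p=1,000 with 10 causal SNPs (5 rare at 0.4–1%
MAF, 5 common, shares 1% and 7% of variance respectively, h²=0.4) over 20
phenotype replicates with default 15,000-sweep chains; null calibration at
n=200, p=100 with π fixed at 0.01. The acceptance script runs three
recovery studies; the test suite runs ten.

## Known limitations

- A single shared π and (by default) a single slab variance assume
  exchangeable SNPs; no gene-, pathway- or LD-block-level structure is
  modelled, and perfectly correlated SNPs split inclusion mass between
  them (the oracle tests demonstrate this on duplicated columns).
- PPAs are Monte-Carlo estimates; their resolution is 1/n_retained.
- No covariate adjustment beyond the intercept, and no binary-trait
  extension.
- Mean-dosage imputation of missing genotypes ignores genotype
  uncertainty; it is adequate for the near-complete matrices this tool
  targets.
- The estimated number of associated SNPs (posterior mode of k) is
  sensitive to the slab scale when signals are weak; the recovery tests
  show it can overshoot the true causal count even when ranking is
  perfect.
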