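# bvsreg

Bayesian spike-and-slab variable selection for identifying rare and common
variants associated with quantitative traits.

Single-SNP tests are underpowered for rare variants (minor allele frequency
below 1%), because each rare variant carries very few observations.
`bvsreg` instead models **all SNPs simultaneously** in one sparse Bayesian
regression, so the evidence for every variant is weighed jointly, and
reports for each SNP a **posterior probability of association (PPA)** and a
posterior-mean effect size. It is aimed at mini-exome-style association
studies of unrelated individuals with quantitative phenotypes — the setting
exemplified by the GAW17 simulated exome (697 individuals, ~24.5k SNPs,
200 phenotype replications over one fixed genotype matrix), whose structure
the bundled simulator reproduces with known ground truth.

## Model

For *n* individuals and *p* SNPs with dosage matrix **X** (entries 0/1/2),

    y = μ1 + X(θ ∘ α) + ε,      ε ~ N(0, σ²ε I)

- θ_j ∈ {0,1} is a latent inclusion indicator with P(θ_j = 1) = π shared
  across SNPs (so the model size k = Σθ_j is a priori Binomial(p, π));
- α_j ~ N(0, σ²α) is the slab effect of SNP j; θ ∘ α is elementwise;
- σ²ε ~ ScaledInv-χ²(v_ε, S_ε), σ²α ~ ScaledInv-χ²(v_α, S_α),
  π ~ Beta(a₀, b₀).

All full conditionals are standard, and the posterior is explored by Gibbs
sampling (default 15,000 sweeps, first 1,000 discarded as burn-in). The PPA
of SNP j is the post-burn-in proportion of sweeps with θ_j = 1; the
(θ_j, α_j) update is partially collapsed: θ_j is drawn from the likelihood
of the sufficient scalar u_j = x_j′r₋ⱼ with α_j integrated over its slab,
then α_j | θ_j = 1 from its Normal full conditional.

Following the GAW17-style analysis, chains are fit to each phenotype
replicate, |coefficients| and PPAs are averaged across replicates and
ranked, and a SNP is called associated when it ranks within the estimated
number of associated SNPs (the across-replicate range of the posterior mode
of k) under **both** rankings. With known truth, cutoff sweeps over either
score give TPR/FPR series, ROC curves and AUCs — on all SNPs and on the
rare (MAF < 1%) subset.

For p ≤ 14 an exact posterior by enumeration over all 2^p models
(`bvsreg.oracle`) provides an independent target that the Gibbs sampler is
validated against.

## Worked example

Simulate a scaled trait-Q1-like dataset (39 causal SNPs in 9 genes,
h² = 0.4), fit one chain per phenotype replicate, and evaluate:

```sh
bvs simulate --preset q1 --out demo/data \
    --n-snps 200 --n-individuals 300 --n-replicates 5 --seed 7
# wrote 300 individuals x 200 SNPs, 5 replicates, 39 causal SNPs -> demo/data

bvs fit --genotypes demo/data/genotypes.tsv \
    --phenotypes demo/data/phenotypes.tsv \
    --truth demo/data/truth.tsv --out demo/fit \
    --iters 4000 --burn-in 500 --seed 7
# k range (7, 47), called 44 SNPs -> demo/fit

cat demo/fit/auc_report.tsv
# metric        value
# auc_all_coef  0.906195
# auc_all_ppa   0.901577
# auc_rare_coef 0.905138
# auc_rare_ppa  0.893281
```

The top of `demo/fit/averaged_report.tsv` (sorted by PPA rank):

```
snp_id  mean_abs_coef  mean_ppa  rank_coef  rank_ppa  called
   S39       1.259272  0.816629          1         1       1
   S44       0.151090  0.483200         11         2       1
    S1       0.367548  0.468571          2         3       1
```

`mean_ppa` is the across-replicate average posterior probability that the
SNP is associated; `rank_coef`/`rank_ppa` are its positions in the two
decreasing-score rankings; `called = 1` means both ranks fall within the
maximum of the estimated-k range. An AUC of ~0.9 on all SNPs says causal
SNPs are ranked above null SNPs 90% of the time; the rare-only AUC is
computed the same way but restricted to MAF < 1% variants.

The same objects are available as a scikit-learn-style estimator:

```python
from bvsreg import SpikeSlabRegressor
est = SpikeSlabRegressor(random_state=0).fit(X, y)   # X: n x p dosages
est.ppa_, est.alpha_mean_, est.k_point_
```

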