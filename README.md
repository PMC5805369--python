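# smarttissue

Infer **trait-relevant tissues** from GWAS summary statistics by jointly
modeling multiple tissue-specific SNP annotations, and reuse the fitted
annotation coefficients as SNP weights for a **more powerful SNP-set
association test**.

Most GWAS loci are noncoding, and their effects act through specific
tissues. Epigenomic projects provide per-tissue functional annotations
(histone-mark peaks, chromatin states, ...) for every SNP; a tissue is
relevant to a trait when its annotations predict SNP effect sizes. This
package implements that idea end to end, for statistical geneticists who
have GWAS summary statistics, a reference LD panel, and per-tissue SNP
annotations.

## Model

With standardized genotypes, the polygenic model

    y = X beta + e,   beta_j ~ N(0, sigma_j^2 / m),   sigma_j^2 = A_j' alpha*

makes each SNP's effect-size variance a linear function of its annotation
vector A_j = (1, C_j1, ..., C_jc)'. The pipeline has three stages:

1. **GEE fit** — marginal chi-square statistics obey
   E[chi2_j] = 1 + (n/m) sum_l r_jl^2 A_l' alpha* under a block-diagonal LD
   approximation; generalized estimating equations give closed-form
   coefficient estimates alpha_hat with a cluster-robust sandwich
   covariance, and a per-tissue multivariate Wald statistic
   alpha_hat' V(alpha_hat)^-1 alpha_hat (df = c).
2. **Mixture classification** — across tissues, Wald statistics are
   modeled as a two-component noncentral chi-square mixture (empirical
   null lambda_0 vs trait-relevant lambda_1, same df); EM yields each
   tissue's posterior probability (PP) of trait relevance. The empirical
   null absorbs the strong cross-tissue annotation correlation that
   inflates statistics of irrelevant tissues.
3. **Weighted SNP-set test** — the top tissue's fitted SNP variances
   sigma_hat_j^2 = A_j' alpha_hat*, shrunk toward equal weights by PP,
   weight a SKAT-style kernel test Q = r' G W G' r in a new cohort
   (Davies/Imhof tail inversion, saddlepoint in the far tail).

A synthetic-data module generates correlated genotypes, tissue-correlated
annotations, effects and summary statistics reproducing both of the study
designs, so everything runs without downloads.

## Worked example

Simulate a cohort of n = 10,000 with m = 2,000 SNPs in 100-SNP LD blocks,
ten candidate tissues with two correlated binary mark annotations each,
and a trait driven by tissue 4 (alpha = (0.25, 0.25), heritability 0.1);
then run the full inference from summary statistics:

```python
import numpy as np
import smarttissue as st

rng = np.random.default_rng(7)
m, n = 2_000, 10_000

G = st.simulate_genotypes(n, m, ld=("ar1", 0.8, 100), rng=rng)
X, _, _ = st.standardize_genotypes(G)
G_ref = st.simulate_genotypes(500, m, ld=("ar1", 0.8, 100), rng=rng)
ld = st.estimate_ld_blocks(G_ref, block_size=100)

tissues = [st.center_annotations(A) for A in
           st.simulate_tissue_annotations(m, 10, (0.18, 0.107), 0.7, rng)]
_, y = st.simulate_effects_phenotype(X, tissues[4], (0.1, 0.25, 0.25), 0.9, rng)

_, chisq = st.marginal_scan(X, y)
stats = st.SummaryStats(np.array([f"rs{i}" for i in range(m)], dtype=object),
                        chisq, n)
table = st.fit_all_tissues(stats, tissues, ld, working="ld")
fit = st.em_fit(table["wald"].to_numpy(), df=2, seed=0)
table["pp"] = fit.pp.round(3)
print(table[["tissue", "wald", "alpha_mark1", "alpha_mark2", "pp"]]
      .round(3).to_string(index=False))
res = st.classify(fit, table["tissue"])
print(f"top tissue: {res['top_tissue']} (PP = {res['top_pp']:.2f}); "
      f"lambda0 = {fit.lambda0:.1f}, lambda1 = {fit.lambda1:.1f}")
```

Output:

```
 tissue   wald  alpha_mark1  alpha_mark2    pp
tissue0 45.248        0.185        0.115 0.965
tissue1 44.741        0.177        0.144 0.963
tissue2 17.200        0.130        0.114 0.437
tissue3 26.735        0.190        0.139 0.762
tissue4 52.205        0.241        0.161 0.982
tissue5 46.884        0.159        0.109 0.970
tissue6 30.873        0.171        0.128 0.846
tissue7 50.094        0.137        0.118 0.978
tissue8 51.572        0.152        0.174 0.981
tissue9 28.325        0.168        0.136 0.798
top tissue: tissue4 (PP = 0.98); lambda0 = 24.1, lambda1 = 39.6
```

The causal tissue 4 has the largest Wald statistic and coefficient
estimates near the truth, and tops the PP ranking. Because its annotations
are correlated 0.7 with every other tissue's, irrelevant tissues also show
inflated statistics — exactly the regime the empirical-null mixture is
built for (lambda_0 = 24 rather than the theoretical 2). Its fitted
coefficients can then weight a SNP-set test in a new cohort via
`st.snp_variances`, `st.construct_weights` and `st.skat_test`.

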