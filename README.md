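# wfkat — Wright–Fisher kernel association testing for SNP sets

`wfkat` is a Python library for **joint association testing of SNP sets**
(genes, pathways) against binary or quantitative traits, aimed at
sequencing panels that mix common variants (MAF > 10%) with many rare ones
(MAF < 1%).  Single-marker tests are underpowered in this regime, burden
tests break when deleterious and protective variants coexist, and linear
aggregation misses epistasis.  `wfkat` addresses all three with:

1. **A Wright–Fisher (WF) Mercer kernel for discrete genotypes.**  A SNP
   set of *p* loci, coded by major-allele counts, is treated as a
   Dirichlet-multinomial draw over *p* + 1 categories (the *p* per-locus
   counts plus the total minor-allele burden).  The WF resampling chain
   with Dirichlet mutation mass **α** moves from genotype **x** to **x′**
   with the multinomial probability of the augmented target vector under

   π<sub>t</sub>(**x**) = (x<sub>t</sub> + α<sub>t</sub>) / (N + |α|),  N = 2p.

   The chain has positive spectrum (eigenvalues (2p)<sub>[i]</sub>/(2p)<sup>i</sup>
   in the small-mutation limit), so the transition matrix between study
   individuals — after per-column ℓ₂ scaling and multiplicative
   symmetrization K ∘ Kᵀ — is a valid similarity kernel.  **α** is fitted
   to the sample by constrained maximum likelihood.

2. **Kernel sliced inverse regression (kSIR)** for supervised, nonlinear
   aggregation.  With the centered Gram matrix K̄ and the slice matrix
   J (J<sub>ij</sub> = 1/(n·n<sub>h</sub>) for samples sharing slice *h*), the dual
   generalized eigenproblem

   K̄ J K̄ **a** = λ (K̄ K̄ + ridge·I) **a**

   yields sufficient predictors s<sub>i</sub> = Σ<sub>j</sub> a<sub>j</sub> k̄(x<sub>j</sub>, x<sub>i</sub>)
   that carry the regression information of the whole SNP set; only n × n
   objects are touched, so p ≫ n is fine.

3. **A GLM + permutation joint test.**  The statistic is the
   likelihood-ratio (deviance difference) of `trait ~ covariates +
   predictors` against `trait ~ covariates` — linear regression for
   quantitative traits, logistic for case–control.  Because the reduction
   is supervised, it is refit inside each of B genotype permutations; the
   empirical p-value is (1 + #{perm ≥ obs}) / (1 + B).

A simulation engine reproduces the evaluation design: TG/COL6A3-like
synthetic panels (n = 697; common MAF 0.32–0.43; rare MAF 0.005–0.0086),
traits Q = f(X) + ε dichotomized at the median, a library of ten genetic
architectures (additive common/rare, protective mixtures, main + epistasis,
pure epistasis, common–rare epistasis), and effect sizes controlled by the
signal-to-noise ratio SNR = var f(X) / var ε.

## Worked example

```python
from wfkat import (make_trait, permutation_test, scenario_library,
                   simulate_genotypes)

g = simulate_genotypes(n=697, seed=3)          # TG-like gene panel
scenarios = {s.name: s for s in scenario_library()}

for name in ("sim1_common_deleterious", "null"):
    _, status = make_trait(g, scenarios[name], seed=5)
    res = permutation_test(g, status, kernel_spec="wf",
                           dr_spec={"method": "ksir", "d": 1}, B=999, seed=7)
    print(f"{name:>25}: statistic = {res.statistic_obs:7.2f}   "
          f"p_empirical = {res.p_empirical:.4f}")
```

prints

```
  sim1_common_deleterious: statistic =   19.41   p_empirical = 0.0090
                     null: statistic =    4.96   p_empirical = 0.7060
```

The additive common-variant trait (SNR 0.1) is detected at p ≈ 0.01 while
the genotype-independent trait is not — the permutation null keeps the test
exactly calibrated.  The scripts in `examples/` walk through the other
capabilities (kernel construction, nonlinear reduction, power studies),
each printing the numbers it computes.

## Command line

```sh
wfkat kernel   --genotypes gene.tsv --kernel wf --out K.tsv
wfkat run      --genotypes gene.vcf --format vcf --trait status.csv \
               --kernel wf --dr ksir --permutations 10000 --seed 1 --out res.tsv
wfkat simulate --config experiment.yaml
```

Genotypes are read from plain {0,1,2} matrices (CSV/TSV) or biallelic-SNP
VCFs; kernels are written as TSV with a JSON provenance sidecar.

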