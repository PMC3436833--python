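# Methods

This note records the model, the estimation and testing procedures, the
defaults and the reasoning behind them, what the synthetic data emulate,
and the known limitations.

## The Wright–Fisher genotype kernel

**State space and chain.**  A SNP set of `p` biallelic loci genotyped in a
diploid individual is summarized, in major-allele coding, by the count
vector `x = (x_1, …, x_p)`, `x_t ∈ {0, 1, 2}`.  We augment it with a slack
category `x_0 = N − Σ_t x_t` (the total minor-allele burden) so the
augmented vector is a composition of `N = 2p`.  The Wright–Fisher
resampling chain with Dirichlet mutation mass `α = (α_1, …, α_p, α_slack)`
draws the next generation multinomially with

    π_t(x) = (x_t + α_t) / (N + |α|).

Its transition probability `k(x → x′)` is the multinomial pmf of the
augmented target.  The chain's spectrum is real and positive —
numerically, eigenvalues follow `N_[i] / (N + |α|)^i` with the
multiplicity of degree-`i` monomials, which reduces to the classical
falling-factorial ratio `(2p)_[i] / (2p)^i` as `|α| → 0`
(`wf_closed_form_eigenvalue`; the package verifies the spectrum of the
full chain at `p = 1, 2` by dense eigendecomposition).  The stationary law
is approximately Dirichlet-multinomial`(N, α)`; the approximation error
shrinks with concentration (total variation ≈ 0.10 at `|α| = 2`, < 0.04 at
`|α| = 10` for `p = 1`, computed exactly from the 3-state chain).

**From chain to kernel.**  The `n × n` matrix `K` with
`K[i, j] = k(x_j → x_i)` is asymmetric; entries are computed in log space
(log-gamma) because the pmf underflows for large `p`.  Each column is
scaled to unit ℓ₂ norm (right-multiplication by a positive diagonal, which
preserves spectrum positivity), then symmetrized.  The default is the
multiplicative (Hadamard) symmetrization `K ∘ Kᵀ`.  The additive form
`(K + Kᵀ)/2` is also provided but is **not** guaranteed positive
semidefinite for a transition matrix restricted to a finite sample of
individuals, even when the asymmetric spectrum is positive; the test suite
keeps a 25-individual counterexample with a −0.3%-relative negative
eigenvalue.  The multiplicative form has never produced a negative
eigenvalue beyond floating-point noise in our checks and is therefore the
default.  PSD is always verified with tolerance `−1e−10 ×` (largest
eigenvalue).

**Estimating α.**  `estimate_dm_params` fits the Dirichlet-multinomial by
the standard digamma fixed-point iteration (method-of-moments start,
tolerance 1e−8 on the parameter change, ≤ 1000 iterations), jointly over
the `p + 1` augmented categories; zero-count categories are pinned to
1e−6 with a warning.  One behaviour deserves emphasis: genotype counts
from *independent loci in Hardy–Weinberg equilibrium are under-dispersed
relative to a multinomial*, so the DM likelihood increases monotonically
in the concentration `|α|` and the MLE sits at the multinomial boundary.
The iteration detects this and stops at the ceiling `|α| = 100 N`, where
the transition law is within ~1% of its multinomial limit and the
likelihood is numerically flat, returning the boundary estimate with
`boundary=True` and a warning.  For over-dispersed data (real LD between
loci) the MLE is interior and the ceiling is never touched.

The concentration acts as the kernel's *bandwidth*: small `|α|` yields a
sharply nonlinear, nearly diagonal kernel (each individual similar mostly
to itself), large `|α|` a smooth kernel approaching a weighted linear one.
At the boundary the kernel is smooth and well conditioned, which is what a
697-sample panel supports; explicitly concentrated chains (e.g.
`|α| = N`) are useful for small, dense SNP sets with strongly nonlinear
signals and can be passed as an explicit `DirichletParams`.

**Out-of-sample evaluation.**  `wf_cross_kernel` evaluates new samples
against a training panel with the same α, the training column norms for
the training side, and the new individual's outgoing-transition norm over
the `n` training individuals for its own column; projecting the training
panel through it reproduces the training kernel exactly.

## Classic kernels

IBS (`Σ_s (2 − |x_is − x_js|) / 2p`, minor coding), weighted IBS with
positive per-variant weights (default `w_s = 1/√f_s`, the MAF floored at
`1/(2n)`; the printed weighting of the cited literature, up-weighting rare
variants), Gaussian with the median-pairwise-distance bandwidth, and the
linear kernel `G Gᵀ` on centered codes.  The IBS family is computed via
threshold-indicator features (`I(x ≥ 1)`, `I(x ≥ 2)`), i.e. matrix
products rather than an `O(n²p)` loop — this identity also shows IBS is a
linear kernel on dominance/recessive indicator features, which explains
both its robustness and its blindness to cross-locus products.

## Kernel sliced inverse regression

Responses are sliced — binary traits by class (`H = 2`), quantitative ones
into `H = 10` near-equal slices by sorted order (stable ties).  Linear SIR
solves `Ω η = λ (Σ + ridge·I) η` with
`Ω = Σ_h (n_h/n)(x̄_h − x̄)(x̄_h − x̄)ᵀ`; kSIR solves the dual problem

    K̄ J K̄ a = λ (K̄ K̄ + ridge·I) a,

with `K̄ = HKH` the doubly centered kernel and `J = Z Zᵀ`,
`Z[:, h] = 1_h / √(n n_h)`.  Both are reduced to ordinary symmetric
eigenproblems: in the eigenbasis of `K̄` the right operator is diagonal,
and the numerator `J` has rank `H`, so the solution lives in an `H`-dim
subspace and is obtained from an `H × H` Gram matrix.  Eigenvalues are
reported on the SIR scale (in [0, 1]); at most `H − 1` directions exist.
Dual vectors are scaled to unit-norm in-sample predictors and signed so
each predictor correlates non-negatively with the response.

**Ridge.**  The default is `trace(K̄K̄)/n` — the mean squared eigenvalue
of `K̄`.  This choice matters: with a vanishing ridge and a binary trait,
the leading kSIR predictor can *interpolate* the class labels through the
numerically full-rank kernel, and the permutation test loses essentially
all power (every permutation interpolates equally well).  With a very
large ridge the predictor degenerates to `K̄²y`, a pure
kernel-alignment score.  The mean-squared-eigenvalue scale sits between
the two regimes, shrinking the weak tail of the spectrum while keeping
the strong components, and is scale-free in the kernel normalization.

## The joint association test

The statistic is the GLM likelihood-ratio (deviance difference) between
`trait ~ covariates` and `trait ~ covariates + predictors`: Gaussian with
identity link for quantitative traits (equal to `n log(RSS₀/RSS₁)`),
binomial with logit link for binary traits.  The public `glm_statistic`
goes through statsmodels (with a ridge-stabilized Newton fallback for
separated logistic fits); the permutation loop uses an equivalent
vectorized Newton/IRLS routine, warm-started at the null fit and checked
against the statsmodels route to 1e−4 relative in the tests.

**Permutation design.**  The null of interest is "genotypes carry no
information about the trait, covariates may".  Permutations therefore
permute the *genotype side* against intact (trait, covariate) pairs —
equivalently a simultaneous row/column permutation of the kernel — which
reduces to permuting the trait when no covariates are present.  Because
the reduction is supervised, it is refit inside every permutation;
reusing the observed directions would be anti-conservative.  The kernel
itself is label-free and computed once.

**Acceleration.**  Per dataset, the eigendecomposition of `K̄` is computed
once and truncated to the top `m = min(n, 150)` components; each
permutation then costs `O(n m)` (slice sums of eigenvector rows) plus an
`H × H` eigensolve, and the GLM refits are batched across permutations.
The tests confirm the truncated path reproduces the unreduced empirical
p-value within resampling noise on an `n = 200` fixture.  The empirical
p-value uses the add-one correction `(1 + #{perm ≥ obs}) / (1 + B)` and
can never return 0.

## Synthetic data

`simulate_genotypes` draws each SNP's MAF uniformly within its declared
range and genotypes as two independent Bernoulli allele draws (HWE).  The
default panel emulates the TG gene: `n = 697`, 10 common variants with
MAF in 0.32–0.43 and 140 rare ones in 0.005–0.0086.  A block-copula mode
thresholds an equicorrelated latent normal to induce declared pairwise
`r²` within blocks (the latent correlation is solved from the bivariate
normal orthant probability; infeasible targets raise).  What the
generator does *not* emulate: realistic LD decay along the gene,
population structure, genotyping error and missingness patterns, or the
site-frequency spectrum of real sequence data — power numbers transfer to
real panels only qualitatively.

Traits follow `Q = f(X) + ε` with standard normal ε (pure noise under the
null); the binary trait declares the top `⌈n/2⌉` of the realized `Q`
affected (stable ties).  Under this design a linear coefficient `β` maps
to a disease odds ratio `(1 − Φ(−β))/Φ(−β)` for a variant at the
distribution's center — the correspondence `beta_to_odds_ratio` and a
simulation check at `n = 20 000` both reproduce the printed endpoints
(β = 1 → 5.3, β = −0.2 → 0.7).

**Scenario library.**  Ten architectures: null; additive effects on the
ten top-MAF common variants (all deleterious, or two protective);
additive effects on ten rare variants (likewise); main + interaction on
two common variants; pure pairwise epistasis among three low-LD common
variants; a three-way product; and two common–rare interaction models
(all-positive, and one protective).  Causal SNPs are addressed by
descending-MAF rank within their stratum, common candidates greedily
filtered to pairwise `r² < 0.3`.  Interaction terms are **raw products of
allele-count codes** (mean-centered products are available via
`center_interactions=True`): a median-split trait built from raw products
retains marginal structure at individual loci, which is what makes
moderate-SNR epistasis detectable at all; fully centered products carry
almost no marginal signal and need far larger SNR.  Effect magnitudes are
set through the target SNR (exact on the realized panel): 0.1 for
main-effect models, 0.12 for interaction models.

**Replicate driver.**  `run_power_experiment` reuses one genotype panel
across replicates with fresh traits (mirroring designs conditioned on
real genotypes; the kernel is then built once) and reports the rejection
fraction at `α`, its binomial Monte-Carlo standard error, and the
per-replicate p-values.  Everything is deterministic given the seed, with
per-replicate substreams drawn from one generator.

## Problem sizes and defaults

The package's own evaluation (acceptance script and test suite) runs at a
desk scale chosen to keep Monte-Carlo error acceptable: type-I error at
`n = 400`, `p = 60`, `R = 200` replicates × `B = 500` permutations
(99% binomial band at the nominal 0.05 is [0.012, 0.095]); power at
`n = 697`, `p = 150`, `R = 50` × `B = 300` (binomial SE ≤ 0.07).  The
paper-scale design (`R = 1000`, `B = 10 000`) is available through the
same interfaces and the YAML config of `wfkat simulate`.

Other defaults: `d = 1` retained component (the leading summary variable
represents the SNP set); `H = 10` slices for quantitative traits;
multiplicative symmetrization; minor-allele coding for IBS/weighted
IBS/Gaussian and major-allele coding for the WF kernel, recoded
automatically; missing genotype calls imputed to the per-SNP rounded mean
count (keeps the {0, 1, 2} lattice the transition pmf is defined on).

## Limitations

- The WF kernel's nonlinearity is governed by the fitted concentration;
  on HWE-independent panels the boundary MLE yields a smooth, nearly
  linear kernel, and detection of *fully centered* interaction effects
  (no marginal component) is then weak.  Passing an explicit concentrated
  `DirichletParams` restores strong nonlinearity at the cost of
  conditioning.
- Additive symmetrization can lose positive semidefiniteness on sampled
  transition matrices (documented counterexample); use multiplicative
  when PSD matters downstream.
- Single SNP set at a time; no multiplicity control across sets, no
  population-stratification adjustment, no phasing or imputation beyond
  mean fill, biallelic SNPs only.
- Comparator methods from the surrounding literature (variable-threshold
  and adaptive-clustering rare-variant tests) are not implemented.
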