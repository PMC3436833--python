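"""Supervised aggregation of a SNP set with kernel sliced inverse regression.

A quantitative trait driven by a squared linear index of the genotypes is
not recoverable by any linear summary.  Linear SIR's leading predictor
barely tracks the signal, while kSIR with a nonlinear kernel follows it
closely; the printed correlations quantify the difference.
"""

import warnings

import numpy as np

from wfkat import (DirichletParams, GenotypeMatrix, TraitVector, fit_ksir,
                   fit_sir, project, wf_kernel)

warnings.simplefilter("ignore")
rng = np.random.default_rng(17)

n, p = 500, 8
maf = rng.uniform(0.2, 0.45, p)
g = GenotypeMatrix(rng.binomial(2, maf, size=(n, p)))
beta = rng.standard_normal(p)
# squared *centered* index: zero linear component, purely nonlinear signal
index = (g.values - g.values.mean(axis=0)) @ beta
signal = index ** 2
y = TraitVector(signal + 0.5 * signal.std() * rng.standard_normal(n))

# a concentrated chain (|alpha| = 2p) makes the WF kernel strongly nonlinear
mean_major = 2.0 - g.values.mean(axis=0)
aug = np.append(mean_major, 2 * p - mean_major.sum())
alpha = 2 * p * aug / aug.sum()
dm = DirichletParams(alpha[:-1], alpha[-1])

sir = fit_sir(g, y, H=10, d=1)
s_sir = project(sir, g_new=g)
ksir = fit_ksir(wf_kernel(g, dm=dm), y, H=10, d=1)
s_ksir = ksir.train_ref["predictors"]

print(f"trait: y = ((X - mean) beta)^2 + noise on {n} individuals, {p} SNPs")
print(f"linear SIR leading eigenvalue:  {sir.eigenvalues[0]:.3f}")
print(f"kSIR (WF) leading eigenvalue:   {ksir.eigenvalues[0]:.3f}")
print("|corr(predictor, true signal)|:")
print(f"  linear SIR: {abs(np.corrcoef(s_sir[:, 0], signal)[0, 1]):.3f}")
print(f"  kSIR (WF):  {abs(np.corrcoef(s_ksir[:, 0], signal)[0, 1]):.3f}")
print("The kernel predictor tracks the nonlinear signal; the linear one "
      "catches only its linear component.")
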