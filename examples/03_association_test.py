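"""The joint SNP-set association test with a permutation p-value.

Simulates a TG-like gene (10 common + 140 rare variants, 697 individuals),
generates a case-control trait from an additive effect on the common
variants at SNR 0.1, and runs the WF-kernel kSIR permutation test — once
for the causal trait and once for a genotype-independent null trait.  The
empirical p-value is (1 + #{permutation statistic >= observed}) / (1 + B).
"""

import warnings

from wfkat import make_trait, permutation_test, scenario_library, simulate_genotypes

warnings.simplefilter("ignore")

g = simulate_genotypes(n=697, seed=3)      # TG-like panel by default
scenarios = {s.name: s for s in scenario_library()}

for name in ("sim1_common_deleterious", "null"):
    _, status = make_trait(g, scenarios[name], seed=5)
    res = permutation_test(g, status, kernel_spec="wf",
                           dr_spec={"method": "ksir", "d": 1}, B=999, seed=7)
    print(f"{name:>25}: statistic = {res.statistic_obs:7.2f}   "
          f"p_empirical = {res.p_empirical:.4f}   (B = {res.B})")

print("\nA small p for the causal scenario and a moderate-to-large p under "
      "the null is the expected pattern;\nthe smallest attainable p at "
      "B = 999 is 0.001.")
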