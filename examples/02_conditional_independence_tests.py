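"""The three conditional-independence regimes on crafted dependencies.

A linear link is caught by partial correlation; a quadratic link is invisible
to it but caught by GP-residual distance correlation (GPDC); multiplicative
noise carries no mean signal at all and needs the kNN conditional mutual
information test (CMIknn).  Each p-value comes from an autocorrelation-aware
permutation scheme.
"""

import numpy as np

import boldcausal as bc

rng = np.random.default_rng(0)
n = 800
x = rng.standard_normal(n)
cases = {
    "linear": 0.5 * x + rng.standard_normal(n),
    "quadratic": 0.5 * x**2 + rng.standard_normal(n),
    "multiplicative noise": (1 + np.abs(x)) * rng.standard_normal(n),
}

print(f"{'dependence':>22} | {'parcorr p':>9} | {'gpdc p':>9} | {'cmiknn p':>9}")
for name, y in cases.items():
    row = []
    for method in ("parcorr", "gpdc", "cmiknn"):
        spec = bc.CITestSpec(i=0, j=1, lag=0, method=method,
                             n_permutations=199, seed=7, max_samples=500)
        res = bc.ci_test(np.column_stack([x, y]), spec)
        row.append(res.p_value)
    print(f"{name:>22} | {row[0]:9.3f} | {row[1]:9.3f} | {row[2]:9.3f}")

print("\nSmall p (< 0.01) marks detected dependence: each test regime "
      "catches its own class,\nwhich is what the triangulation rule "
      "(linear / non-linear / complex) exploits.")
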