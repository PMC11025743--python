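"""The evaluation-statistics suite on one observed-vs-predicted pair.

Simulates slightly biased predictions and prints RMSE, Pearson r, Lin's
concordance coefficient, the MSEP decomposition and the joint test of the
observed-on-predicted regression having intercept 0 and slope 1.
"""

import numpy as np

import silcal as sc

rng = np.random.default_rng(5)
obs = rng.normal(45, 5, 25)  # e.g. NDF, % DM
pred = obs + 0.4 + rng.normal(0, 1.2, 25)  # small bias + noise

rmse, r = sc.error_metrics(obs, pred)
print(f"RMSE_P = {rmse:.3f} % DM, r = {r:.3f}, r^2 = {r**2:.3f}")
print(f"CCC    = {sc.ccc(obs, pred):.3f}  (1 = perfect agreement)")

d = sc.msep_decompose(obs, pred)
print(f"MSEP   = {d.msep:.3f} = SB {d.sb:.3f} + MaF {d.maf:.3f} + MoF {d.mof:.3f}")
print(f"         ({100 * d.mof / d.msep:.0f}% of the error is random, not systematic)")

eq = sc.equivalence_test(obs, pred, alpha=0.05)
print(f"obs = {eq.beta0:.2f} + {eq.beta1:.2f} x pred;  joint P = {eq.p_joint:.3f} -> "
      f"{'reject equivalence' if eq.reject else 'predictions statistically equivalent'}")
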