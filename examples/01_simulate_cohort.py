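"""Simulate a PGx cohort with a baseline mediator effect and inspect it.

The genotype raises the baseline (beta_G0 = 0.1) and the baseline predicts
the change from baseline (beta_y0 = -0.2), so the genotype has an indirect
(mediator) effect of beta_G0 * beta_y0 = -0.02 on CFB even though its direct
effect beta_G is zero.
"""

import numpy as np

from cfbgwas import SimulationParams, simulate_cohort, unadjusted_marginal_effect

params = SimulationParams(beta_G0=0.1, beta_y0=-0.2, beta_G=0.0, seed=1)
cohort = simulate_cohort(params)

print(f"subjects: {len(cohort)}")
print(f"mean ln y0: {cohort.log_y0.mean():.3f}  (intercept 4.6)")
print(f"allele frequency: {cohort.genotype.mean() / 2:.3f}  (MAF 0.2)")
print(f"corr(ln y0, CFB): {np.corrcoef(cohort.log_y0, cohort.log_fold_cfb)[0, 1]:.3f}")
print(f"marginal G effect tested by unadjusted models: "
      f"{unadjusted_marginal_effect(params):+.3f}")
# The negative baseline-CFB correlation comes from beta_y0 < 0; the -0.02
# marginal effect is what makes unadjusted analyses reject a true null.
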