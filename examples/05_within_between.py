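"""Co-twin control: does the exposure effect survive within pairs?

Splits the total event count into the pair mean (between-family
information) and the within-pair deviation, estimated separately for MZ
and DZ pairs. A within-MZ effect cannot be explained by genes or shared
environment, so it is the design's closest approach to a causal effect.
The demonstration contrasts a purely causal exposure with a purely
family-environment-confounded one.
"""

import numpy as np

from twinsle import paper_like_config, simulate_cohort, within_between_rr
from twinsle.config import N_SLE_TOTAL

common = dict(
    n_pairs_by_group={"MZ-female": 2500, "DZ-female": 2500},
    sle_prevalence=np.full(N_SLE_TOTAL, 0.3),
    w_a=np.zeros(N_SLE_TOTAL),
)

print("scenario 1: purely causal exposure (RR 2, no confounding)")
config = paper_like_config(seed=8).replace(
    sigma2_a=0, sigma2_c=0, sigma2_e=0, sigma2_resid=0, mu0=-0.3,
    gamma=np.where(np.arange(N_SLE_TOTAL) == 4, np.log(2.0), 0.0),
    w_c=np.zeros(N_SLE_TOTAL), n_criteria=50, **common,
)
cohort = simulate_cohort(config)
table = within_between_rr(cohort, cohort["sle_c_05"].astype(float))
print(table[["effect", "rr"]].round(2).to_string(index=False))

print()
print("scenario 2: shared-environment selection only (no causal effect)")
config = paper_like_config(seed=8).replace(
    sigma2_a=0.0, sigma2_c=0.5, sigma2_e=0.1, sigma2_resid=0.1, mu0=-0.5,
    gamma=np.zeros(N_SLE_TOTAL),
    w_c=np.where(np.arange(N_SLE_TOTAL) == 4, 1.2, 0.0), **common,
)
cohort = simulate_cohort(config)
table = within_between_rr(cohort, cohort["sle_c_05"].astype(float))
print(table[["effect", "rr"]].round(2).to_string(index=False))
# In scenario 1 the whole-sample and within-pair RRs agree (~2); in
# scenario 2 the whole-sample RR is inflated by family selection while
# the within-pair RRs sit at 1 - the signature of confounding the
# co-twin design exists to detect.
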