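"""Bayes factors, posterior model probabilities and exceedance probabilities.

For two models under uniform priors, a Bayes factor BF gives posterior
BF/(1+BF); the Dirichlet posterior over group-level model frequencies gives
the expected frequency <r_1> and the exceedance probability p(r_1 > 0.5).
"""

import numpy as np

from bmsmaps import (
    DirichletPosterior,
    evidence_strength,
    exceedance_probs,
    expected_model_probs,
    posterior_from_bayes_factor,
)

for bf in (1.0, 3.0, 20.0, 150.0):
    p = posterior_from_bayes_factor(bf)
    print(f"BF = {bf:6.1f}  ->  posterior p(m1|y) = {p:.4f}  ({evidence_strength(bf)} evidence)")

# a fitted group posterior Dir(alpha = [3, 1]): e.g. 2 subjects, both assigned
# to model 1, on top of the one-observation-per-model prior
post = DirichletPosterior(alpha=np.array([3.0, 1.0]), alpha0=np.ones(2), n_subjects=2)
print(f"\nDir(alpha=[3,1]):  <r> = {expected_model_probs(post).round(4)}")
print(f"exceedance phi = {exceedance_probs(post).round(4)}")
print("phi_1 = p(r_1 > 0.5) = 1 - 0.5^3 = 0.875: the belief that model 1 is")
print("the more frequent model in the population, not just in this sample.")
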