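"""Simulate censored lineup data from known parameters and refit the model.

Shows that with generous per-condition sample sizes the maximum-likelihood
fit recovers the generating discriminability (d_a), criteria, and
target-rejection effect.
"""

import numpy as np

from seqsdt import LineupDesign, ModelSpec, ParameterSet, d_a, fit
from seqsdt.synthetic import simulate_table

truth = ParameterSet(mu_T=0.8, sigma2_T=0.6,
                     tau0=[0.10, 0.20, 0.00, 0.05, 0.15, 0.25],
                     delta=1.0, lambda_=0.5)
spec = ModelSpec("tau4", "null")
design = LineupDesign(6, 1)

table = simulate_table(truth, spec, design, n_per_condition=20_000, seed=11)
result = fit(spec, table, restarts=8, seed=1)
est = result.estimates

print(f"{'quantity':<12}{'true':>8}{'estimate':>10}")
for name, t, e in [("mu_T", truth.mu_T, est.mu_T),
                   ("sigma2_T", truth.sigma2_T, est.sigma2_T),
                   ("delta", truth.delta, est.delta),
                   ("lambda", truth.lambda_, est.lambda_),
                   ("d_a", d_a(truth), d_a(est))]:
    print(f"{name:<12}{t:>8.3f}{e:>10.3f}")
print(f"tau_0      {np.round(truth.tau0, 3)}")
print(f"tau_0 est  {np.round(est.tau0, 3)}")
print(f"\nG^2 = {result.g_squared:.1f} on {result.df} df "
      f"(p = {result.p_value:.2f}): the generating model fits its own data, "
      "and the\nestimates sit on top of the truth at this sample size.")
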