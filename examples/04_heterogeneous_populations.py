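"""Can witness heterogeneity alone mimic a target-rejection effect?

Simulates aggregate data from three heterogeneous populations in which every
witness holds a FIXED criterion (no within-witness shift), then computes the
hazard differences an analyst would observe.  Any nonzero difference is a
pure aggregation (selection-bias) artifact.
"""

import numpy as np

from seqsdt import builtin_table, hazard_differences
from seqsdt.studies import selection_bias_study

res = selection_bias_study(n_witnesses=700_000, seed=3)

obs = np.nanmean(hazard_differences(builtin_table("wilson")))
print(f"Observed mean hazard difference in the real data: {obs:+.3f}\n")
print(f"{'population':<14}{'mean diff':>11}{'max |diff|':>12}")
for label in res.scenarios:
    s = res.summary[label]
    print(f"{label:<14}{s['mean_difference']:>+11.4f}"
          f"{s['max_abs_difference']:>12.4f}")

print(
    "\nCriterion-only heterogeneity (simulation1) produces an artifact in "
    "the same\ndirection as the data but an order of magnitude smaller; "
    "adding\ndiscriminability heterogeneity (simulations 2-3) flips the "
    "sign.  Aggregation\nbias therefore cannot explain the observed effect.")
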