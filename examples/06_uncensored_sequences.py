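"""Analyze full (uncensored) response sequences without a stopping rule.

Simulates six-response sequences in which discriminability drops and
criteria tighten after the first "yes", then (1) tests the i.i.d.
assumption that a position's yes rate ignores the preceding responses and
(2) recovers the pre/post differences with a conventional yes/no SDT fit.
"""

import numpy as np

from seqsdt import LineupDesign, ParameterSet
from seqsdt.studies import iid_position_test, prepost_binary_sdt
from seqsdt.synthetic import simulate_uncensored

design = LineupDesign(6, 1)
pre = ParameterSet(mu_T=0.9, sigma2_T=1.0,
                   tau0=[0.10, 0.15, 0.10, 0.12, 0.18, 0.20])
post = ParameterSet(mu_T=0.725, sigma2_T=1.0,
                    tau0=np.asarray(pre.tau0) + 0.565)

counts = simulate_uncensored(pre, post, design, n_per_condition=100_000,
                             seed=21)

res = iid_position_test(counts, position=3, face_type="target")
print("i.i.d. test at position 3 (target): are yes rates equal across the "
      "four\npossible preceding no/yes histories?")
print(f"  per-history yes rates: {np.round(res['proportions'], 3)}")
print(f"  G^2 = {res['g2']:.1f} on {res['df']} df, p = {res['p']:.2g} "
      "-> firmly rejected:\n  responses after a 'yes' follow different "
      "parameters.")

sdt = prepost_binary_sdt(counts, design, seed=1)
print("\nPre/post-first-'yes' SDT fit (positions 2-6):")
print(f"  d_a pre  = {sdt['da_pre']:.2f}   d_a post = {sdt['da_post']:.2f}  "
      f"(difference {sdt['da_difference']:+.2f})")
print(f"  mean criterion difference (post - pre) = "
      f"{sdt['mean_tau_difference']:+.2f}")
print(f"  LR test, equal discriminability: p = "
      f"{sdt['lr_discriminability']['p']:.2g}")
print(f"  LR test, equal criteria:         p = {sdt['lr_criteria']['p']:.2g}")
print("\nBoth generating differences (0.35 in d_a, 0.39 in criteria) are "
      "recovered,\nshowing why collapsing pre/post strata makes "
      "discriminability appear to\ndecline over the sequence.")
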