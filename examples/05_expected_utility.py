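"""Compare identification procedures by expected utility.

Computes the outcome probabilities of the stopping-rule lineup from the
packaged frequency table, combines them with outcome utilities, and finds
the prior probability of guilt at which the lineup and the showup break
even.
"""

import numpy as np

from seqsdt import (ProcedureOutcomes, UtilitySpec, builtin_table, crossover,
                    expected_utility, showup_outcomes)
from seqsdt.utility import no_stopping_rule_outcomes, utility_curve

lineup = ProcedureOutcomes.from_table("lineup (stopping rule)",
                                      builtin_table("wilson"))
procs = [lineup, no_stopping_rule_outcomes(), showup_outcomes()]

grid = np.round(np.arange(0.0, 1.01, 0.1), 2)
frame = utility_curve(procs, UtilitySpec(), grid)
print("Expected utility by prior probability of guilt:")
print(frame.round(3).to_string())

x = crossover(lineup, showup_outcomes())
print(f"\nLineup (stopping rule) and showup break even at p_guilty = "
      f"{x.p_guilty:.3f}.")
print("Below that prior the lineup's known lures shield the innocent "
      "suspect and the\nlineup wins; above it the showup's higher hit rate "
      "dominates.  Removing the\nstopping rule improves the lineup at every "
      "prior (witnesses can correct\nearlier mistakes).")
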