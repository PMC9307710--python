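"""Expected-utility comparison of identification procedures.

Given a procedure's outcome probabilities (hits, known-lure and
innocent-suspect false alarms, misses/rejections) and a utility assigned to
each outcome, the expected utility at prior guilt probability p is

    U(p) = p * sum_i P_TPi * U_TPi  +  (1 - p) * sum_i P_TAi * U_TAi,

an affine function of p.  Crossovers between two procedures therefore have
a closed-form solution.  The default utilities are deliberately
illustrative, not normative: they encode that falsely implicating an
innocent suspect is by far the worst outcome, and that freeing a guilty
suspect via a known-lure pick is worse than an outright miss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .data import LineupTable, OutcomeSummary, outcome_summary

__all__ = [
    "UtilitySpec",
    "ProcedureOutcomes",
    "expected_utility",
    "crossover",
    "utility_curve",
    "showup_outcomes",
    "no_stopping_rule_outcomes",
]

DEFAULT_UTILITIES = (2.0, -5.0, -1.0, -1.0, -20.0, 2.0)


@dataclass(frozen=True)
class UtilitySpec:
    """Outcome utilities (dimensionless): TP1..TP3 then TA1..TA3."""

    u_tp1: float = DEFAULT_UTILITIES[0]
    u_tp2: float = DEFAULT_UTILITIES[1]
    u_tp3: float = DEFAULT_UTILITIES[2]
    u_ta1: float = DEFAULT_UTILITIES[3]
    u_ta2: float = DEFAULT_UTILITIES[4]
    u_ta3: float = DEFAULT_UTILITIES[5]

    @property
    def tp(self) -> np.ndarray:
        return np.array([self.u_tp1, self.u_tp2, self.u_tp3])

    @property
    def ta(self) -> np.ndarray:
        return np.array([self.u_ta1, self.u_ta2, self.u_ta3])


@dataclass(frozen=True)
class ProcedureOutcomes:
    """A labeled pair of outcome triples for one procedure.

    For procedures without known lures (showups) the TP2/TA1 components are
    structurally zero.
    """

    label: str
    outcomes: OutcomeSummary

    @classmethod
    def from_table(cls, label: str, table: LineupTable) -> "ProcedureOutcomes":
        return cls(label, outcome_summary(table))

    @classmethod
    def from_triples(cls, label: str, tp: Sequence[float],
                     ta: Sequence[float]) -> "ProcedureOutcomes":
        return cls(label, OutcomeSummary(*tp, *ta))


def showup_outcomes() -> ProcedureOutcomes:
    """Published showup outcome percentages (single-face procedure).

    Hit 86.6% / miss 13.4% when the face is the target; innocent-suspect
    false alarm 26.4% / correct rejection 73.6% otherwise.  Known-lure
    outcomes do not exist in a showup.
    """
    return ProcedureOutcomes.from_triples(
        "showup", (0.866, 0.0, 0.134), (0.0, 0.264, 0.736))


def no_stopping_rule_outcomes() -> ProcedureOutcomes:
    """Published outcome percentages for the lineup scored by the last "yes".

    Removing the stopping rule lets witnesses revise earlier lure picks,
    raising the hit rate (66.2% vs 52.3%) at the expense of nothing in the
    target-absent column, which is unaffected.
    """
    return ProcedureOutcomes.from_triples(
        "lineup (no stopping rule)", (0.662, 0.249, 0.089),
        (0.579, 0.116, 0.305))


def expected_utility(proc: ProcedureOutcomes, spec: UtilitySpec = UtilitySpec(),
                     p_guilty: float = 0.5) -> float:
    """Expected utility of a procedure at prior guilt probability p."""
    if not 0.0 <= p_guilty <= 1.0:
        raise ValueError("p_guilty must be in [0, 1]")
    o = proc.outcomes
    u_tp = float(np.dot(o.tp_triple, spec.tp))
    u_ta = float(np.dot(o.ta_triple, spec.ta))
    return p_guilty * u_tp + (1.0 - p_guilty) * u_ta


@dataclass(frozen=True)
class Crossover:
    """Solution of U_A(p) = U_B(p)."""

    p_guilty: Optional[float]
    kind: str           # "interior", "outside", "parallel", "degenerate"


def crossover(proc_a: ProcedureOutcomes, proc_b: ProcedureOutcomes,
              spec: UtilitySpec = UtilitySpec()) -> Crossover:
    """Guilt probability at which two procedures' expected utilities agree.

    Both utilities are affine in p, so the solution is exact.  Identical
    lines are reported as degenerate, parallel distinct lines as having no
    crossover, and a solution outside [0, 1] is reported with its value but
    flagged.
    """
    a0 = expected_utility(proc_a, spec, 0.0)
    a1 = expected_utility(proc_a, spec, 1.0)
    b0 = expected_utility(proc_b, spec, 0.0)
    b1 = expected_utility(proc_b, spec, 1.0)
    slope_diff = (a1 - a0) - (b1 - b0)
    intercept_diff = a0 - b0
    if abs(slope_diff) < 1e-14:
        kind = "degenerate" if abs(intercept_diff) < 1e-14 else "parallel"
        return Crossover(None, kind)
    p = -intercept_diff / slope_diff
    return Crossover(float(p), "interior" if 0.0 <= p <= 1.0 else "outside")


def utility_curve(procs: Iterable[ProcedureOutcomes],
                  spec: UtilitySpec = UtilitySpec(),
                  grid: Optional[np.ndarray] = None):
    """Expected utilities of several procedures over a grid of p_guilty.

    Returns a pandas DataFrame indexed by p_guilty with one column per
    procedure label; ``attrs['dominant']`` records the best procedure at
    each grid point.
    """
    import pandas as pd

    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    if ((grid < 0) | (grid > 1)).any():
        raise ValueError("grid values must lie in [0, 1]")
    procs = list(procs)
    data = {p.label: [expected_utility(p, spec, g) for g in grid] for p in procs}
    frame = pd.DataFrame(data, index=pd.Index(grid, name="p_guilty"))
    frame.attrs["dominant"] = frame.idxmax(axis=1).tolist()
    return frame
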