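"""Sequential-lineup frequency tables.

The observable in a sequential lineup experiment is a *censored* response
sequence: the position of the first "yes" (optionally with a confidence
level), or a rejection of the whole lineup.  Aggregated over witnesses this
yields one multinomial count vector per lineup condition (target at position
1..I, or target absent).  This module holds that data structure, readers and
writers for a plain CSV layout, the two published frequency tables that ship
with the package, and two descriptive summaries: outcome proportions and
discrete-hazard differences.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "ABSENT",
    "LineupDesign",
    "LineupTable",
    "OutcomeSummary",
    "load_table",
    "write_table",
    "builtin_table",
    "outcome_summary",
    "hazard_differences",
]

#: Distinguished label for the target-absent condition.
ABSENT = "absent"


@dataclass(frozen=True)
class LineupDesign:
    """Shape of a sequential lineup procedure.

    Parameters
    ----------
    sequence_length
        Number of faces shown, I >= 1.
    confidence_bins
        Number of confidence levels K attached to "yes" responses.
        K = 1 means binary yes/no judgments only.
    """

    sequence_length: int = 6
    confidence_bins: int = 1

    def __post_init__(self) -> None:
        if self.sequence_length < 1:
            raise ValueError(f"sequence_length must be >= 1, got {self.sequence_length}")
        if self.confidence_bins < 1:
            raise ValueError(f"confidence_bins must be >= 1, got {self.confidence_bins}")

    @property
    def n_categories(self) -> int:
        """Response categories per condition: I*K "yes" cells plus "reject"."""
        return self.sequence_length * self.confidence_bins + 1

    @property
    def n_conditions(self) -> int:
        return self.sequence_length + 1

    @property
    def degrees_of_freedom(self) -> int:
        """Non-redundant cells: (I+1) * I * K."""
        return self.n_conditions * self.sequence_length * self.confidence_bins

    def category_labels(self) -> list[str]:
        labels = []
        for i in range(1, self.sequence_length + 1):
            if self.confidence_bins == 1:
                labels.append(f"yes@{i}")
            else:
                labels.extend(
                    f"yes@{i}:bin{k}" for k in range(1, self.confidence_bins + 1)
                )
        labels.append("reject")
        return labels

    def condition_labels(self) -> list[str]:
        return [f"tp{h}" for h in range(1, self.sequence_length + 1)] + ["ta"]


Condition = Union[int, str]


def _condition_index(design: LineupDesign, condition: Condition) -> int:
    """Column index of a condition; target positions are 1-based."""
    if condition == ABSENT or condition == "ta":
        return design.sequence_length
    h = int(condition)
    if not 1 <= h <= design.sequence_length:
        raise ValueError(f"target position must be in 1..{design.sequence_length}, got {h}")
    return h - 1


@dataclass
class LineupTable:
    """Censored lineup choice frequencies.

    ``counts`` has one column per condition (target at 1..I, then absent)
    and one row per response category (the I*K "yes" cells in sequence/bin
    order, low confidence first, then "reject").
    """

    design: LineupDesign
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = (self.design.n_categories, self.design.n_conditions)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match design {expected}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.round(self.counts).astype(np.int64)
            if not np.allclose(self.counts, as_int):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            r, c = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at category {self.design.category_labels()[r]!r}, "
                f"condition {self.design.condition_labels()[c]!r}"
            )

    @property
    def condition_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_total(self) -> int:
        """Total number of lineups across all conditions."""
        return int(self.counts.sum())

    def condition_counts(self, condition: Condition) -> np.ndarray:
        return self.counts[:, _condition_index(self.design, condition)]

    def yes_counts(self, condition: Condition) -> np.ndarray:
        """Counts of "yes" responses by position, summed over confidence bins."""
        col = self.condition_counts(condition)[:-1]
        return col.reshape(self.design.sequence_length, self.design.confidence_bins).sum(axis=1)

    def reject_count(self, condition: Condition) -> int:
        return int(self.condition_counts(condition)[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.design.category_labels(), name="category"),
            columns=self.design.condition_labels(),
        )

    def collapse_confidence(self) -> "LineupTable":
        """Sum out confidence bins, returning a binary (K=1) table."""
        design = LineupDesign(self.design.sequence_length, 1)
        yes = self.counts[:-1].reshape(
            self.design.sequence_length, self.design.confidence_bins, -1
        ).sum(axis=1)
        counts = np.vstack([yes, self.counts[-1:]])
        return LineupTable(design, counts)


def load_table(source: Union[str, Path], design: LineupDesign) -> LineupTable:
    """Read a lineup table from CSV.

    The layout has a ``category`` column with labels ``yes@1`` .. ``yes@I``
    (suffixed ``:binK`` when confidence bins are present) plus ``reject``,
    and one integer column per condition named ``tp1`` .. ``tpI``, ``ta``.
    """
    frame = pd.read_csv(source, dtype={"category": str})
    if "category" not in frame.columns:
        raise ValueError("malformed header: missing 'category' column")
    expected_cols = design.condition_labels()
    missing = [c for c in expected_cols if c not in frame.columns]
    if missing:
        raise ValueError(f"malformed header: missing condition columns {missing}")
    frame = frame.set_index("category")
    expected_rows = design.category_labels()
    if list(frame.index) != expected_rows:
        raise ValueError(
            f"category rows {list(frame.index)} do not match expected {expected_rows}"
        )
    values = frame[expected_cols].to_numpy()
    for (r, c), v in np.ndenumerate(values):
        fv = float(v)
        if fv < 0 or fv != int(fv):
            raise ValueError(
                f"cell ({expected_rows[r]!r}, {expected_cols[c]!r}) = {v!r} "
                "is not a nonnegative integer"
            )
    return LineupTable(design, values.astype(np.int64))


def write_table(table: LineupTable, target: Union[str, Path]) -> None:
    """Write a table in the canonical CSV layout (round-trips with load_table)."""
    table.to_frame().to_csv(target)


_BUILTIN = {"wilson": "wilson.csv", "dunn": "dunn.csv"}


def builtin_table(study: str) -> LineupTable:
    """Return one of the two packaged binary frequency tables.

    ``wilson`` is the pooled two-experiment dataset with an emulated stopping
    rule (8,343 lineups); ``dunn`` is the follow-up study with an enforced
    stopping rule and a ~4:1 target-present ratio.
    """
    try:
        name = _BUILTIN[study]
    except KeyError:
        raise ValueError(f"unknown study {study!r}; expected one of {sorted(_BUILTIN)}")
    ref = importlib.resources.files("seqsdt.tables") / name
    with importlib.resources.as_file(ref) as path:
        return load_table(path, LineupDesign(6, 1))


@dataclass(frozen=True)
class OutcomeSummary:
    """Outcome proportions of an identification procedure.

    Target-present lineups: TP1 hit, TP2 known-lure false alarm, TP3 miss.
    Target-absent lineups: TA1 known-lure false alarm, TA2 innocent-suspect
    false alarm (the 1/I share of all lure identifications), TA3 correct
    rejection.  Each triple sums to one.
    """

    tp1: float
    tp2: float
    tp3: float
    ta1: float
    ta2: float
    ta3: float

    def __post_init__(self) -> None:
        if abs(self.tp1 + self.tp2 + self.tp3 - 1.0) > 1e-12:
            raise ValueError("TP outcome proportions must sum to 1")
        if abs(self.ta1 + self.ta2 + self.ta3 - 1.0) > 1e-12:
            raise ValueError("TA outcome proportions must sum to 1")

    @property
    def tp_triple(self) -> tuple[float, float, float]:
        return (self.tp1, self.tp2, self.tp3)

    @property
    def ta_triple(self) -> tuple[float, float, float]:
        return (self.ta1, self.ta2, self.ta3)


def outcome_summary(table: LineupTable) -> OutcomeSummary:
    """Outcome proportions averaged over target positions.

    Hits are "yes" at the target's position; known-lure false alarms in
    target-present lineups are "yes" anywhere else.  Target-present rates
    are the unweighted mean of the per-target-position rates (each target
    position treated as equiprobable, so small imbalances in condition
    sample sizes do not tilt the summary).  The total lure identification
    rate in target-absent lineups is split 1/I : (I-1)/I between the
    designated innocent suspect (TA2) and the remaining known lures (TA1),
    each lineup member being equally likely to stand in for the suspect.
    """
    if table.design.confidence_bins != 1:
        raise ValueError("outcome_summary expects a binary (K=1) table; "
                         "collapse_confidence() first")
    I = table.design.sequence_length
    hit_rates = []
    lure_rates = []
    for h in range(1, I + 1):
        yes = table.yes_counts(h)
        n = table.condition_totals[h - 1]
        hit_rates.append(yes[h - 1] / n)
        lure_rates.append((yes.sum() - yes[h - 1]) / n)
    ta_total = table.condition_totals[I]
    ta_yes_rate = table.yes_counts(ABSENT).sum() / ta_total
    tp1 = float(np.mean(hit_rates))
    tp2 = float(np.mean(lure_rates))
    tp3 = 1.0 - tp1 - tp2
    ta2 = ta_yes_rate / I
    ta1 = ta_yes_rate * (I - 1) / I
    ta3 = 1.0 - ta_yes_rate
    return OutcomeSummary(tp1, tp2, tp3, ta1, ta2, ta3)


def hazard_differences(table: LineupTable) -> np.ndarray:
    """Differences of discrete hazard rates after a target rejection.

    For each target position h and later sequence position i, contrasts the
    conditional probability of a "yes" to the lure at position i among
    witnesses still in the lineup (a discrete hazard) between the
    target-at-h condition and the target-absent condition::

        count(tp_h, yes@i) / remaining(tp_h, i) - count(ta, yes@i) / remaining(ta, i)

    where ``remaining(c, i)`` is the number of witnesses who had not yet
    identified anyone when face i was shown.  Returns an (I, I) array with
    entry [h-1, i-1]; cells with i <= h, or with a zero denominator, are NaN.
    """
    if table.design.confidence_bins != 1:
        raise ValueError("hazard_differences expects a binary (K=1) table")
    I = table.design.sequence_length
    out = np.full((I, I), np.nan)

    def hazard(condition: Condition, i: int) -> float:
        yes = table.yes_counts(condition)
        remaining = table.condition_totals[_condition_index(table.design, condition)] \
            - yes[: i - 1].sum()
        if remaining <= 0:
            return np.nan
        return yes[i - 1] / remaining

    for h in range(1, I + 1):
        for i in range(h + 1, I + 1):
            out[h - 1, i - 1] = hazard(h, i) - hazard(ABSENT, i)
    return out
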