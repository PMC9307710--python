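"""Synthetic lineup data with the structure the analyses assume.

Three generators:

* ``simulate_table`` - aggregate multinomial sampling of censored responses
  from any model in the family (the homogeneous-witness case);
* ``simulate_population`` - witness-level simulation in which each synthetic
  eyewitness draws private discriminability and/or criterion values (fixed
  within witness) and responds under the fixed-criterion baseline model;
  used to probe aggregation/selection-bias artifacts;
* ``simulate_uncensored`` - full 2^I response sequences with separate
  parameter regimes before and after the first "yes".

All generators are pure functions of their arguments and a single integer
seed; per-condition substreams are spawned deterministically so that adding
conditions never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .core import ParameterSet, cell_probabilities, uncensored_probabilities
from .data import ABSENT, LineupDesign, LineupTable
from .models import ModelSpec

__all__ = [
    "PopulationSpec",
    "simulate_table",
    "simulate_population",
    "simulate_uncensored",
    "likelihood_ratio_criterion",
]


def _condition_rngs(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def simulate_table(params: ParameterSet, spec: ModelSpec, design: LineupDesign,
                   n_per_condition: Union[int, dict], seed: int = 0) -> LineupTable:
    """Multinomial counts per condition from a model's cell probabilities.

    ``n_per_condition`` is a single integer applied to every condition or a
    mapping {1..I, "ta"} -> n.
    """
    conditions = list(range(1, design.sequence_length + 1)) + ["ta"]
    if isinstance(n_per_condition, dict):
        ns = [int(n_per_condition[c]) for c in conditions]
    else:
        ns = [int(n_per_condition)] * len(conditions)
    rngs = _condition_rngs(seed, len(conditions))
    cols = []
    for cond, n, rng in zip(conditions, ns, rngs):
        p = cell_probabilities(params, design, cond, mixture=spec.mixture)
        cols.append(rng.multinomial(n, p / p.sum()) if n > 0
                    else np.zeros(len(p), dtype=np.int64))
    return LineupTable(design, np.column_stack(cols))


# ---------------------------------------------------------------------------
# Heterogeneous populations

def likelihood_ratio_criterion(lr: float, mu_T: float,
                               sigma2_T: float = 1.0,
                               sigma2_L: float = 1.0) -> float:
    """Criterion where the target/lure density ratio equals ``lr``.

    Distributions are N(mu_T, sigma2_T) and N(-mu_T, sigma2_L).  With equal
    variances the log density ratio is linear, 2*mu_T*x / sigma2, giving
    the closed form x = sigma2 * ln(lr) / (2*mu_T).  Otherwise the equation
    is solved numerically on the rising segment between the means.
    """
    if mu_T == 0:
        raise ValueError("likelihood-ratio placement undefined at mu_T = 0")
    if lr <= 0:
        raise ValueError("lr must be positive")
    if sigma2_T == sigma2_L:
        return float(sigma2_T * np.log(lr) / (2.0 * mu_T))

    def log_ratio(x: float) -> float:
        return (norm.logpdf(x, mu_T, np.sqrt(sigma2_T))
                - norm.logpdf(x, -mu_T, np.sqrt(sigma2_L)) - np.log(lr))

    lo, hi = -mu_T, mu_T
    span = abs(mu_T) + 3 * max(np.sqrt(sigma2_T), np.sqrt(sigma2_L))
    lo, hi = -span, span
    return float(optimize.brentq(log_ratio, lo, hi))


@dataclass
class PopulationSpec:
    """Distributions of per-witness parameters for heterogeneity simulations.

    ``mu_T`` and ``tau0`` are either a fixed float or a (low, high) uniform
    range.  ``tau0_lr`` instead places each witness's criterion at the point
    where the target/lure likelihood ratio equals a value drawn uniformly
    from the given range (overrides ``tau0``).  Witnesses respond under the
    fixed-criterion baseline model: one criterion, fixed discriminability,
    no shift kernel.  ``contamination`` optionally adds an always-choose-
    the-first-face class with weight 1 - pi.
    """

    mu_T: Union[float, tuple] = 0.75
    tau0: Union[float, tuple] = 0.0
    tau0_lr: Optional[tuple] = None
    sigma2_T: float = 1.0
    sigma2_L: float = 1.0
    contamination: Optional[tuple] = None   # (pi_serious, zeta)
    stopping_rule: bool = True

    def __post_init__(self) -> None:
        for name in ("mu_T", "tau0"):
            v = getattr(self, name)
            if isinstance(v, tuple):
                lo, hi = v
                if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                    raise ValueError(f"{name} range must be finite with low <= high")
        if self.tau0_lr is not None:
            lo, hi = self.tau0_lr
            if not (lo > 0 and hi >= lo):
                raise ValueError("likelihood-ratio bounds must be positive")

    def draw(self, rng: np.random.Generator):
        """One witness's (mu_T, tau0)."""
        mu = (rng.uniform(*self.mu_T) if isinstance(self.mu_T, tuple)
              else float(self.mu_T))
        if self.tau0_lr is not None:
            lr = rng.uniform(*self.tau0_lr)
            tau = likelihood_ratio_criterion(lr, mu, self.sigma2_T, self.sigma2_L)
        elif isinstance(self.tau0, tuple):
            tau = rng.uniform(*self.tau0)
        else:
            tau = float(self.tau0)
        return mu, tau


def simulate_population(pop: PopulationSpec, design: LineupDesign,
                        n_witnesses_per_condition: int,
                        seed: int = 0) -> LineupTable:
    """Aggregate censored counts from a heterogeneous witness population.

    Each witness draws private (mu_T, tau0), then walks the lineup with
    those values held fixed: latent strengths are sampled per face and the
    first supra-criterion face is identified.  Contaminated witnesses skip
    the walk and always choose face 1.
    """
    I = design.sequence_length
    if design.confidence_bins != 1:
        raise ValueError("population simulation produces binary tables")
    conditions = list(range(1, I + 1)) + ["ta"]
    rngs = _condition_rngs(seed, len(conditions))
    cols = []
    pi_serious = 1.0 if pop.contamination is None else float(pop.contamination[0])
    for cond, rng in zip(conditions, rngs):
        n = n_witnesses_per_condition
        counts = np.zeros(I + 1, dtype=np.int64)
        target_at = None if cond == "ta" else int(cond)
        mus = np.empty(n)
        taus = np.empty(n)
        for w in range(n):
            mus[w], taus[w] = pop.draw(rng)
        serious = rng.random(n) < pi_serious
        # latent strengths: row per witness, column per position
        means = np.where(
            np.arange(1, I + 1)[None, :] == (target_at or -1),
            mus[:, None], -mus[:, None])
        sds = np.where(
            np.arange(1, I + 1)[None, :] == (target_at or -1),
            np.sqrt(pop.sigma2_T), np.sqrt(pop.sigma2_L))
        strengths = rng.normal(means, sds)
        yes = strengths > taus[:, None]
        first = np.where(yes.any(axis=1), yes.argmax(axis=1), I)
        first = np.where(serious, first, 0)     # contaminants pick face 1
        np.add.at(counts, first, 1)
        cols.append(counts)
    return LineupTable(design, np.column_stack(cols))


def simulate_uncensored(pre: ParameterSet, post: ParameterSet,
                        design: LineupDesign,
                        n_per_condition: Union[int, dict],
                        seed: int = 0) -> dict:
    """Counts over all 2^I full response sequences, per condition.

    Sequences are encoded as integers with bit j set when position j+1
    received a "yes" (see ``core.sequence_first_yes``).  Returns a mapping
    {condition: counts array of length 2^I}.
    """
    I = design.sequence_length
    conditions = list(range(1, I + 1)) + [ABSENT]
    if isinstance(n_per_condition, dict):
        ns = [int(n_per_condition.get(c, n_per_condition.get("ta", 0))
                  if c == ABSENT else n_per_condition[c]) for c in conditions]
    else:
        ns = [int(n_per_condition)] * len(conditions)
    rngs = _condition_rngs(seed, len(conditions))
    out = {}
    for cond, n, rng in zip(conditions, ns, rngs):
        p = uncensored_probabilities(pre, post, design, cond)
        out[cond] = (rng.multinomial(n, p / p.sum()) if n > 0
                     else np.zeros(len(p), dtype=np.int64))
    return out
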