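"""Maximum-likelihood fitting of lineup SDT models.

Each lineup condition contributes an independent multinomial likelihood
over its response categories.  Badness of fit is the deviance against the
saturated model,

    G^2 = 2 * sum_cells O * ln(O / E),    E = n_condition * p_model,

which is asymptotically chi-square with (I+1)*I*K - p degrees of freedom.
Models are optimized on the unconstrained transformed scale (see
``models``) with L-BFGS-B from several seeded scattered starting points;
the shift-kernel models have a mildly multimodal likelihood surface, so
headline fits should use generous restarts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .core import ParameterSet, probability_matrix
from .data import LineupDesign, LineupTable
from .models import ModelSpec, ParameterLayout, build_model, is_nested

__all__ = ["FitResult", "g_squared", "fit", "lr_test", "selection_table"]

_EPS = 1e-300


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    spec: ModelSpec
    estimates: ParameterSet
    free_vector: np.ndarray
    loglik: float
    g_squared: float
    df: int
    p_value: float
    aic: float
    bic: float
    n_restarts_used: int
    converged: bool

    @property
    def n_parameters(self) -> int:
        return len(self.free_vector)

    def summary(self) -> dict:
        return {
            "model": self.spec.to_string(),
            "parameters": self.n_parameters,
            "g_squared": round(self.g_squared, 2),
            "df": self.df,
            "p_value": round(self.p_value, 4),
            "aic": round(float(self.aic), 2),
            "bic": round(float(self.bic), 2),
            "converged": self.converged,
        }


def expected_probabilities(params: ParameterSet, spec: ModelSpec,
                           design: LineupDesign) -> np.ndarray:
    """Model cell probabilities arranged like LineupTable.counts."""
    return probability_matrix(params, design, mixture=spec.mixture)


def g_squared(observed: LineupTable, expected: np.ndarray) -> float:
    """Multinomial deviance of observed counts against cell probabilities.

    ``expected`` holds per-condition probabilities in table layout.  Cells
    with O = 0 contribute nothing; a structural zero (E = 0) under a
    positive count makes the deviance infinite and raises.
    """
    O = observed.counts.astype(float)
    n = observed.condition_totals.astype(float)
    E = expected * n
    bad = (O > 0) & (E <= 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"expected probability is zero where observed > 0 "
            f"(category {observed.design.category_labels()[r]!r}, "
            f"condition {observed.design.condition_labels()[c]!r})")
    mask = O > 0
    return float(2.0 * np.sum(O[mask] * np.log(O[mask] / E[mask])))


def _objective(layout: ParameterLayout, table: LineupTable) -> tuple:
    """Returns (negative-loglik-core function, saturated constant).

    The function computes -sum O log p; adding the saturated constant
    sum O log(O/n) and doubling gives G^2.
    """
    design = layout.design
    conditions = list(range(1, design.sequence_length + 1)) + ["ta"]
    O = table.counts.astype(float)
    n = table.condition_totals.astype(float)
    mask = O > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = float(np.sum(O[mask] * np.log(O[mask] / np.broadcast_to(n, O.shape)[mask])))
    spec = layout.spec

    def nll(x: np.ndarray) -> float:
        try:
            params = layout.to_natural(x)
            P = probability_matrix(params, design, mixture=spec.mixture)
        except (ValueError, FloatingPointError):
            return 1e12
        total = -float(np.sum(O[mask] * np.log(np.maximum(P[mask], _EPS))))
        if not np.isfinite(total):
            return 1e12
        return total

    return nll, sat


def _start_points(layout: ParameterLayout, rng: np.random.Generator,
                  n: int) -> np.ndarray:
    """Seeded scattered starting vectors on the free scale.

    Centered on a mildly informative anchor (unit variance, near-zero
    criteria, moderate discriminability) with wide jitter.
    """
    center = np.zeros(layout.n_free)
    for i, name in enumerate(layout.names):
        if name == "mu_T":
            center[i] = 0.8
        elif name.startswith("log_dtau0") or name.startswith("log_kappa"):
            center[i] = -1.0
        elif name == "log_lambda":
            center[i] = -0.7
        elif name == "logit_pi":
            center[i] = 2.0
    return center + rng.uniform(-1.2, 1.2, size=(n, layout.n_free))


def fit(spec: ModelSpec, table: LineupTable, *, restarts: int = 10,
        seed: int = 0, tol: float = 1e-10,
        start: Optional[np.ndarray] = None,
        extra_starts: Optional[Sequence[np.ndarray]] = None) -> FitResult:
    """Fit a model by maximum likelihood with seeded multistart L-BFGS-B.

    ``start``/``extra_starts`` add deterministic starting vectors (on the
    free scale) to the scattered ones - useful when polishing a nested
    refit from the parent's solution.  The best local optimum across all
    starts is polished once more and reported; results are deterministic
    given the seed.
    """
    layout = build_model(spec, table.design)
    nll, sat = _objective(layout, table)
    rng = np.random.default_rng(seed)
    starts = list(_start_points(layout, rng, restarts))
    if start is not None:
        starts.insert(0, np.asarray(start, dtype=float))
    if extra_starts:
        starts = [np.asarray(s, dtype=float) for s in extra_starts] + starts

    best_x, best_f = None, np.inf
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": tol,
                                         "gtol": 1e-10})
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
            any_converged = bool(res.success) or any_converged
    # polish the winner
    res = optimize.minimize(nll, best_x, method="L-BFGS-B",
                            options={"maxiter": 4000, "ftol": tol / 10,
                                     "gtol": 1e-12})
    if res.fun <= best_f:
        best_x, best_f = res.x, float(res.fun)
        any_converged = bool(res.success) or any_converged

    params = layout.to_natural(best_x)
    g2 = 2.0 * (best_f + sat)
    p = layout.n_free
    df = table.design.degrees_of_freedom - p
    n_total = table.n_total
    return FitResult(
        spec=spec,
        estimates=params,
        free_vector=best_x,
        loglik=-best_f,
        g_squared=g2,
        df=df,
        p_value=float(chi2.sf(max(g2, 0.0), df)) if df > 0 else np.nan,
        aic=g2 + 2 * p,
        bic=g2 + p * np.log(n_total),
        n_restarts_used=len(starts),
        converged=any_converged,
    )


@dataclass
class LRTest:
    """Likelihood-ratio comparison of two nested fits."""

    delta_g2: float
    df: int
    p_value: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def lr_test(full: FitResult, restricted: FitResult,
            tolerance: float = 1e-6) -> LRTest:
    """Chi-square test of a nested restriction.

    delta G^2 = G^2(restricted) - G^2(full) on df equal to the parameter
    difference.  A materially negative delta signals that the restricted
    fit found a better optimum than the full one - refit with more
    restarts rather than report a nonsense test.
    """
    if not is_nested(restricted.spec, full.spec):
        raise ValueError(
            f"{restricted.spec.to_string()} is not nested in {full.spec.to_string()}")
    delta = restricted.g_squared - full.g_squared
    df = full.n_parameters - restricted.n_parameters
    if df <= 0:
        raise ValueError("restricted model must have fewer parameters")
    if delta < -tolerance:
        raise RuntimeError(
            f"restricted fit beat the full fit (delta G^2 = {delta:.4g}); "
            "refit the full model with more restarts")
    delta = max(delta, 0.0)
    return LRTest(delta_g2=delta, df=df, p_value=float(chi2.sf(delta, df)))


def selection_table(specs: Iterable[ModelSpec], table: LineupTable, *,
                    restarts: int = 10, seed: int = 0) -> list[FitResult]:
    """Fit a collection of models and flag the AIC/BIC minima.

    Output ordering is canonical (criterion variant, then discriminability
    variant, then extensions) regardless of input order.  Each result
    gains ``best_aic`` / ``best_bic`` attributes.
    """
    crit_rank = {v: i for i, v in enumerate(("tau1", "tau2", "tau3", "tau4"))}
    disc_rank = {v: i for i, v in enumerate(("null", "mu1", "sigma1", "mu2", "sigma2"))}
    ordered = sorted(set(specs), key=lambda s: (
        crit_rank[s.criterion_variant], disc_rank[s.discriminability_variant],
        s.confidence, s.mixture, tuple(sorted(s.restrictions))))
    results = [fit(s, table, restarts=restarts, seed=seed + i)
               for i, s in enumerate(ordered)]
    aics = np.array([r.aic for r in results])
    bics = np.array([r.bic for r in results])
    for r in results:
        r.best_aic = bool(r.aic == aics.min())
        r.best_bic = bool(r.bic == bics.min())
    return results
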