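"""Gaussian SDT probabilities for censored and uncensored lineup sequences.

The model: the face at sequence position i carries a latent strength drawn
from N(mu_T,i, sigma2_T,i) if it is the target and N(mu_L,i, sigma2_L,i) if
it is a lure, with the lure distributions anchored at mu_L,i = -mu_T,i and
sigma2_L = 1 as the reference.  A "yes" occurs when the strength exceeds the
position's response criterion.  Under the stopping rule the observable is
the first "yes" position (or a full rejection), so the probability of a
"yes" at position i is the product of i-1 sub-criterion terms and one
supra-criterion term.

Criteria may react to an earlier rejection of the target: after the target
was shown (and necessarily rejected) at position h < i, the binary criterion
becomes tau_0,i + delta * exp(lambda * (h - i)), an effect of size delta
that decays geometrically with the lag at rate lambda.  Confidence criteria
are cumulative nonnegative increments kappa over the binary criterion, with
their own post-target-rejection modulation (omega, eta, gamma).  A
two-component mixture adds a fraction 1 - pi of "unserious" respondents who
always pick the first face, with geometrically decaying confidence (zeta).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from .data import ABSENT, Condition, LineupDesign

__all__ = [
    "ParameterSet",
    "effective_criterion",
    "censored_probabilities",
    "probability_matrix",
    "censored_probability_matrix",
    "confidence_criteria",
    "censored_confidence_probabilities",
    "unserious_confidence_pmf",
    "mixture_probabilities",
    "cell_probabilities",
    "d_a",
    "predicted_rocs",
    "uncensored_probabilities",
    "sequence_first_yes",
]


@dataclass
class ParameterSet:
    """All SDT quantities for one lineup model.

    Positional arrays have length I (index 0 = sequence position 1).
    ``kappa`` has shape (I, K-1): nonnegative confidence-criterion
    increments, which guarantees ordered criteria.  Fields beyond the
    binary core default to neutral values so that a plain yes/no model can
    be written compactly.
    """

    mu_T: float
    sigma2_T: float
    tau0: np.ndarray
    alpha: Optional[np.ndarray] = None      # per-position mean factors, alpha[0] = 1
    xi: Optional[np.ndarray] = None         # per-position variance factors, xi[0] = 1
    delta: float = 0.0                      # target-rejection criterion effect
    lambda_: float = 0.0                    # decay of that effect, >= 0
    kappa: Optional[np.ndarray] = None      # (I, K-1) confidence increments, >= 0
    omega: float = 1.0                      # confidence-increment effect, >= 0
    eta: float = 0.0                        # its decay over lag
    gamma: float = 0.0                      # its modulation across confidence levels
    pi_serious: float = 1.0                 # mixture weight of the SDT component
    zeta: float = 1.0                       # unserious confidence decay, > 0

    def __post_init__(self) -> None:
        self.tau0 = np.atleast_1d(np.asarray(self.tau0, dtype=float))
        I = len(self.tau0)
        if self.alpha is None:
            self.alpha = np.ones(I)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.xi is None:
            self.xi = np.ones(I)
        self.xi = np.asarray(self.xi, dtype=float)
        if self.kappa is not None:
            self.kappa = np.asarray(self.kappa, dtype=float)
            if self.kappa.ndim != 2 or self.kappa.shape[0] != I:
                raise ValueError("kappa must have shape (I, K-1)")
            if (self.kappa < 0).any():
                raise ValueError("kappa increments must be nonnegative")
        if self.sigma2_T <= 0:
            raise ValueError("sigma2_T must be positive")
        if (self.xi <= 0).any():
            raise ValueError("xi factors must be positive")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be nonnegative")
        if not 0.0 <= self.pi_serious <= 1.0:
            raise ValueError("pi_serious must be in [0, 1]")

    @property
    def n_positions(self) -> int:
        return len(self.tau0)

    def mu_at(self, i: int, is_target: bool) -> float:
        """Latent-strength mean at 1-based position i."""
        m = self.mu_T * self.alpha[i - 1]
        return m if is_target else -m

    def sigma_at(self, i: int, is_target: bool) -> float:
        var = self.xi[i - 1] * (self.sigma2_T if is_target else 1.0)
        return float(np.sqrt(var))


def effective_criterion(params: ParameterSet, i: int,
                        h: Optional[int] = None) -> float:
    """Binary criterion at position i given a target rejected at position h.

    With no preceding target (h is None) this is tau_0,i.  Otherwise the
    criterion is shifted by delta * exp(lambda * (h - i)); since h < i the
    exponent is negative and the shift decays with the lag.
    """
    base = float(params.tau0[i - 1])
    if h is None:
        return base
    if h >= i:
        raise ValueError(f"target position h={h} must precede i={i} for a shift")
    return base + params.delta * np.exp(params.lambda_ * (h - i))


def _z(params: ParameterSet, i: int, is_target: bool, h: Optional[int]) -> float:
    tau = effective_criterion(params, i, h)
    return (tau - params.mu_at(i, is_target)) / params.sigma_at(i, is_target)


def _condition_zs(params: ParameterSet, I: int, condition: Condition) -> np.ndarray:
    """Standardized criterion positions for each sequence position."""
    target_at = None if condition in (ABSENT, "ta") else int(condition)
    zs = np.empty(I)
    for i in range(1, I + 1):
        is_target = target_at == i
        h = target_at if (target_at is not None and target_at < i) else None
        zs[i - 1] = _z(params, i, is_target, h)
    return zs


def censored_probabilities(params: ParameterSet, design: LineupDesign,
                           condition: Condition) -> np.ndarray:
    """Category probabilities for binary censored responses.

    Returns a vector of length I + 1: P(first "yes" at position 1..I)
    followed by P(reject all).  Computed in log space so extreme criteria
    do not underflow.
    """
    I = design.sequence_length
    zs = _condition_zs(params, I, condition)
    log_no = log_ndtr(zs)                       # log P("no") per position
    log_yes = norm.logsf(zs)                    # log P("yes") per position
    cum = np.concatenate([[0.0], np.cumsum(log_no)])
    out = np.empty(I + 1)
    out[:I] = np.exp(cum[:I] + log_yes)
    out[I] = np.exp(cum[I])
    return out


def _binary_z_matrix(params: ParameterSet, design: LineupDesign):
    """Standardized binary criteria, means and SDs for all (position, condition).

    Conditions are target at 1..I followed by target-absent.  Also returns
    the boolean 'shifted' mask (target previously rejected) used by the
    confidence extension.
    """
    I = design.sequence_length
    pos = np.arange(1, I + 1)[:, None]
    cond = np.arange(1, I + 2)[None, :]
    is_target = (pos == cond) & (cond <= I)
    mu = np.where(is_target, params.mu_T * params.alpha[:, None],
                  -params.mu_T * params.alpha[:, None])
    sd = np.sqrt(np.where(is_target, params.sigma2_T, 1.0) * params.xi[:, None])
    shifted = (cond < pos) & (cond <= I)
    lag = np.where(shifted, cond - pos, 0)      # nonpositive where it matters
    tau = params.tau0[:, None] + np.where(
        shifted, params.delta * np.exp(params.lambda_ * lag), 0.0)
    return tau, mu, sd, shifted, lag


def probability_matrix(params: ParameterSet, design: LineupDesign,
                       mixture: bool = False) -> np.ndarray:
    """All category probabilities at once, laid out like LineupTable.counts.

    Vectorized equivalent of stacking ``cell_probabilities`` over the
    conditions (target at 1..I, then absent); the workhorse inside
    optimization loops.
    """
    I, K = design.sequence_length, design.confidence_bins
    tau, mu, sd, shifted, lag = _binary_z_matrix(params, design)
    z = (tau - mu) / sd
    log_no = log_ndtr(z)
    cum = np.vstack([np.zeros((1, I + 1)), np.cumsum(log_no, axis=0)])
    if K == 1:
        out = np.empty((I + 1, I + 1))
        out[:I] = np.exp(cum[:I] + log_ndtr(-z))
        out[I] = np.exp(cum[I])
    else:
        if params.kappa is None:
            raise ValueError("confidence design requires kappa increments")
        m = np.arange(1, K)
        scale = np.where(shifted[:, :, None],
                         (params.omega * np.exp(params.eta * lag))[:, :, None]
                         * np.exp(-params.gamma * m)[None, None, :],
                         1.0)
        incr = params.kappa[:, None, :] * scale
        crit = tau[:, :, None] + np.concatenate(
            [np.zeros((I, I + 1, 1)), np.cumsum(incr, axis=2)], axis=2)
        zc = (crit - mu[:, :, None]) / sd[:, :, None]
        upper = ndtr(zc)
        mass = np.empty((I, I + 1, K))
        mass[:, :, :-1] = np.diff(upper, axis=2)
        mass[:, :, -1] = norm.sf(zc[:, :, -1])
        mass = np.maximum(mass, 0.0) * np.exp(cum[:I])[:, :, None]
        out = np.empty((I * K + 1, I + 1))
        out[:I * K] = mass.transpose(0, 2, 1).reshape(I * K, I + 1)
        out[I * K] = np.exp(cum[I])
    if mixture:
        contaminant = np.zeros(out.shape[0])
        if K == 1:
            contaminant[0] = 1.0
        else:
            contaminant[:K] = unserious_confidence_pmf(params.zeta, K)
        out = params.pi_serious * out + (1 - params.pi_serious) * contaminant[:, None]
    return out


def censored_probability_matrix(params: ParameterSet,
                                design: LineupDesign) -> np.ndarray:
    """Binary (K=1) probability matrix; see ``probability_matrix``."""
    if design.confidence_bins != 1:
        raise ValueError("censored_probability_matrix expects K = 1")
    return probability_matrix(params, design)


def confidence_criteria(params: ParameterSet, i: int,
                        h: Optional[int] = None) -> np.ndarray:
    """Ordered criterion vector (tau_0 .. tau_{K-1}) at position i.

    Before the target (or in its absence) the confidence criteria are
    cumulative sums of the kappa increments over tau_0,i.  After a target
    rejection at h < i, the base criterion shifts by the binary kernel and
    each increment is rescaled by omega * exp(eta*(h-i)) * exp(-gamma*m).
    """
    if params.kappa is None:
        raise ValueError("ParameterSet has no confidence increments (kappa)")
    base = effective_criterion(params, i, h)
    inc = params.kappa[i - 1].astype(float)
    if h is not None:
        m = np.arange(1, len(inc) + 1)
        rho = params.omega * np.exp(params.eta * (h - i))
        inc = inc * rho * np.exp(-params.gamma * m)
    return base + np.concatenate([[0.0], np.cumsum(inc)])


def censored_confidence_probabilities(params: ParameterSet, design: LineupDesign,
                                      condition: Condition) -> np.ndarray:
    """Category probabilities with the "yes" mass split over K confidence bins.

    Output ordering matches LineupTable: for each position the K bins run
    low -> high confidence, followed by the single "reject" cell.
    Marginalizing the bins recovers ``censored_probabilities`` exactly.
    """
    I, K = design.sequence_length, design.confidence_bins
    if K < 2:
        raise ValueError("use censored_probabilities for a binary design")
    target_at = None if condition in (ABSENT, "ta") else int(condition)
    zs = _condition_zs(params, I, condition)
    log_no = log_ndtr(zs)
    cum = np.concatenate([[0.0], np.cumsum(log_no)])
    out = np.empty(I * K + 1)
    for i in range(1, I + 1):
        is_target = target_at == i
        h = target_at if (target_at is not None and target_at < i) else None
        crit = confidence_criteria(params, i, h)
        zc = (crit - params.mu_at(i, is_target)) / params.sigma_at(i, is_target)
        upper = ndtr(zc)                        # Phi at each criterion
        # bin k = 1..K-1: Phi(tau_k) - Phi(tau_{k-1}); top bin: 1 - Phi(tau_{K-1})
        mass = np.empty(K)
        mass[:-1] = np.diff(upper)
        mass[-1] = norm.sf(zc[-1])
        out[(i - 1) * K: i * K] = np.maximum(mass, 0.0) * np.exp(cum[i - 1])
    out[-1] = np.exp(cum[I])
    return out


def unserious_confidence_pmf(zeta: float, K: int) -> np.ndarray:
    """Confidence distribution of an always-choose-first respondent.

    P(k | yes, unserious) = exp(-zeta*k) / sum_k' exp(-zeta*k'), k = 1..K
    (k = 1 is the lowest confidence level).  zeta -> 0 gives the uniform
    distribution.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if zeta < 0:
        raise ValueError("zeta must be nonnegative")
    k = np.arange(1, K + 1)
    w = np.exp(-zeta * (k - 1))     # shift-invariant; avoids underflow for large zeta
    return w / w.sum()


def mixture_probabilities(params: ParameterSet, design: LineupDesign,
                          condition: Condition) -> np.ndarray:
    """Two-component mixture: serious SDT witnesses plus first-face choosers.

    With probability pi_serious the response follows the base SDT model;
    otherwise the first face is always chosen, with confidence spread by
    ``unserious_confidence_pmf``.
    """
    K = design.confidence_bins
    if K == 1:
        base = censored_probabilities(params, design, condition)
        contaminant = np.zeros_like(base)
        contaminant[0] = 1.0
    else:
        base = censored_confidence_probabilities(params, design, condition)
        contaminant = np.zeros_like(base)
        contaminant[:K] = unserious_confidence_pmf(params.zeta, K)
    pi = params.pi_serious
    return pi * base + (1.0 - pi) * contaminant


def cell_probabilities(params: ParameterSet, design: LineupDesign,
                       condition: Condition, mixture: bool = False) -> np.ndarray:
    """Dispatch to the appropriate probability rule for a design."""
    if mixture:
        return mixture_probabilities(params, design, condition)
    if design.confidence_bins == 1:
        return censored_probabilities(params, design, condition)
    return censored_confidence_probabilities(params, design, condition)


def d_a(params: ParameterSet, i: int = 1) -> float:
    """Unequal-variance discriminability at position i.

    d_a = (mu_T,i - mu_L,i) / sqrt((sigma2_T,i + sigma2_L,i) / 2), the
    distance between the target and lure distributions in root-mean-square
    SD units.
    """
    num = 2.0 * params.mu_T * params.alpha[i - 1]
    den = np.sqrt(params.xi[i - 1] * (params.sigma2_T + 1.0) / 2.0)
    return float(num / den)


def predicted_rocs(params: ParameterSet,
                   design: LineupDesign) -> dict[int, np.ndarray]:
    """Per-target-position confidence-rating ROC point sets.

    For target position h, sweeps the confidence criteria at position h from
    the strictest down: point c pairs the cumulative "yes at h with
    confidence >= c" probability in the target-at-h condition (hit) with the
    same cumulative cell mass in the target-absent condition (false alarm).
    Returns {h: array of (FA, hit) rows, strictest first}.
    """
    I, K = design.sequence_length, design.confidence_bins
    if K < 2:
        raise ValueError("ROCs require a confidence design (K >= 2)")
    ta = censored_confidence_probabilities(params, design, ABSENT)
    rocs: dict[int, np.ndarray] = {}
    for h in range(1, I + 1):
        tp = censored_confidence_probabilities(params, design, h)
        tp_bins = tp[(h - 1) * K: h * K]
        ta_bins = ta[(h - 1) * K: h * K]
        hit = np.cumsum(tp_bins[::-1])
        fa = np.cumsum(ta_bins[::-1])
        rocs[h] = np.column_stack([fa, hit])
    return rocs


# ---------------------------------------------------------------------------
# Uncensored sequences (no stopping rule)

def sequence_first_yes(seq_index: int, I: int) -> Optional[int]:
    """First "yes" position (1-based) of an encoded sequence, or None.

    Sequences over I yes/no responses are encoded as integers with bit j
    (0-based) set when position j+1 received a "yes".
    """
    for i in range(I):
        if seq_index >> i & 1:
            return i + 1
    return None


def uncensored_probabilities(pre: ParameterSet, post: ParameterSet,
                             design: LineupDesign,
                             condition: Condition) -> np.ndarray:
    """Probabilities of all 2^I full response sequences.

    Responses up to and including the first "yes" follow the ``pre``
    parameters; all later responses follow ``post`` (the parameters may
    coincide).  Within each regime the target-rejection criterion kernel
    applies whenever the target was shown earlier and received a "no".
    Marginalizing to the first-"yes" position reproduces
    ``censored_probabilities(pre, ...)`` exactly.
    """
    I = design.sequence_length
    if design.confidence_bins != 1:
        raise ValueError("uncensored sequences are modeled for binary judgments")
    target_at = None if condition in (ABSENT, "ta") else int(condition)
    out = np.empty(2 ** I)
    for s in range(2 ** I):
        responses = [(s >> i) & 1 for i in range(I)]   # 1 = yes at position i+1
        logp = 0.0
        seen_yes = False
        target_rejected = False
        for i in range(1, I + 1):
            p = post if seen_yes else pre
            is_target = target_at == i
            h = target_at if target_rejected else None
            z = _z(p, i, is_target, h)
            if responses[i - 1]:
                logp += norm.logsf(z)
                seen_yes = True
            else:
                logp += log_ndtr(z)
                if is_target:
                    target_rejected = True
        out[s] = np.exp(logp)
    return out
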