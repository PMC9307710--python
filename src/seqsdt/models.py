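"""The factorial model family and its parameter layouts.

Twenty binary models arise from crossing four criterion hypotheses with
five discriminability hypotheses:

* ``tau1`` - one criterion for all positions and sequences;
* ``tau2`` - a free criterion per sequence position;
* ``tau3`` - one base criterion plus the target-rejection shift kernel
  (delta, lambda);
* ``tau4`` - free per-position criteria plus the shift kernel;

* ``null``   - fixed discriminability;
* ``mu1``    - a single symmetric mean factor alpha applied from position 2 on;
* ``sigma1`` - a single common variance factor xi from position 2 on;
* ``mu2`` / ``sigma2`` - the unrestricted variants, one factor per position
  2..I.

Optional extensions add ordered confidence criteria (kappa increments plus
the omega/eta/gamma post-target modulation) and the serious/unserious
mixture (pi, zeta).  Named restrictions remove or reparameterize blocks;
each restricted model is nested in its parent.

A layout maps between an unconstrained free vector (what the optimizer
sees) and a natural ParameterSet: positivity via log transforms, criterion
ordering via cumulative nonnegative increments, the mixture weight via a
logistic transform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, logit

from .core import ParameterSet
from .data import LineupDesign

__all__ = ["ModelSpec", "ParameterLayout", "build_model", "parameter_count"]

CRITERION_VARIANTS = ("tau1", "tau2", "tau3", "tau4")
DISCRIMINABILITY_VARIANTS = ("null", "mu1", "sigma1", "mu2", "sigma2")
RESTRICTIONS = (
    "fixed_tau0",
    "monotone_increasing_tau0",
    "monotone_decreasing_tau0",
    "lambda_zero",
    "equal_variance",
    "omega_eta_gamma_fixed",
    "shared_kappa_across_positions",
)


@dataclass(frozen=True)
class ModelSpec:
    """A point in the factorial family, plus optional extensions/restrictions."""

    criterion_variant: str = "tau4"
    discriminability_variant: str = "null"
    confidence: bool = False
    mixture: bool = False
    restrictions: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.criterion_variant not in CRITERION_VARIANTS:
            raise ValueError(f"unknown criterion variant {self.criterion_variant!r}")
        if self.discriminability_variant not in DISCRIMINABILITY_VARIANTS:
            raise ValueError(
                f"unknown discriminability variant {self.discriminability_variant!r}")
        object.__setattr__(self, "restrictions", frozenset(self.restrictions))
        unknown = self.restrictions - set(RESTRICTIONS)
        if unknown:
            raise ValueError(f"unknown restrictions {sorted(unknown)}")
        r = self.restrictions
        varying = self.criterion_variant in ("tau2", "tau4")
        for mono in ("monotone_increasing_tau0", "monotone_decreasing_tau0",
                     "fixed_tau0"):
            if mono in r and not varying:
                raise ValueError(f"{mono} requires tau2 or tau4 (varying criteria)")
        if ("monotone_increasing_tau0" in r and "monotone_decreasing_tau0" in r):
            raise ValueError("monotone increasing and decreasing are incompatible")
        if "fixed_tau0" in r and (r & {"monotone_increasing_tau0",
                                       "monotone_decreasing_tau0"}):
            raise ValueError("fixed_tau0 is incompatible with monotone restrictions")
        if "lambda_zero" in r and self.criterion_variant in ("tau1", "tau2"):
            raise ValueError("lambda_zero requires a shift kernel (tau3 or tau4)")
        for conf_r in ("omega_eta_gamma_fixed", "shared_kappa_across_positions"):
            if conf_r in r and not self.confidence:
                raise ValueError(f"{conf_r} requires a confidence model")

    @property
    def has_shift_kernel(self) -> bool:
        return self.criterion_variant in ("tau3", "tau4")

    # -- compact string form: "tau4+mu1[K=4][mixture][restr:lambda_zero]" ----

    def to_string(self) -> str:
        s = f"{self.criterion_variant}+{self.discriminability_variant}"
        if self.confidence:
            s += "[confidence]"
        if self.mixture:
            s += "[mixture]"
        if self.restrictions:
            s += f"[restr:{','.join(sorted(self.restrictions))}]"
        return s

    @classmethod
    def from_string(cls, text: str) -> "ModelSpec":
        m = re.fullmatch(r"(\w+)\+(\w+)((?:\[[^\]]*\])*)", text.strip())
        if not m:
            raise ValueError(f"cannot parse model string {text!r}")
        crit, disc, opts = m.groups()
        confidence = mixture = False
        restrictions: set[str] = set()
        for opt in re.findall(r"\[([^\]]*)\]", opts):
            if opt == "confidence" or re.fullmatch(r"K=\d+", opt):
                confidence = True
            elif opt == "mixture":
                mixture = True
            elif opt.startswith("restr:"):
                restrictions.update(x for x in opt[6:].split(",") if x)
            else:
                raise ValueError(f"unknown model option [{opt}]")
        return cls(crit, disc, confidence, mixture, frozenset(restrictions))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_string()


@dataclass
class ParameterLayout:
    """Ordered free parameters of a model and the free<->natural transforms."""

    spec: ModelSpec
    design: LineupDesign
    names: list[str]

    @property
    def n_free(self) -> int:
        return len(self.names)

    # The assembly below is the single source of truth for which quantities
    # are free; `names` is built alongside in build_model.

    def to_natural(self, x: np.ndarray) -> ParameterSet:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_free,):
            raise ValueError(f"free vector length {x.shape} != {self.n_free}")
        spec, design = self.spec, self.design
        I, K = design.sequence_length, design.confidence_bins
        r = spec.restrictions
        pos = 0

        def take(n: int) -> np.ndarray:
            nonlocal pos
            out = x[pos: pos + n]
            pos += n
            return out

        def take_exp(n: int, hi: float = 50.0) -> np.ndarray:
            # clip on the log scale so wild optimizer excursions stay finite
            return np.exp(np.clip(take(n), -700.0, hi))

        mu_T = float(take(1)[0])
        sigma2_T = 1.0 if "equal_variance" in r else float(take_exp(1)[0])

        if spec.criterion_variant in ("tau1", "tau3") or "fixed_tau0" in r:
            tau0 = np.full(I, float(take(1)[0]))
        elif "monotone_increasing_tau0" in r:
            base = float(take(1)[0])
            tau0 = base + np.concatenate([[0.0], np.cumsum(take_exp(I - 1))])
        elif "monotone_decreasing_tau0" in r:
            base = float(take(1)[0])
            tau0 = base - np.concatenate([[0.0], np.cumsum(take_exp(I - 1))])
        else:
            tau0 = take(I).copy()

        delta, lambda_ = 0.0, 0.0
        if spec.has_shift_kernel:
            delta = float(take(1)[0])
            lambda_ = 0.0 if "lambda_zero" in r else float(take_exp(1)[0])

        alpha = np.ones(I)
        if spec.discriminability_variant == "mu1":
            alpha[1:] = take_exp(1)[0]
        elif spec.discriminability_variant == "mu2":
            alpha[1:] = take_exp(I - 1)
        xi = np.ones(I)
        if spec.discriminability_variant == "sigma1":
            xi[1:] = take_exp(1)[0]
        elif spec.discriminability_variant == "sigma2":
            xi[1:] = take_exp(I - 1)

        kappa = None
        omega, eta, gamma = 1.0, 0.0, 0.0
        if spec.confidence:
            if K < 2:
                raise ValueError("confidence model requires a design with K >= 2")
            if "shared_kappa_across_positions" in r:
                row = take_exp(K - 1)
                kappa = np.tile(row, (I, 1))
            else:
                kappa = take_exp(I * (K - 1)).reshape(I, K - 1)
            if spec.has_shift_kernel and "omega_eta_gamma_fixed" not in r:
                omega = float(take_exp(1)[0])
                eta = float(take(1)[0])
                gamma = float(take(1)[0])

        pi_serious, zeta = 1.0, 1.0
        if spec.mixture:
            pi_serious = float(expit(take(1)[0]))
            zeta = float(take_exp(1)[0])

        assert pos == self.n_free
        return ParameterSet(mu_T=mu_T, sigma2_T=sigma2_T, tau0=tau0,
                            alpha=alpha, xi=xi, delta=delta, lambda_=lambda_,
                            kappa=kappa, omega=omega, eta=eta, gamma=gamma,
                            pi_serious=pi_serious, zeta=zeta)

    def from_natural(self, params: ParameterSet) -> np.ndarray:
        spec, design = self.spec, self.design
        I, K = design.sequence_length, design.confidence_bins
        r = spec.restrictions
        parts: list[float] = []
        parts.append(params.mu_T)
        if "equal_variance" not in r:
            parts.append(np.log(params.sigma2_T))
        if spec.criterion_variant in ("tau1", "tau3") or "fixed_tau0" in r:
            parts.append(params.tau0[0])
        elif "monotone_increasing_tau0" in r:
            parts.append(params.tau0[0])
            parts.extend(np.log(np.diff(params.tau0)))
        elif "monotone_decreasing_tau0" in r:
            parts.append(params.tau0[0])
            parts.extend(np.log(-np.diff(params.tau0)))
        else:
            parts.extend(params.tau0)
        if spec.has_shift_kernel:
            parts.append(params.delta)
            if "lambda_zero" not in r:
                parts.append(np.log(params.lambda_))
        if spec.discriminability_variant == "mu1":
            parts.append(np.log(params.alpha[1]))
        elif spec.discriminability_variant == "mu2":
            parts.extend(np.log(params.alpha[1:]))
        if spec.discriminability_variant == "sigma1":
            parts.append(np.log(params.xi[1]))
        elif spec.discriminability_variant == "sigma2":
            parts.extend(np.log(params.xi[1:]))
        if spec.confidence:
            if "shared_kappa_across_positions" in r:
                parts.extend(np.log(params.kappa[0]))
            else:
                parts.extend(np.log(params.kappa).ravel())
            if spec.has_shift_kernel and "omega_eta_gamma_fixed" not in r:
                parts.extend([np.log(params.omega), params.eta, params.gamma])
        if spec.mixture:
            parts.extend([logit(params.pi_serious), np.log(params.zeta)])
        vec = np.asarray(parts, dtype=float)
        assert vec.shape == (self.n_free,)
        return vec


def build_model(spec: ModelSpec, design: LineupDesign) -> ParameterLayout:
    """Enumerate the free parameters of a model on a design."""
    I, K = design.sequence_length, design.confidence_bins
    if spec.confidence and K < 2:
        raise ValueError("confidence model requires K >= 2 in the design")
    if not spec.confidence and K > 1:
        raise ValueError("binary model on a confidence design: collapse bins first")
    r = spec.restrictions
    names = ["mu_T"]
    if "equal_variance" not in r:
        names.append("log_sigma2_T")
    if spec.criterion_variant in ("tau1", "tau3") or "fixed_tau0" in r:
        names.append("tau0")
    elif r & {"monotone_increasing_tau0", "monotone_decreasing_tau0"}:
        names.append("tau0_1")
        names.extend(f"log_dtau0_{i}" for i in range(2, I + 1))
    else:
        names.extend(f"tau0_{i}" for i in range(1, I + 1))
    if spec.has_shift_kernel:
        names.append("delta")
        if "lambda_zero" not in r:
            names.append("log_lambda")
    if spec.discriminability_variant == "mu1":
        names.append("log_alpha")
    elif spec.discriminability_variant == "mu2":
        names.extend(f"log_alpha_{i}" for i in range(2, I + 1))
    elif spec.discriminability_variant == "sigma1":
        names.append("log_xi")
    elif spec.discriminability_variant == "sigma2":
        names.extend(f"log_xi_{i}" for i in range(2, I + 1))
    if spec.confidence:
        if "shared_kappa_across_positions" in r:
            names.extend(f"log_kappa_{m}" for m in range(1, K))
        else:
            names.extend(f"log_kappa_{m}_{i}"
                         for i in range(1, I + 1) for m in range(1, K))
        if spec.has_shift_kernel and "omega_eta_gamma_fixed" not in r:
            names.extend(["log_omega", "eta", "gamma"])
    if spec.mixture:
        names.extend(["logit_pi", "log_zeta"])
    return ParameterLayout(spec=spec, design=design, names=names)


def parameter_count(spec: ModelSpec, design: LineupDesign,
                    paper_count_mode: bool = False) -> int:
    """Number of free parameters of a model.

    ``paper_count_mode`` subtracts one parameter for confidence models with
    a shift kernel, matching a published count of 6*(K-1)+3 additional
    parameters over a 10-parameter binary base that tallies to one fewer
    than this layout enumerates; the default reports the layout's own count.
    """
    n = build_model(spec, design).n_free
    if paper_count_mode and spec.confidence and spec.has_shift_kernel \
            and "omega_eta_gamma_fixed" not in spec.restrictions:
        n -= 1
    return n


def is_nested(restricted: ModelSpec, full: ModelSpec) -> bool:
    """True when every ParameterSet of `restricted` is reachable in `full`.

    Captures the documented nesting relations: the criterion chain
    tau1 < tau2 < tau4 and tau1 < tau3 < tau4, the discriminability chains
    null < mu1 < mu2 and null < sigma1 < sigma2, added restrictions, and a
    dropped mixture component.
    """
    crit_order = {"tau1": {"tau1", "tau2", "tau3", "tau4"},
                  "tau2": {"tau2", "tau4"},
                  "tau3": {"tau3", "tau4"},
                  "tau4": {"tau4"}}
    disc_order = {"null": {"null", "mu1", "sigma1", "mu2", "sigma2"},
                  "mu1": {"mu1", "mu2"},
                  "sigma1": {"sigma1", "sigma2"},
                  "mu2": {"mu2"},
                  "sigma2": {"sigma2"}}
    if full.criterion_variant not in crit_order[restricted.criterion_variant]:
        return False
    if full.discriminability_variant not in disc_order[restricted.discriminability_variant]:
        return False
    if restricted.confidence != full.confidence:
        return False
    if restricted.mixture and not full.mixture:
        return False
    # every restriction of the full model must also bind the restricted one
    monotone = {"monotone_increasing_tau0", "monotone_decreasing_tau0"}
    if not (full.restrictions - monotone) <= restricted.restrictions:
        return False
    if full.restrictions & monotone and not (
            restricted.restrictions & (monotone | {"fixed_tau0"})
            or restricted.criterion_variant in ("tau1", "tau3")):
        return False
    return True
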