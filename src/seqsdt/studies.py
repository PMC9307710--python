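"""Re-runnable simulation studies and uncensored-sequence diagnostics.

Every study is a pure function of its configuration and a single seed, and
returns a :class:`StudyResult` carrying the full replicate-level record so
that summaries can be recomputed.  The default generating parameters are
the published confidence-fit estimates for the best-performing model on
the pooled no-stopping-rule dataset (binary part): they define realistic
discriminability, criterion placement, and target-rejection effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import chi2, norm, spearmanr

from .core import ParameterSet, d_a
from .data import ABSENT, LineupDesign, LineupTable, hazard_differences
from .fitting import _objective, fit
from .models import ModelSpec, build_model
from .synthetic import PopulationSpec, simulate_population, simulate_table

__all__ = [
    "StudyResult",
    "reference_tau4_null",
    "reference_tau4_mu1",
    "WILSON_N_PER_CONDITION",
    "dfd_power_study",
    "da_recovery_study",
    "group_difference_study",
    "selection_bias_study",
    "simulation_population_specs",
    "iid_position_test",
    "prepost_binary_sdt",
]

#: Condition sample sizes of the pooled no-stopping-rule study
#: (target at 1..6, then target-absent).
WILSON_N_PER_CONDITION = {1: 709, 2: 696, 3: 691, 4: 699, 5: 696, 6: 701,
                          "ta": 4151}


def reference_tau4_null(kappa: Optional[float] = None, K: int = 4) -> ParameterSet:
    """Confidence-fit estimates of the free-criteria shift-kernel model.

    Binary part: mu_T = 0.77, sigma2_T = 0.51, per-position criteria, a
    target-rejection effect delta = 1.04 decaying at lambda = 0.49.  When
    ``kappa`` is given, equal confidence increments of that size are added
    for K levels together with the published omega/eta/gamma values (the
    increments themselves were not published; equal spacing is a package
    default).
    """
    kw = {}
    if kappa is not None:
        kw = dict(kappa=np.full((6, K - 1), kappa),
                  omega=1.44, eta=-0.03, gamma=0.12)
    return ParameterSet(mu_T=0.77, sigma2_T=0.51,
                        tau0=[0.13, 0.22, 0.08, 0.05, 0.20, 0.25],
                        delta=1.04, lambda_=0.49, **kw)


def reference_tau4_mu1(alpha: float = 1.02, kappa: Optional[float] = None,
                       K: int = 4) -> ParameterSet:
    """Confidence-fit estimates of the restricted mean-shift variant.

    ``alpha`` scales the target/lure means from position 2 on (the
    published estimate is 1.02; power studies override it with the effect
    size under test).
    """
    a = np.ones(6)
    a[1:] = alpha
    kw = {}
    if kappa is not None:
        kw = dict(kappa=np.full((6, K - 1), kappa),
                  omega=1.37, eta=-0.04, gamma=0.11)
    return ParameterSet(mu_T=0.76, sigma2_T=0.51,
                        tau0=[0.13, 0.21, 0.08, 0.05, 0.20, 0.25],
                        delta=1.05, lambda_=0.49, alpha=a, **kw)


@dataclass
class StudyResult:
    """Replicate-level record plus summary of one simulation study."""

    study: str
    scenarios: list
    replicates: dict            # scenario -> list of per-replicate records
    summary: dict               # scenario -> summary statistics
    reps: int
    seed: int

    def __post_init__(self) -> None:
        if self.reps <= 0:
            raise ValueError("reps must be positive")


def _rep_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Statistical power for position effects on discriminability

def dfd_power_study(alpha_values: Sequence[float] = (1.0, 1.10, 1.50),
                    reps: int = 200,
                    n_per_condition=None,
                    seed: int = 0,
                    response_mode: str = "binary",
                    restarts: int = 3,
                    kappa: float = 0.35) -> StudyResult:
    """Power to detect a discriminability increase from position 2 on.

    For each effect size alpha: simulate data from the mean-shift model
    with that alpha, fit both the null (fixed discriminability) and the
    mean-shift model, and record delta G^2 with its chi-square(1) p-value.
    ``response_mode`` chooses binary tables or K=4 confidence tables (the
    latter use the package's default equal confidence increments).
    """
    if response_mode not in ("binary", "confidence"):
        raise ValueError("response_mode must be 'binary' or 'confidence'")
    if n_per_condition is None:
        n_per_condition = dict(WILSON_N_PER_CONDITION)
    confidence = response_mode == "confidence"
    design = LineupDesign(6, 4 if confidence else 1)
    null_spec = ModelSpec("tau4", "null", confidence=confidence)
    alt_spec = ModelSpec("tau4", "mu1", confidence=confidence)
    replicates: dict = {}
    summary: dict = {}
    for alpha in alpha_values:
        gen = reference_tau4_mu1(alpha=alpha, kappa=kappa if confidence else None)
        recs = []
        for rep_seed in _rep_seeds(seed + int(round(alpha * 1000)), reps):
            table = simulate_table(gen, alt_spec, design, n_per_condition,
                                   seed=rep_seed)
            f0 = fit(null_spec, table, restarts=restarts, seed=rep_seed)
            # the mean-shift layout inserts log_alpha after the 10 binary
            # parameters, so the null solution with log_alpha = 0 is a valid start
            f1 = fit(alt_spec, table, restarts=restarts, seed=rep_seed + 1,
                     extra_starts=[np.insert(f0.free_vector, 10, 0.0)])
            delta = max(f0.g_squared - f1.g_squared, 0.0)
            recs.append({"delta_g2": delta,
                         "p": float(chi2.sf(delta, 1))})
        replicates[alpha] = recs
        ps = np.array([r["p"] for r in recs])
        summary[alpha] = {"pct_significant": 100.0 * float((ps < 0.05).mean()),
                          "mean_delta_g2": float(np.mean([r["delta_g2"] for r in recs]))}
    return StudyResult("dfd_power", list(alpha_values), replicates, summary,
                       reps, seed)


# ---------------------------------------------------------------------------
# d_a recovery from binary tables

def da_recovery_study(mu_range: tuple = (0.2, 1.40),
                      sigma2_range: tuple = (0.3, 1.2),
                      reps: int = 200,
                      n_per_condition: int = 1000,
                      seed: int = 0,
                      restarts: int = 3) -> StudyResult:
    """Recovery of discriminability (d_a) from binary censored tables.

    Each replicate draws its own (mu_T, sigma2_T) uniformly, keeps the
    remaining generating parameters at the reference estimates, simulates
    a binary table, refits the free-criteria shift-kernel model, and pairs
    the true with the estimated d_a.  Summary: Spearman rank correlation.
    """
    design = LineupDesign(6, 1)
    spec = ModelSpec("tau4", "null")
    base = reference_tau4_null()
    recs = []
    for rep_seed in _rep_seeds(seed, reps):
        rng = np.random.default_rng(rep_seed)
        mu = rng.uniform(*mu_range)
        s2 = rng.uniform(*sigma2_range)
        gen = ParameterSet(mu_T=mu, sigma2_T=s2, tau0=base.tau0.copy(),
                           delta=base.delta, lambda_=base.lambda_)
        table = simulate_table(gen, spec, design, n_per_condition, seed=rep_seed)
        f = fit(spec, table, restarts=restarts, seed=rep_seed)
        recs.append({"true_da": d_a(gen), "est_da": d_a(f.estimates),
                     "g_squared": f.g_squared})
    true = [r["true_da"] for r in recs]
    est = [r["est_da"] for r in recs]
    rho = float(spearmanr(true, est).statistic)
    return StudyResult("da_recovery", ["default"], {"default": recs},
                       {"default": {"rank_correlation": rho,
                                    "n_per_condition": n_per_condition}},
                       reps, seed)


# ---------------------------------------------------------------------------
# Two-group hypothesis identification

GROUP_SCENARIOS = ("none", "discriminability", "criteria_plus",
                   "criteria_minus", "both_plus", "both_minus")


def _scenario_params(scenario: str) -> tuple[ParameterSet, ParameterSet]:
    a = reference_tau4_null()
    mu_B = a.mu_T
    tau_B = a.tau0.copy()
    if scenario in ("discriminability", "both_plus", "both_minus"):
        mu_B = a.mu_T * 0.9
    if scenario in ("criteria_plus", "both_plus"):
        tau_B = a.tau0 - 0.20        # more lenient
    if scenario in ("criteria_minus", "both_minus"):
        tau_B = a.tau0 + 0.20        # stricter
    b = ParameterSet(mu_T=mu_B, sigma2_T=a.sigma2_T, tau0=tau_B,
                     delta=a.delta, lambda_=a.lambda_)
    return a, b


def fit_two_groups(table_a: LineupTable, table_b: LineupTable, *,
                   share_discriminability: bool = False,
                   share_criteria: bool = False,
                   restarts: int = 2, seed: int = 0,
                   extra_starts: Optional[Sequence[np.ndarray]] = None):
    """Joint ML fit of the free-criteria shift-kernel model to two groups.

    Blocks of the 10-parameter layout (mu_T, log sigma2_T | tau0 x 6,
    delta, log lambda) can be shared across groups.  Returns
    (g_squared, n_parameters, free_vector).
    """
    spec = ModelSpec("tau4", "null")
    layout = build_model(spec, table_a.design)
    disc_idx = np.array([0, 1])
    crit_idx = np.arange(2, 10)
    nll_a, sat_a = _objective(layout, table_a)
    nll_b, sat_b = _objective(layout, table_b)

    b_free_blocks = []
    if not share_discriminability:
        b_free_blocks.append(disc_idx)
    if not share_criteria:
        b_free_blocks.append(crit_idx)
    b_free = np.concatenate(b_free_blocks) if b_free_blocks else np.array([], int)
    n_params = 10 + len(b_free)

    def split(x: np.ndarray):
        xa = x[:10]
        xb = xa.copy()
        if len(b_free):
            xb[b_free] = x[10:]
        return xa, xb

    def nll(x: np.ndarray) -> float:
        xa, xb = split(x)
        return nll_a(xa) + nll_b(xb)

    rng = np.random.default_rng(seed)
    starts = []
    if extra_starts:
        starts.extend(np.asarray(s, float) for s in extra_starts)
    from .fitting import _start_points
    for s in _start_points(layout, rng, restarts):
        starts.append(np.concatenate([s, s[b_free]]))
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"maxiter": 3000, "ftol": 1e-11})
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    g2 = 2.0 * (best_f + sat_a + sat_b)
    return g2, n_params, best_x


def group_difference_study(scenarios: Sequence[str] = GROUP_SCENARIOS,
                           reps: int = 200,
                           n_per_condition: int = 500,
                           seed: int = 0,
                           restarts: int = 2) -> StudyResult:
    """Identify whether two groups differ in discriminability, criteria, or both.

    Group A uses the reference parameters; group B's mu_T is reduced by 10%
    and/or its criteria shifted by -/+ 0.20 (lenient/strict) depending on
    the scenario.  Per replicate, the fully free two-group model is
    compared by likelihood ratio against the model equating
    discriminability (df = 2) and the model equating criteria including the
    shift kernel (df = 8); the summary reports rejection percentages of
    each equality hypothesis at p < .05.
    """
    unknown = set(scenarios) - set(GROUP_SCENARIOS)
    if unknown:
        raise ValueError(f"unknown scenarios {sorted(unknown)}")
    if not scenarios:
        raise ValueError("scenarios must be nonempty")
    design = LineupDesign(6, 1)
    spec = ModelSpec("tau4", "null")
    replicates: dict = {}
    summary: dict = {}
    for si, scenario in enumerate(scenarios):
        pa, pb = _scenario_params(scenario)
        recs = []
        for rep_seed in _rep_seeds(seed + si * 1_000_003, reps):
            ta = simulate_table(pa, spec, design, n_per_condition, seed=rep_seed)
            tb = simulate_table(pb, spec, design, n_per_condition,
                                seed=rep_seed + 1)
            fa = fit(spec, ta, restarts=restarts, seed=rep_seed)
            fb = fit(spec, tb, restarts=restarts, seed=rep_seed + 1)
            g2_both = fa.g_squared + fb.g_squared
            g2_eqdisc, p_eqdisc, _ = _joint_with_sharing(
                ta, tb, share_disc=True, share_crit=False,
                fa=fa, fb=fb, restarts=restarts, seed=rep_seed)
            g2_eqcrit, p_eqcrit, _ = _joint_with_sharing(
                ta, tb, share_disc=False, share_crit=True,
                fa=fa, fb=fb, restarts=restarts, seed=rep_seed + 2)
            d_disc = max(g2_eqdisc - g2_both, 0.0)
            d_crit = max(g2_eqcrit - g2_both, 0.0)
            recs.append({
                "delta_g2_discriminability": d_disc,
                "p_discriminability": float(chi2.sf(d_disc, 2)),
                "delta_g2_criteria": d_crit,
                "p_criteria": float(chi2.sf(d_crit, 8)),
            })
        replicates[scenario] = recs
        pd_ = np.array([r["p_discriminability"] for r in recs])
        pc_ = np.array([r["p_criteria"] for r in recs])
        summary[scenario] = {
            "pct_reject_equal_discriminability": 100.0 * float((pd_ < 0.05).mean()),
            "pct_reject_equal_criteria": 100.0 * float((pc_ < 0.05).mean()),
        }
    return StudyResult("group_difference", list(scenarios), replicates,
                       summary, reps, seed)


def _joint_with_sharing(ta, tb, *, share_disc, share_crit, fa, fb,
                        restarts, seed):
    disc_idx = np.array([0, 1])
    crit_idx = np.arange(2, 10)
    b_free_blocks = []
    if not share_disc:
        b_free_blocks.append(disc_idx)
    if not share_crit:
        b_free_blocks.append(crit_idx)
    b_free = (np.concatenate(b_free_blocks) if b_free_blocks
              else np.array([], int))
    # start at the separate solutions with the shared block averaged
    xa = fa.free_vector.copy()
    xb = fb.free_vector.copy()
    shared = np.setdiff1d(np.arange(10), b_free)
    start = xa.copy()
    start[shared] = (xa[shared] + xb[shared]) / 2.0
    start = np.concatenate([start, xb[b_free]])
    g2, n_params, x = fit_two_groups(
        ta, tb, share_discriminability=share_disc, share_criteria=share_crit,
        restarts=restarts, seed=seed, extra_starts=[start])
    return g2, n_params, x


# ---------------------------------------------------------------------------
# Selection-bias (aggregation) simulations

def simulation_population_specs() -> dict[str, PopulationSpec]:
    """The three heterogeneous-population scenarios for the selection-bias probe.

    1. criterion heterogeneity only (tau0 ~ U[-0.25, 1], mu_T = 0.75);
    2. criterion and discriminability heterogeneity (mu_T ~ U[0.10, 1.40]);
    3. as 2 but criteria placed at a likelihood ratio drawn from U[0.75, 2].
    """
    return {
        "simulation1": PopulationSpec(mu_T=0.75, tau0=(-0.25, 1.0)),
        "simulation2": PopulationSpec(mu_T=(0.10, 1.40), tau0=(-0.25, 1.0)),
        "simulation3": PopulationSpec(mu_T=(0.10, 1.40), tau0_lr=(0.75, 2.0)),
    }


def selection_bias_study(pop_specs: Optional[dict] = None,
                         n_witnesses: int = 100_000,
                         seed: int = 0,
                         design: LineupDesign = LineupDesign(6, 1)) -> StudyResult:
    """Hazard-difference curves from heterogeneous witness populations.

    Each population responds under the fixed-criterion baseline model, so
    any nonzero hazard difference is an aggregation artifact rather than a
    within-witness criterion shift.  ``n_witnesses`` is the total across
    the I+1 conditions (split equally).
    """
    if pop_specs is None:
        pop_specs = simulation_population_specs()
    n_per = max(n_witnesses // design.n_conditions, 1)
    replicates: dict = {}
    summary: dict = {}
    for i, (label, pop) in enumerate(pop_specs.items()):
        table = simulate_population(pop, design, n_per, seed=seed + i)
        diffs = hazard_differences(table)
        finite = diffs[np.isfinite(diffs)]
        replicates[label] = [{"hazard_differences": diffs}]
        summary[label] = {"mean_difference": float(finite.mean()),
                          "max_abs_difference": float(np.abs(finite).max())}
    return StudyResult("selection_bias", list(pop_specs), replicates, summary,
                       reps=1, seed=seed)


# ---------------------------------------------------------------------------
# Uncensored-sequence diagnostics

def _strata_counts(counts: np.ndarray, i: int, I: int) -> np.ndarray:
    """(2^(i-1), 2) table of no/yes responses at position i by history."""
    out = np.zeros((2 ** (i - 1), 2))
    for s, c in enumerate(counts):
        if c == 0:
            continue
        history = s & ((1 << (i - 1)) - 1)
        resp = (s >> (i - 1)) & 1
        out[history, resp] += c
    return out


def iid_position_test(uncensored_counts: dict, position: int,
                      face_type: str = "target",
                      design: LineupDesign = LineupDesign(6, 1)) -> dict:
    """Test that P("yes") at a position ignores the preceding responses.

    Strata are the 2^(i-1) possible preceding response patterns; under the
    i.i.d. null the yes rate is constant across them.  ``face_type``
    selects the condition: "target" uses the target-at-i condition (the
    judged face is the target), "lure" the target-absent condition.
    Returns {"g2", "df", "p", "proportions"}; empty strata are dropped
    with a warning and the degrees of freedom adjusted.
    """
    I = design.sequence_length
    if not 1 <= position <= I:
        raise ValueError(f"position must be in 1..{I}")
    if face_type not in ("target", "lure"):
        raise ValueError("face_type must be 'target' or 'lure'")
    cond = position if face_type == "target" else ABSENT
    counts = np.asarray(uncensored_counts[cond])
    tab = _strata_counts(counts, position, I)
    keep = tab.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} empty history strata dropped; "
                      "df adjusted", stacklevel=2)
    tab = tab[keep]
    if len(tab) < 2:
        raise ValueError("need at least two nonempty history strata")
    row = tab.sum(axis=1, keepdims=True)
    col = tab.sum(axis=0, keepdims=True)
    expected = row * col / tab.sum()
    mask = tab > 0
    g2 = float(2.0 * np.sum(tab[mask] * np.log(tab[mask] / expected[mask])))
    df = len(tab) - 1
    props = (tab[:, 1] / tab.sum(axis=1))
    return {"g2": g2, "df": df, "p": float(chi2.sf(g2, df)),
            "proportions": props}


def _prepost_pairs(uncensored_counts: dict, design: LineupDesign):
    """Hit/FA counts per (position 2..I, pre/post-first-"yes" stratum)."""
    I = design.sequence_length
    pairs = []
    for i in range(2, I + 1):
        hit_tab = _strata_counts(np.asarray(uncensored_counts[i]), i, I)
        fa_tab = _strata_counts(np.asarray(uncensored_counts[ABSENT]), i, I)
        for post in (0, 1):
            sel = np.array([bool(h) == bool(post)
                            for h in range(2 ** (i - 1))])
            hits = hit_tab[sel].sum(axis=0)
            fas = fa_tab[sel].sum(axis=0)
            if hits.sum() == 0 or fas.sum() == 0:
                continue
            pairs.append({"position": i, "post": bool(post),
                          "hit_yes": hits[1], "hit_n": hits.sum(),
                          "fa_yes": fas[1], "fa_n": fas.sum()})
    return pairs


def prepost_binary_sdt(uncensored_counts: dict,
                       design: LineupDesign = LineupDesign(6, 1),
                       restarts: int = 4, seed: int = 0) -> dict:
    """Unequal-variance SDT fit of pre- vs post-first-"yes" hit/FA pairs.

    Pools positions 2..I of uncensored sequences into hit/false-alarm
    pairs per (position, stratum), where the stratum records whether any
    "yes" preceded.  The model puts lures at N(0, 1) and targets at
    N(mu_s, sigma2_s) with stratum-specific (mu, sigma2) and criteria free
    per (position, stratum).  Reports the d_a and mean-criterion
    differences (pre minus post, post minus pre respectively) with
    likelihood-ratio tests of their nullity.
    """
    pairs = _prepost_pairs(uncensored_counts, design)
    if not pairs:
        raise ValueError("no usable (position, stratum) pairs")
    positions = sorted({p["position"] for p in pairs})
    strata_present = sorted({p["post"] for p in pairs})

    def nll_factory(equal_disc: bool, equal_crit: bool):
        # x = [mu_pre, log s2_pre, (mu_post, log s2_post), criteria ...]
        n_disc = 2 if equal_disc else 4
        crit_keys = ([(i,) for i in positions] if equal_crit
                     else [(i, s) for i in positions for s in strata_present
                           if any(p["position"] == i and p["post"] == s
                                  for p in pairs)])
        n_par = n_disc + len(crit_keys)

        def unpack(x):
            mu = {False: x[0], True: x[0] if equal_disc else x[2]}
            s2 = {False: np.exp(x[1]),
                  True: np.exp(x[1]) if equal_disc else np.exp(x[3])}
            crit = {}
            for j, key in enumerate(crit_keys):
                crit[key] = x[n_disc + j]
            return mu, s2, crit

        def nll(x):
            mu, s2, crit = unpack(x)
            total = 0.0
            for p in pairs:
                key = (p["position"],) if equal_crit else (p["position"], p["post"])
                tau = crit[key]
                ph = norm.sf((tau - mu[p["post"]]) / np.sqrt(s2[p["post"]]))
                pf = norm.sf(tau)
                for y, n, pr in ((p["hit_yes"], p["hit_n"], ph),
                                 (p["fa_yes"], p["fa_n"], pf)):
                    pr = min(max(pr, 1e-12), 1 - 1e-12)
                    total -= y * np.log(pr) + (n - y) * np.log(1 - pr)
            return total if np.isfinite(total) else 1e12

        return nll, n_par

    def best_fit(equal_disc=False, equal_crit=False):
        nll, n_par = nll_factory(equal_disc, equal_crit)
        rng = np.random.default_rng(seed)
        best = (np.inf, None)
        for _ in range(restarts):
            x0 = np.concatenate([
                [1.0 + rng.normal(0, 0.3), rng.normal(0, 0.3)],
                [] if equal_disc else [1.0 + rng.normal(0, 0.3),
                                       rng.normal(0, 0.3)],
                rng.normal(0.3, 0.3, n_par - (2 if equal_disc else 4)),
            ])
            res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                    options={"maxiter": 3000, "ftol": 1e-12})
            if res.fun < best[0]:
                best = (float(res.fun), res.x)
        return best[0], best[1], n_par

    f_full, x_full, p_full = best_fit()
    f_eqd, _, p_eqd = best_fit(equal_disc=True)
    f_eqc, _, p_eqc = best_fit(equal_crit=True)

    mu_pre, s2_pre = x_full[0], float(np.exp(x_full[1]))
    mu_post, s2_post = x_full[2], float(np.exp(x_full[3]))
    da_pre = mu_pre / np.sqrt((1 + s2_pre) / 2)
    da_post = mu_post / np.sqrt((1 + s2_post) / 2)
    # mean criterion per stratum across positions present in both strata
    crit_keys = [(i, s) for i in positions for s in strata_present
                 if any(p["position"] == i and p["post"] == s for p in pairs)]
    crit = {k: x_full[4 + j] for j, k in enumerate(crit_keys)}
    both = [i for i in positions
            if (i, False) in crit and (i, True) in crit]
    mean_tau_diff = (np.mean([crit[(i, True)] for i in both])
                     - np.mean([crit[(i, False)] for i in both])) if both else np.nan

    d_disc = max(f_eqd - f_full, 0.0) * 2.0
    d_crit = max(f_eqc - f_full, 0.0) * 2.0
    return {
        "da_pre": float(da_pre), "da_post": float(da_post),
        "da_difference": float(da_pre - da_post),
        "mean_tau_difference": float(mean_tau_diff),
        "lr_discriminability": {"delta_g2": d_disc, "df": p_full - p_eqd,
                                "p": float(chi2.sf(d_disc, p_full - p_eqd))},
        "lr_criteria": {"delta_g2": d_crit, "df": p_full - p_eqc,
                        "p": float(chi2.sf(d_crit, p_full - p_eqc))},
        "n_pairs": len(pairs),
    }
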