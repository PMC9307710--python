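"""SDT probability machinery: examples, invariants, and simulation oracles."""

import numpy as np
import pytest
from scipy.stats import norm

from seqsdt import (
    ABSENT,
    LineupDesign,
    ParameterSet,
    censored_confidence_probabilities,
    censored_probabilities,
    confidence_criteria,
    d_a,
    effective_criterion,
    mixture_probabilities,
    predicted_rocs,
    uncensored_probabilities,
    unserious_confidence_pmf,
)
from seqsdt.core import probability_matrix, sequence_first_yes

from conftest import random_parameters


def mc_censored(params, condition, n, rng):
    """Brute-force simulation of the censored decision chain.

    Samples latent strengths face by face and applies the criterion
    comparison directly - independent of the analytic Eq.-style product
    formulas it is used to check.
    """
    I = params.n_positions
    target_at = None if condition == ABSENT else condition
    counts = np.zeros(I + 1)
    strengths = np.empty((n, I))
    for i in range(1, I + 1):
        is_t = target_at == i
        mu = params.mu_at(i, is_t)
        sd = params.sigma_at(i, is_t)
        strengths[:, i - 1] = rng.normal(mu, sd, n)
    taken = np.zeros(n, dtype=bool)
    rejected_target = np.zeros(n, dtype=bool)
    first = np.full(n, I)
    for i in range(1, I + 1):
        tau = np.full(n, params.tau0[i - 1])
        if target_at is not None and target_at < i:
            tau = np.where(rejected_target,
                           effective_criterion(params, i, target_at), tau)
        yes = (strengths[:, i - 1] > tau) & ~taken
        first[yes] = i - 1
        taken |= yes
        if target_at == i:
            rejected_target = ~taken
    np.add.at(counts, first, 1)
    return counts / n


class TestEffectiveCriterion:
    def test_zero_effect(self):
        p = ParameterSet(mu_T=1, sigma2_T=1, tau0=[0.1, 0.2, 0.3, 0.4],
                         delta=0.0, lambda_=0.7)
        assert effective_criterion(p, 4, 2) == pytest.approx(0.4)

    def test_no_decay_constant_shift(self):
        p = ParameterSet(mu_T=1, sigma2_T=1, tau0=np.zeros(6),
                         delta=1.07, lambda_=0.0)
        assert effective_criterion(p, 2, 1) == pytest.approx(1.07)
        assert effective_criterion(p, 6, 1) == pytest.approx(1.07)

    def test_published_kernel_value(self):
        p = ParameterSet(mu_T=1, sigma2_T=1, tau0=np.zeros(6),
                         delta=1.07, lambda_=0.50)
        assert effective_criterion(p, 2, 1) == pytest.approx(
            1.07 * np.exp(-0.5), abs=1e-12)

    def test_target_after_position_rejected(self):
        p = ParameterSet(mu_T=1, sigma2_T=1, tau0=np.zeros(6))
        with pytest.raises(ValueError, match="precede"):
            effective_criterion(p, 3, 3)


class TestCensoredProbabilities:
    def test_symmetric_coin_flip_chain(self, binary_design):
        p = ParameterSet(mu_T=0.0, sigma2_T=1.0, tau0=np.zeros(6))
        probs = censored_probabilities(p, binary_design, ABSENT)
        assert np.allclose(probs[:6], 0.5 ** np.arange(1, 7))
        assert probs[6] == pytest.approx(0.5 ** 6)

    def test_liberal_first_criterion_limit(self, binary_design):
        tau = np.zeros(6)
        tau[0] = -40.0
        p = ParameterSet(mu_T=0.5, sigma2_T=1.0, tau0=tau)
        probs = censored_probabilities(p, binary_design, 3)
        assert probs[0] == pytest.approx(1.0, abs=1e-12)
        assert probs[1:].sum() == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("condition", [1, 4, ABSENT])
    def test_matches_simulation_oracle(self, condition, binary_design, rng):
        # published shift-kernel estimates, 10^6 simulated witnesses, 3 SE
        p = ParameterSet(mu_T=0.91, sigma2_T=1.03,
                         tau0=[-0.01, 0.09, -0.07, -0.09, 0.06, 0.11],
                         delta=1.07, lambda_=0.50)
        n = 10 ** 6
        emp = mc_censored(p, condition, n, rng)
        ana = censored_probabilities(p, binary_design, condition)
        se = np.sqrt(np.maximum(ana * (1 - ana), 1e-12) / n)
        assert (np.abs(emp - ana) < 3.5 * se + 1e-9).all()

    def test_normalization_random_params(self, binary_design, rng):
        for _ in range(20):
            p = random_parameters(rng)
            for cond in [1, 3, 6, ABSENT]:
                assert censored_probabilities(
                    p, binary_design, cond).sum() == pytest.approx(1, abs=1e-10)

    def test_monotonicity_in_criterion(self, binary_design, rng):
        # raising tau_0,i weakly lowers P(yes@i), raises later cells
        p = random_parameters(rng)
        base = censored_probabilities(p, binary_design, ABSENT)
        tau = p.tau0.copy()
        tau[2] += 0.5
        q = censored_probabilities(
            ParameterSet(mu_T=p.mu_T, sigma2_T=p.sigma2_T, tau0=tau,
                         delta=p.delta, lambda_=p.lambda_),
            binary_design, ABSENT)
        assert q[2] < base[2]
        assert (q[3:] >= base[3:] - 1e-15).all()


class TestConfidence:
    def test_cumulative_criteria_by_hand(self):
        p = ParameterSet(mu_T=1, sigma2_T=1, tau0=np.full(6, 0.1),
                         kappa=np.tile([0.2, 0.3, 0.4], (6, 1)))
        crit = confidence_criteria(p, 2, None)
        assert np.allclose(crit, [0.1, 0.3, 0.6, 1.0])

    def test_neutral_modulation_is_rigid_shift(self, rng):
        p = random_parameters(rng, K=4)
        p.omega, p.eta, p.gamma = 1.0, 0.0, 0.0
        pre = confidence_criteria(p, 5, None)
        post = confidence_criteria(p, 5, 2)
        shift = effective_criterion(p, 5, 2) - p.tau0[4]
        assert np.allclose(post - pre, shift)

    def test_criteria_nondecreasing(self, rng):
        for _ in range(20):
            p = random_parameters(rng, K=5)
            for i in (1, 4, 6):
                for h in (None, *range(1, i)):
                    crit = confidence_criteria(p, i, h)
                    assert (np.diff(crit) >= 0).all()

    def test_bins_marginalize_to_binary(self, confidence_design, rng):
        for _ in range(10):
            p = random_parameters(rng, K=4)
            for cond in [2, ABSENT]:
                conf = censored_confidence_probabilities(
                    p, confidence_design, cond)
                binary = censored_probabilities(
                    p, LineupDesign(6, 1), cond)
                yes = conf[:-1].reshape(6, 4).sum(axis=1)
                assert np.allclose(yes, binary[:-1], atol=1e-12)
                assert conf[-1] == pytest.approx(binary[-1], abs=1e-12)

    def test_zero_increments_put_mass_in_top_bin(self, confidence_design):
        p = ParameterSet(mu_T=0.8, sigma2_T=1.0, tau0=np.zeros(6),
                         kappa=np.zeros((6, 3)))
        probs = censored_confidence_probabilities(p, confidence_design, ABSENT)
        bins = probs[:-1].reshape(6, 4)
        assert np.allclose(bins[:, :3], 0.0, atol=1e-14)

    def test_matches_simulation_oracle(self, confidence_design, rng):
        p = ParameterSet(mu_T=0.77, sigma2_T=0.51,
                         tau0=[0.13, 0.22, 0.08, 0.05, 0.20, 0.25],
                         delta=1.04, lambda_=0.49,
                         kappa=np.tile([0.3, 0.35, 0.4], (6, 1)),
                         omega=1.44, eta=-0.03, gamma=0.12)
        n = 10 ** 6
        cond = 2
        # simulate the full decision chain with confidence partitioning
        I, K = 6, 4
        counts = np.zeros(I * K + 1)
        taken = np.zeros(n, dtype=bool)
        rejected_target = np.zeros(n, dtype=bool)
        for i in range(1, I + 1):
            is_t = cond == i
            x = rng.normal(p.mu_at(i, is_t), p.sigma_at(i, is_t), n)
            crit_pre = confidence_criteria(p, i, None)
            crit_post = (confidence_criteria(p, i, cond)
                         if cond < i else crit_pre)
            crit = np.where(rejected_target[:, None], crit_post, crit_pre)
            yes = (x > crit[:, 0]) & ~taken
            level = (x[:, None] > crit).sum(axis=1)   # 1..K among yes
            for k in range(1, K + 1):
                counts[(i - 1) * K + k - 1] += (yes & (level == k)).sum()
            taken |= yes
            if is_t:
                rejected_target = ~taken
        counts[-1] = (~taken).sum()
        emp = counts / n
        ana = censored_confidence_probabilities(p, confidence_design, cond)
        se = np.sqrt(np.maximum(ana * (1 - ana), 1e-12) / n)
        assert (np.abs(emp - ana) < 3.5 * se + 1e-9).all()


class TestUnseriousMixture:
    def test_published_confidence_probabilities(self):
        assert np.allclose(unserious_confidence_pmf(0.89, 4).round(2),
                           [0.61, 0.25, 0.10, 0.04])

    def test_uniform_limit(self):
        assert np.allclose(unserious_confidence_pmf(1e-12, 4), 0.25)

    def test_two_level_closed_form(self):
        pmf = unserious_confidence_pmf(1.0, 2)
        assert pmf[0] == pytest.approx(1 / (1 + np.exp(-1)))
        assert pmf[1] == pytest.approx(np.exp(-1) / (1 + np.exp(-1)))

    def test_pure_serious_is_base_model(self, confidence_design, rng):
        p = random_parameters(rng, K=4, mixture=True)
        p.pi_serious = 1.0
        assert np.allclose(
            mixture_probabilities(p, confidence_design, 3),
            censored_confidence_probabilities(p, confidence_design, 3))

    def test_pure_contaminant_binary(self, binary_design, rng):
        p = random_parameters(rng, mixture=True)
        p.pi_serious = 0.0
        probs = mixture_probabilities(p, binary_design, ABSENT)
        assert probs[0] == pytest.approx(1.0)
        assert probs[1:].sum() == pytest.approx(0.0)

    def test_mixture_algebra_binary(self, binary_design, rng):
        p = random_parameters(rng, mixture=True)
        p.pi_serious = 0.95
        base = censored_probabilities(p, binary_design, ABSENT)
        mixed = mixture_probabilities(p, binary_design, ABSENT)
        assert mixed[0] - base[0] == pytest.approx(0.05 * (1 - base[0]))


class TestDiscriminability:
    def test_zero_mean_zero_da(self):
        p = ParameterSet(mu_T=0.0, sigma2_T=1.0, tau0=np.zeros(6))
        assert d_a(p) == 0.0

    def test_equal_variance_reduction(self):
        p = ParameterSet(mu_T=0.7, sigma2_T=1.0, tau0=np.zeros(6))
        assert d_a(p) == pytest.approx(1.4)

    def test_published_binary_estimate(self):
        # mu_T=0.91, sigma2_T=1.03 evaluates near the printed 1.79 (rounding)
        p = ParameterSet(mu_T=0.91, sigma2_T=1.03, tau0=np.zeros(6))
        assert d_a(p) == pytest.approx(1.79, abs=0.02)

    def test_position_factors(self):
        alpha = np.array([1, 1.2, 1, 1, 1, 1.0])
        xi = np.array([1, 1, 0.8, 1, 1, 1.0])
        p = ParameterSet(mu_T=0.5, sigma2_T=1.0, tau0=np.zeros(6),
                         alpha=alpha, xi=xi)
        assert d_a(p, 2) == pytest.approx(1.2 * d_a(p, 1))
        assert d_a(p, 3) == pytest.approx(d_a(p, 1) / np.sqrt(0.8))


class TestPredictedRocs:
    def test_null_discriminability_on_diagonal(self, confidence_design):
        p = ParameterSet(mu_T=0.0, sigma2_T=1.0, tau0=np.full(6, 0.2),
                         kappa=np.tile([0.3, 0.3, 0.3], (6, 1)))
        rocs = predicted_rocs(p, confidence_design)
        for h, pts in rocs.items():
            assert np.allclose(pts[:, 0], pts[:, 1], atol=1e-12)

    def test_points_cumulative(self, confidence_design, rng):
        p = random_parameters(rng, K=4)
        for pts in predicted_rocs(p, confidence_design).values():
            assert (np.diff(pts[:, 0]) >= -1e-15).all()
            assert (np.diff(pts[:, 1]) >= -1e-15).all()

    def test_early_positions_dominate(self, confidence_design):
        p = ParameterSet(mu_T=0.77, sigma2_T=0.51,
                         tau0=[0.13, 0.22, 0.08, 0.05, 0.20, 0.25],
                         delta=1.04, lambda_=0.49,
                         kappa=np.tile([0.3, 0.35, 0.4], (6, 1)),
                         omega=1.44, eta=-0.03, gamma=0.12)
        rocs = predicted_rocs(p, confidence_design)
        # survival to position 6 shrinks hit rates: position 1 ROC dominates
        assert rocs[1][-1, 1] > rocs[6][-1, 1]
        assert (rocs[1][:, 1] >= rocs[6][:, 1] - 1e-12).all()


class TestUncensored:
    def test_stopping_rule_emulation(self, binary_design, rng):
        pre = random_parameters(rng)
        post = ParameterSet(mu_T=pre.mu_T, sigma2_T=pre.sigma2_T,
                            tau0=np.full(6, 40.0), delta=pre.delta,
                            lambda_=pre.lambda_)
        probs = uncensored_probabilities(pre, post, binary_design, 3)
        for s, q in enumerate(probs):
            n_yes = bin(s).count("1")
            if n_yes > 1:
                assert q == pytest.approx(0.0, abs=1e-12)
        # marginal over completions equals the censored model
        censored = censored_probabilities(pre, binary_design, 3)
        marg = np.zeros(7)
        for s, q in enumerate(probs):
            first = sequence_first_yes(s, 6)
            marg[6 if first is None else first - 1] += q
        assert np.allclose(marg, censored, atol=1e-12)

    def test_independent_fair_coins(self):
        design = LineupDesign(2, 1)
        p = ParameterSet(mu_T=0.0, sigma2_T=1.0, tau0=np.zeros(2))
        probs = uncensored_probabilities(p, p, design, ABSENT)
        assert np.allclose(probs, 0.25)

    def test_marginalization_holds_for_distinct_post(self, binary_design, rng):
        pre = random_parameters(rng)
        post = random_parameters(rng)
        for cond in [1, 4, ABSENT]:
            probs = uncensored_probabilities(pre, post, binary_design, cond)
            assert probs.sum() == pytest.approx(1.0, abs=1e-10)
            censored = censored_probabilities(pre, binary_design, cond)
            marg = np.zeros(7)
            for s, q in enumerate(probs):
                first = sequence_first_yes(s, 6)
                marg[6 if first is None else first - 1] += q
            assert np.allclose(marg, censored, atol=1e-12)

    def test_matches_two_phase_simulation(self, rng):
        design = LineupDesign(4, 1)
        pre = ParameterSet(mu_T=0.8, sigma2_T=0.7, tau0=[0.1, 0.3, 0.0, 0.2],
                           delta=0.9, lambda_=0.4)
        post = ParameterSet(mu_T=0.5, sigma2_T=0.7,
                            tau0=[0.5, 0.7, 0.4, 0.6], delta=0.9, lambda_=0.4)
        cond = 2
        n = 10 ** 6
        seqs = np.zeros(n, dtype=int)
        seen_yes = np.zeros(n, dtype=bool)
        rejected_target = np.zeros(n, dtype=bool)
        for i in range(1, 5):
            params_mu = np.where(seen_yes, post.mu_at(i, cond == i),
                                 pre.mu_at(i, cond == i))
            params_sd = np.where(seen_yes, post.sigma_at(i, cond == i),
                                 pre.sigma_at(i, cond == i))
            tau_pre = (effective_criterion(pre, i, cond)
                       if (cond < i) else pre.tau0[i - 1])
            tau_post = (effective_criterion(post, i, cond)
                        if (cond < i) else post.tau0[i - 1])
            tau_eff = np.where(seen_yes, tau_post, tau_pre)
            if cond < i:
                tau_eff = np.where(rejected_target, tau_eff,
                                   np.where(seen_yes, post.tau0[i - 1],
                                            pre.tau0[i - 1]))
            x = rng.normal(0, 1, n) * params_sd + params_mu
            yes = x > tau_eff
            seqs |= yes.astype(int) << (i - 1)
            seen_yes |= yes
            if cond == i:
                rejected_target = ~yes
        emp = np.bincount(seqs, minlength=16) / n
        ana = uncensored_probabilities(pre, post, design, cond)
        se = np.sqrt(np.maximum(ana * (1 - ana), 1e-12) / n)
        assert (np.abs(emp - ana) < 3.5 * se + 1e-9).all()
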