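"""Model family layouts, transforms, counts, and nesting."""

import numpy as np
import pytest

from seqsdt import LineupDesign, ModelSpec, build_model, is_nested, parameter_count
from seqsdt.core import probability_matrix

from conftest import random_parameters

BINARY = LineupDesign(6, 1)
CONF4 = LineupDesign(6, 4)

# published parameter tallies for the 20 binary models, in canonical order
PUBLISHED_COUNTS = {
    ("tau1", "null"): 3, ("tau1", "mu1"): 4, ("tau1", "sigma1"): 4,
    ("tau1", "mu2"): 8, ("tau1", "sigma2"): 8,
    ("tau2", "null"): 8, ("tau2", "mu1"): 9, ("tau2", "sigma1"): 9,
    ("tau2", "mu2"): 13, ("tau2", "sigma2"): 13,
    ("tau3", "null"): 5, ("tau3", "mu1"): 6, ("tau3", "sigma1"): 6,
    ("tau3", "mu2"): 10, ("tau3", "sigma2"): 10,
    ("tau4", "null"): 10, ("tau4", "mu1"): 11, ("tau4", "sigma1"): 11,
    ("tau4", "mu2"): 15, ("tau4", "sigma2"): 15,
}


@pytest.mark.parametrize("crit,disc", sorted(PUBLISHED_COUNTS))
def test_binary_parameter_counts(crit, disc):
    spec = ModelSpec(crit, disc)
    assert parameter_count(spec, BINARY) == PUBLISHED_COUNTS[(crit, disc)]


def test_mixture_adds_two_parameters():
    base = ModelSpec("tau4", "null", confidence=True)
    mixed = ModelSpec("tau4", "null", confidence=True, mixture=True)
    assert (parameter_count(mixed, CONF4)
            - parameter_count(base, CONF4)) == 2


def test_confidence_additional_parameters():
    # 6*(K-1) kappa increments plus omega/eta/gamma over the binary base
    base = parameter_count(ModelSpec("tau4", "null"), BINARY)
    conf = parameter_count(ModelSpec("tau4", "null", confidence=True), CONF4)
    assert conf - base == 6 * 3 + 3
    # the published-count toggle tallies one fewer
    assert parameter_count(ModelSpec("tau4", "null", confidence=True), CONF4,
                           paper_count_mode=True) == conf - 1


def test_equal_variance_removes_one():
    spec = ModelSpec("tau1", "null", restrictions={"equal_variance"})
    assert parameter_count(spec, BINARY) == 2


class TestTransforms:
    @pytest.mark.parametrize("spec", [
        ModelSpec("tau1", "null"),
        ModelSpec("tau2", "sigma1"),
        ModelSpec("tau3", "mu2"),
        ModelSpec("tau4", "null"),
        ModelSpec("tau4", "sigma2", restrictions={"lambda_zero"}),
        ModelSpec("tau4", "null", restrictions={"monotone_increasing_tau0"}),
        ModelSpec("tau4", "null", confidence=True, mixture=True),
        ModelSpec("tau4", "mu1", confidence=True,
                  restrictions={"shared_kappa_across_positions"}),
    ])
    def test_free_natural_round_trip(self, spec, rng):
        design = CONF4 if spec.confidence else BINARY
        layout = build_model(spec, design)
        v = rng.uniform(-1.5, 1.5, layout.n_free)
        back = layout.from_natural(layout.to_natural(v))
        assert np.allclose(back, v, atol=1e-10)

    def test_log_anchor(self):
        layout = build_model(ModelSpec("tau1", "null"), BINARY)
        params = layout.to_natural(np.array([0.5, 0.0, 0.2]))
        assert params.sigma2_T == pytest.approx(1.0)

    def test_monotone_layout_orders_criteria(self, rng):
        for restr, sign in [("monotone_increasing_tau0", 1),
                            ("monotone_decreasing_tau0", -1)]:
            layout = build_model(
                ModelSpec("tau4", "null", restrictions={restr}), BINARY)
            for _ in range(10):
                p = layout.to_natural(rng.uniform(-3, 2, layout.n_free))
                assert (sign * np.diff(p.tau0) >= 0).all()

    def test_any_finite_vector_is_admissible(self, rng):
        layout = build_model(
            ModelSpec("tau4", "sigma2", confidence=True, mixture=True), CONF4)
        for _ in range(10):
            p = layout.to_natural(rng.uniform(-5, 5, layout.n_free))
            assert p.sigma2_T > 0 and (p.xi > 0).all()
            assert (p.kappa >= 0).all() and 0 <= p.pi_serious <= 1


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(criterion_variant="tau9"),
        dict(discriminability_variant="mu3"),
        dict(criterion_variant="tau1",
             restrictions={"monotone_increasing_tau0"}),
        dict(criterion_variant="tau2", restrictions={"lambda_zero"}),
        dict(restrictions={"omega_eta_gamma_fixed"}),
        dict(restrictions={"monotone_increasing_tau0",
                           "monotone_decreasing_tau0"}),
    ])
    def test_inconsistent_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelSpec(**kwargs)

    def test_string_round_trip(self):
        for spec in [ModelSpec("tau4", "mu1"),
                     ModelSpec("tau3", "null",
                               restrictions={"lambda_zero"}),
                     ModelSpec("tau4", "null", confidence=True,
                               mixture=True)]:
            assert ModelSpec.from_string(spec.to_string()) == spec
        assert ModelSpec.from_string("tau4+mu1[K=4]").confidence


class TestNesting:
    def test_documented_nestings(self):
        t4 = ModelSpec("tau4", "null")
        assert is_nested(ModelSpec("tau2", "null"), t4)
        assert is_nested(ModelSpec("tau3", "null"), t4)
        assert is_nested(ModelSpec("tau4", "null",
                                   restrictions={"lambda_zero"}), t4)
        assert is_nested(ModelSpec("tau4", "mu1"), ModelSpec("tau4", "mu2"))
        assert not is_nested(t4, ModelSpec("tau2", "null"))
        assert not is_nested(ModelSpec("tau4", "mu1"),
                             ModelSpec("tau4", "sigma1"))

    def test_restricted_parameters_reproduce_parent_probabilities(self, rng):
        """Mapping a restricted solution into the parent layout leaves all
        cell probabilities unchanged (numerical nesting audit)."""
        cases = [
            (ModelSpec("tau4", "null", restrictions={"lambda_zero"}),
             ModelSpec("tau4", "null")),
            (ModelSpec("tau4", "null",
                       restrictions={"monotone_increasing_tau0"}),
             ModelSpec("tau4", "null")),
            (ModelSpec("tau3", "null"), ModelSpec("tau4", "null")),
            (ModelSpec("tau2", "mu1"), ModelSpec("tau4", "mu2")),
        ]
        for restricted, full in cases:
            lay_r = build_model(restricted, BINARY)
            lay_f = build_model(full, BINARY)
            for _ in range(5):
                p = lay_r.to_natural(rng.uniform(-1, 1, lay_r.n_free))
                if restricted.criterion_variant in ("tau1", "tau2"):
                    p.delta, p.lambda_ = 0.0, 0.0
                # λ=0 is on the log-transform boundary of the parent layout;
                # approach it numerically
                q_lambda = max(p.lambda_, 1e-12)
                p2 = p
                v_f = lay_f.from_natural(
                    type(p)(mu_T=p.mu_T, sigma2_T=p.sigma2_T, tau0=p.tau0,
                            alpha=p.alpha, xi=p.xi, delta=p.delta,
                            lambda_=q_lambda))
                back = lay_f.to_natural(v_f)
                assert np.allclose(
                    probability_matrix(back, BINARY),
                    probability_matrix(p2, BINARY), atol=1e-9)


class TestReductionChain:
    """Exact model-reduction equivalences asserted on probabilities."""

    def test_tau4_delta_zero_is_tau2(self, rng):
        p = random_parameters(rng)
        p.delta = 0.0
        q = type(p)(mu_T=p.mu_T, sigma2_T=p.sigma2_T, tau0=p.tau0)
        assert np.allclose(probability_matrix(p, BINARY),
                           probability_matrix(q, BINARY), atol=1e-14)

    def test_tau2_equal_criteria_is_tau1(self, rng):
        p = random_parameters(rng)
        p.delta, p.lambda_ = 0.0, 0.0
        p.tau0 = np.full(6, 0.17)
        layout1 = build_model(ModelSpec("tau1", "null"), BINARY)
        q = layout1.to_natural(np.array([p.mu_T, np.log(p.sigma2_T), 0.17]))
        assert np.allclose(probability_matrix(p, BINARY),
                           probability_matrix(q, BINARY), atol=1e-12)

    def test_unit_factors_reduce_to_null(self, rng):
        p = random_parameters(rng)
        p.alpha = np.ones(6)
        p.xi = np.ones(6)
        q = type(p)(mu_T=p.mu_T, sigma2_T=p.sigma2_T, tau0=p.tau0,
                    delta=p.delta, lambda_=p.lambda_)
        assert np.allclose(probability_matrix(p, BINARY),
                           probability_matrix(q, BINARY), atol=1e-14)

    def test_tau_shift_models_have_zero_analytic_hazard_difference(self, rng):
        """Without a target-rejection effect the analytic hazard difference
        is identically zero at every (target position, later position)."""
        from seqsdt import LineupTable, hazard_differences
        p = random_parameters(rng)
        p.delta = 0.0
        P = probability_matrix(p, BINARY)
        counts = np.round(P * 10 ** 9).astype(np.int64)
        d = hazard_differences(LineupTable(BINARY, counts))
        assert np.nanmax(np.abs(d)) < 1e-7
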