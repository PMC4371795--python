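"""Cost model, assumption audit, and cost-minimising solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from startleopt import (
    BlowBelief,
    ConfigurationError,
    CostFamily,
    DomainError,
    EvaluationError,
    audit_assumptions,
    family_from_dict,
    family_to_dict,
    make_cost_family,
    optimal_startle,
    sample_cost_family,
    scale_opportunity,
    total_cost,
)

ZERO = lambda r: np.zeros_like(np.asarray(r, dtype=float))


def grid_oracle(family, belief, n=10_000):
    """Independent exhaustive grid search for the global minimiser."""
    lo, hi = family.r_domain
    grid = np.linspace(lo, hi, n)
    vals = np.asarray(total_cost(family, belief, grid))
    return float(grid[np.argmin(vals)])


class TestTotalCost:
    def test_zero_blow_probability_leaves_startle_cost(self, default_family):
        r = np.linspace(0, 1, 11)
        got = total_cost(default_family, BlowBelief(0.0), r)
        np.testing.assert_allclose(got, default_family.startle_cost(r))

    def test_closed_form_arithmetic(self, quad_linear_family):
        # 0.5^2 + 0.5 * (1 - 0.5) = 0.5
        assert total_cost(quad_linear_family, BlowBelief(0.5), 0.5) == pytest.approx(0.5)

    @pytest.mark.parametrize("eta", [0.0, 1.0, 2.5])
    def test_affine_in_blow_probability(self, default_family, eta):
        fam = scale_opportunity(default_family, eta)
        r = 0.37
        c = [total_cost(fam, BlowBelief(p), r) for p in (0.1, 0.4, 0.7)]
        assert c[2] - c[1] == pytest.approx(c[1] - c[0], abs=1e-12)

    def test_affine_in_eta(self, default_family):
        r, p = 0.37, 0.6
        c = [
            total_cost(scale_opportunity(default_family, eta), BlowBelief(p), r)
            for eta in (0.5, 1.0, 1.5)
        ]
        assert c[2] - c[1] == pytest.approx(c[1] - c[0], abs=1e-12)

    def test_unit_eta_matches_unscaled_components(self, default_family):
        r = np.linspace(0, 1, 7)
        p = 0.4
        expected = (
            default_family._component("c_r_direct", r)
            + default_family._component("c_r_forgone", r)
            + p
            * (
                default_family._component("c_b_direct", r)
                + default_family._component("c_b_forgone", r)
            )
        )
        np.testing.assert_allclose(total_cost(default_family, BlowBelief(p), r), expected)

    def test_r_outside_domain_rejected(self, default_family):
        with pytest.raises(DomainError):
            total_cost(default_family, BlowBelief(0.5), 1.5)

    def test_non_finite_component_named(self):
        fam = CostFamily(
            c_r_direct=ZERO,
            c_r_forgone=ZERO,
            c_b_direct=lambda r: np.full_like(np.asarray(r, float), np.nan),
            c_b_forgone=ZERO,
        )
        with pytest.raises(EvaluationError, match="c_b_direct"):
            total_cost(fam, BlowBelief(0.5), 0.5)

    def test_invalid_probability_rejected(self):
        with pytest.raises(DomainError):
            BlowBelief(1.2)


class TestOptimalStartle:
    @pytest.mark.parametrize("p", [0.0, 0.2, 0.6, 1.0])
    def test_closed_form_minimiser(self, quad_linear_family, p):
        opt = optimal_startle(quad_linear_family, BlowBelief(p), check_assumptions=False)
        assert opt.r0 == pytest.approx(p / 2, abs=1e-6)
        assert opt.c0 == pytest.approx(
            total_cost(quad_linear_family, BlowBelief(p), opt.r0), abs=1e-12
        )

    def test_floor_when_only_startle_cost_remains(self):
        fam = CostFamily(
            c_r_direct=lambda r: np.asarray(r, float),
            c_r_forgone=ZERO,
            c_b_direct=lambda r: 1.0 - np.asarray(r, float),
            c_b_forgone=ZERO,
        )
        opt = optimal_startle(fam, BlowBelief(0.0), check_assumptions=False)
        assert opt.r0 == 0.0

    def test_blow_probability_monotone_example(self, default_family):
        r_low = optimal_startle(default_family, BlowBelief(0.2)).r0
        r_high = optimal_startle(default_family, BlowBelief(0.6)).r0
        assert r_high >= r_low - 1e-8

    def test_eta_monotone_example(self, default_family):
        r1 = optimal_startle(default_family, BlowBelief(0.3)).r0
        r2 = optimal_startle(scale_opportunity(default_family, 2.0), BlowBelief(0.3)).r0
        assert r2 >= r1 - 1e-8

    def test_flat_objective_ties_break_to_smallest_r(self):
        one = lambda r: np.ones_like(np.asarray(r, dtype=float))
        fam = CostFamily(c_r_direct=one, c_r_forgone=ZERO, c_b_direct=ZERO, c_b_forgone=ZERO)
        opt = optimal_startle(fam, BlowBelief(0.5), check_assumptions=False)
        assert opt.r0 == 0.0

    def test_audit_gate_refuses_violating_family(self, quad_linear_family):
        with pytest.raises(ConfigurationError, match="audit"):
            optimal_startle(quad_linear_family, BlowBelief(0.5))

    @pytest.mark.parametrize("form", ["quadratic-exponential", "linear", "logistic"])
    @pytest.mark.parametrize("p", [0.05, 0.35, 0.8])
    def test_matches_grid_oracle_for_shipped_families(self, form, p):
        fam = make_cost_family(form)
        opt = optimal_startle(fam, BlowBelief(p))
        assert abs(opt.r0 - grid_oracle(fam, BlowBelief(p))) <= 1.0 / 9_999


class TestAudit:
    def test_shipped_defaults_pass(self):
        for form in ("quadratic-exponential", "linear", "logistic"):
            report = audit_assumptions(make_cost_family(form))
            assert report.passed, report.failures()

    def test_textbook_compliant_family_passes(self):
        fam = CostFamily(
            c_r_direct=ZERO,
            c_r_forgone=lambda r: 0.1 * np.asarray(r, float),
            c_b_direct=lambda r: np.exp(-np.asarray(r, float)),
            c_b_forgone=lambda r: 2.0 * (1.0 - np.asarray(r, float)),
        )
        assert audit_assumptions(fam).passed

    def test_steep_startle_opportunity_fails_with_witness(self):
        fam = CostFamily(
            c_r_direct=ZERO,
            c_r_forgone=lambda r: 3.0 * np.asarray(r, float),
            c_b_direct=lambda r: np.exp(-np.asarray(r, float)),
            c_b_forgone=lambda r: 2.0 * (1.0 - np.asarray(r, float)),
        )
        report = audit_assumptions(fam)
        check = report["opportunity_slopes"]
        assert not check.passed
        lo, hi = fam.r_domain
        assert lo <= check.worst_r <= hi

    def test_flat_blow_cost_fails(self):
        fam = CostFamily(
            c_r_direct=lambda r: np.asarray(r, float),
            c_r_forgone=lambda r: 0.1 * np.asarray(r, float),
            c_b_direct=lambda r: np.ones_like(np.asarray(r, float)),
            c_b_forgone=ZERO,
        )
        assert not audit_assumptions(fam)["blow_cost_decreasing"].passed

    def test_structural_checks_reported_satisfied(self, default_family):
        report = audit_assumptions(default_family)
        assert report["additivity"].passed and report["p_independence"].passed

    def test_weighted_slope_check_tightens_with_small_p(self):
        # raw slopes 0.5 < 0.6 pass; weighted by p=0.5 they fail (0.5 > 0.3)
        fam = CostFamily(
            c_r_direct=ZERO,
            c_r_forgone=lambda r: 0.5 * np.asarray(r, float),
            c_b_direct=lambda r: np.exp(-np.asarray(r, float)),
            c_b_forgone=lambda r: 0.6 * (1.0 - np.asarray(r, float)),
        )
        assert audit_assumptions(fam).passed
        assert not audit_assumptions(fam, p_blow=0.5).passed

    def test_small_grid_rejected(self, default_family):
        with pytest.raises(DomainError):
            audit_assumptions(default_family, n_grid=2)


class TestScalingAndRegistry:
    def test_identity_scaling_preserves_cost(self, default_family):
        fam = scale_opportunity(default_family, 1.0)
        r = np.linspace(0, 1, 9)
        np.testing.assert_allclose(
            total_cost(fam, BlowBelief(0.4), r),
            total_cost(default_family, BlowBelief(0.4), r),
        )

    def test_zero_scaling_drops_opportunity_terms(self, default_family):
        fam = scale_opportunity(default_family, 0.0)
        r = np.linspace(0, 1, 9)
        expected = default_family._component("c_r_direct", r) + 0.4 * default_family._component(
            "c_b_direct", r
        )
        np.testing.assert_allclose(total_cost(fam, BlowBelief(0.4), r), expected)

    def test_negative_eta_rejected(self, default_family):
        with pytest.raises(DomainError):
            scale_opportunity(default_family, -0.1)

    def test_unknown_form_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown cost form"):
            make_cost_family("cubic")

    def test_negative_cost_scale_rejected(self):
        with pytest.raises(ConfigurationError):
            make_cost_family("linear", {"s_rd": -1.0})

    def test_linear_form_matches_stated_slopes(self):
        fam = make_cost_family("linear", {"s_rd": 0.4, "s_rf": 0.05, "a_bd": 2.0, "s_bf": 1.0})
        r = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(fam._component("c_r_direct", r), 0.4 * r)
        np.testing.assert_allclose(fam._component("c_b_direct", r), 2.0 * (1 - r))

    def test_serialisation_round_trip(self, rng):
        fam = sample_cost_family(rng)
        clone = family_from_dict(family_to_dict(fam))
        r = np.linspace(0, 1, 17)
        np.testing.assert_allclose(clone.startle_cost(r), fam.startle_cost(r))
        np.testing.assert_allclose(clone.blow_cost(r), fam.blow_cost(r))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**20),
    p_pair=st.tuples(st.floats(0, 1), st.floats(0, 1)),
)
def test_blow_probability_monotonicity_property(seed, p_pair):
    """Raising P(B|X) never lowers the cost-minimising startle magnitude,
    and the solver agrees with a dense grid oracle."""
    rng = np.random.default_rng(seed)
    fam = sample_cost_family(rng)
    assert audit_assumptions(fam).passed
    p_lo, p_hi = sorted(p_pair)
    r_lo = optimal_startle(fam, BlowBelief(p_lo)).r0
    r_hi = optimal_startle(fam, BlowBelief(p_hi)).r0
    assert r_hi >= r_lo - 1e-6
    assert abs(r_hi - grid_oracle(fam, BlowBelief(p_hi))) <= 1.0 / 9_999


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**20),
    p=st.floats(0.15, 1.0),
    eta_pair=st.tuples(st.floats(1.0, 4.0), st.floats(1.0, 4.0)),
)
def test_opportunity_cost_monotonicity_property(seed, p, eta_pair):
    """Raising eta never lowers the minimiser, within the regime where the
    opportunity-slope condition holds in its expectation-weighted form."""
    rng = np.random.default_rng(seed)
    fam = sample_cost_family(rng)
    assert audit_assumptions(fam, p_blow=p).passed
    eta_lo, eta_hi = sorted(eta_pair)
    r_lo = optimal_startle(scale_opportunity(fam, eta_lo), BlowBelief(p)).r0
    r_hi = optimal_startle(scale_opportunity(fam, eta_hi), BlowBelief(p)).r0
    assert r_hi >= r_lo - 1e-6
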