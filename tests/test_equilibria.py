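"""Next-generation numbers, R0, equilibria and the invasion threshold."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wolbsim import (
    ModelParams,
    basic_reproductive_number,
    complete_infection_equilibrium,
    disease_free_equilibrium,
    endemic_equilibrium,
    endemic_ratio,
    equilibrium_report,
    female_infection_fraction,
    next_generation_numbers,
    rhs,
    threshold_female_fraction,
)

from conftest import random_params


def relative_residual(params, state):
    y = state.to_array()
    return np.max(np.abs(rhs(0.0, y, params))) / max(np.max(np.abs(y)), 1.0)


class TestNextGenerationNumbers:
    def test_baseline_values(self, baseline):
        # frozen from hand arithmetic on the defining products
        g0u, g0w = next_generation_numbers(baseline)
        assert g0u == pytest.approx(15.39, abs=0.005)
        assert g0w == pytest.approx(10.54, abs=0.005)

    def test_zero_laying_rate_kills_g0u(self, baseline):
        g0u, _ = next_generation_numbers(baseline.replace(phi_u=1e-300))
        assert g0u == pytest.approx(0.0, abs=1e-290)

    def test_no_transmission_kills_g0w(self, baseline):
        _, g0w = next_generation_numbers(baseline.replace(v_w=0.0))
        assert g0w == 0.0


class TestBasicReproductiveNumber:
    def test_baseline_value(self, baseline):
        assert round(basic_reproductive_number(baseline), 2) == 0.68

    def test_identity_with_next_generation_ratio(self):
        """R0 == G0w/G0u identically across random parameter draws."""
        rng = np.random.default_rng(21)
        for _ in range(100):
            p = random_params(rng)
            g0u, g0w = next_generation_numbers(p)
            assert basic_reproductive_number(p) == pytest.approx(
                g0w / g0u, rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.3, 3.0),
        phi_w=st.floats(0.5, 10.0),
        mu_ratio=st.floats(0.5, 2.0),
        v_w=st.floats(0.1, 1.0),
    )
    def test_identity_holds_across_parameter_space(self, scale, phi_w,
                                                   mu_ratio, v_w):
        """Property: R0 == G0w/G0u wherever parameters are valid, and both
        next-generation numbers are positive whenever v_w > 0."""
        base = ModelParams()
        p = base.replace(phi_w=phi_w, v_w=v_w,
                         delta=base.delta * scale,
                         mu_ew=base.mu_ew * mu_ratio,
                         mu_fw=base.mu_fw * mu_ratio)
        g0u, g0w = next_generation_numbers(p)
        assert g0u > 0 and g0w > 0
        assert basic_reproductive_number(p) == pytest.approx(
            g0w / g0u, rel=1e-12)

    def test_symmetric_cohorts_give_unity(self, baseline):
        p = baseline.replace(mu_fw=baseline.mu_fu, mu_ew=baseline.mu_eu,
                             phi_w=baseline.phi_u, v_w=1.0)
        assert basic_reproductive_number(p) == pytest.approx(1.0, rel=1e-14)


class TestDiseaseFreeEquilibrium:
    def test_baseline_components(self, baseline):
        # frozen from the closed forms; cross-checked by the rhs residual
        dfe = disease_free_equilibrium(baseline)
        assert dfe.L_u == pytest.approx(1.870e5, rel=1e-3)
        assert dfe.F_u == pytest.approx(6.75e4, rel=1e-3)
        assert dfe.M_u == pytest.approx(3.64e4, abs=50)
        assert dfe.E_u == pytest.approx(5.66e5, rel=1e-3)
        assert dfe.L_w == dfe.F_w == dfe.M_w == dfe.E_w == 0.0
        assert relative_residual(baseline, dfe) < 1e-8

    def test_marginal_wild_population_is_empty(self, baseline):
        # tune phi_u so G0u == 1 exactly
        g0u, _ = next_generation_numbers(baseline)
        p = baseline.replace(phi_u=baseline.phi_u / g0u)
        with pytest.warns(UserWarning, match="extinct"):
            dfe = disease_free_equilibrium(p)
        assert dfe.L_u == pytest.approx(0.0, abs=1e-6)

    def test_subcritical_warns_and_returns_origin(self, baseline):
        p = baseline.replace(phi_u=0.01)
        with pytest.warns(UserWarning, match="extinct"):
            dfe = disease_free_equilibrium(p)
        assert np.all(dfe.to_array() == 0.0)


class TestCompleteInfectionEquilibrium:
    def test_baseline_level_and_residual(self, baseline):
        cie = complete_infection_equilibrium(baseline)
        assert cie.L_w == pytest.approx(1.810e5, rel=1e-3)
        assert relative_residual(baseline, cie) < 1e-8

    def test_requires_perfect_transmission(self, baseline):
        with pytest.raises(ValueError, match="endemic_equilibrium"):
            complete_infection_equilibrium(baseline.replace(v_w=0.99))

    def test_marginal_infected_population_is_empty(self, baseline):
        _, g0w = next_generation_numbers(baseline)
        p = baseline.replace(phi_w=baseline.phi_w / g0w)
        with pytest.raises(ValueError, match="persist"):
            complete_infection_equilibrium(p)


class TestEndemicRatio:
    def test_perfect_transmission_linear_case(self, baseline):
        r0 = basic_reproductive_number(baseline)
        roots = endemic_ratio(baseline)
        assert len(roots) == 1
        assert roots[0] == pytest.approx((1 - r0) / r0, rel=1e-12)
        assert roots[0] == pytest.approx(0.460, abs=5e-4)

    def test_r0_one_gives_zero_ratio(self, baseline):
        p = baseline.replace(mu_fw=baseline.mu_fu, mu_ew=baseline.mu_eu,
                             phi_w=baseline.phi_u, v_w=1.0)
        assert endemic_ratio(p) == [0.0]

    def test_imperfect_transmission_quadratic_roots(self, baseline):
        p = baseline.replace(v_w=0.99)
        roots = endemic_ratio(p)
        assert len(roots) == 2
        # residual of the quadratic at each root
        r0 = basic_reproductive_number(p)
        a = (p.v_u / p.v_w) * (p.delta + p.mu_ew) / (p.delta + p.mu_eu)
        for r in roots:
            assert abs(a * r * r + (a - 1) * r + (1 - r0) / r0) < 1e-12
        assert roots[0] == pytest.approx(0.486, abs=5e-4)

    def test_threshold_branch_continuous_at_perfect_transmission(self, baseline):
        """The smaller quadratic root converges to the linear-case ratio as
        v_w -> 1 (the larger root diverges)."""
        r_linear = endemic_ratio(baseline)[0]
        p = baseline.replace(v_w=1 - 1e-8)
        roots = endemic_ratio(p)
        assert roots[0] == pytest.approx(r_linear, abs=1e-6)
        assert roots[1] > 1e6


class TestEndemicEquilibrium:
    def test_residual_and_stage_identities(self, baseline):
        r = endemic_ratio(baseline)[0]
        ee = endemic_equilibrium(baseline, r)
        assert relative_residual(baseline, ee) < 1e-8
        assert ee.E_w / ee.E_u == pytest.approx(r, rel=1e-12)
        assert ee.L_w / ee.L_u == pytest.approx(r, rel=1e-12)

    def test_total_larvae_independent_of_ratio(self, baseline):
        """L_u* + L_w* = K_l (1 - 1/G0w) regardless of the ratio."""
        _, g0w = next_generation_numbers(baseline)
        expected = baseline.K_l * (1 - 1 / g0w)
        for r in (0.2, 0.46, 1.7):
            ee = endemic_equilibrium(baseline, r)
            assert ee.L_u + ee.L_w == pytest.approx(expected, rel=1e-12)

    def test_residuals_across_random_draws(self):
        """All three equilibrium constructors give near-zero vector-field
        residuals for random valid parameters (complete CI, equal male
        rates, supercritical cohorts)."""
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 100:
            p = random_params(rng, v_w=1.0, c_i=1.0, equal_male_rates=True)
            g0u, g0w = next_generation_numbers(p)
            if g0u <= 1.05 or g0w <= 1.05:
                continue
            assert relative_residual(p, disease_free_equilibrium(p)) < 1e-8
            assert relative_residual(p, complete_infection_equilibrium(p)) < 1e-8
            roots = endemic_ratio(p)
            for r in roots:
                if r > 0:
                    assert relative_residual(p, endemic_equilibrium(p, r)) < 1e-8
            checked += 1


class TestThresholdFraction:
    def test_baseline_closed_form(self, baseline):
        thr = threshold_female_fraction(baseline)
        assert thr == pytest.approx(0.3469, abs=5e-4)

    def test_vanishes_as_r0_approaches_one(self, baseline):
        p = baseline.replace(phi_u=baseline.phi_u
                             * basic_reproductive_number(baseline) / 0.999)
        assert threshold_female_fraction(p) < 0.002

    def test_none_when_supercritical(self, baseline):
        p = baseline.replace(phi_u=1.0)  # R0 > 1
        assert basic_reproductive_number(p) > 1
        assert threshold_female_fraction(p) is None

    def test_monotone_increasing_as_r0_decreases(self, baseline):
        """Along the bifurcation diagram's unstable branch the threshold
        rises as the infection becomes less competitive."""
        thresholds = []
        for r0 in (0.9, 0.8, 0.7, 0.6, 0.5, 0.4):
            phi = (baseline.phi_u * basic_reproductive_number(baseline) / r0)
            thresholds.append(threshold_female_fraction(baseline.replace(phi_u=phi)))
        assert all(a < b for a, b in zip(thresholds, thresholds[1:]))


class TestEquilibriumReport:
    def test_report_is_consistent(self, baseline):
        rep = equilibrium_report(baseline)
        assert rep.R0 == pytest.approx(rep.G0w / rep.G0u, rel=1e-12)
        assert rep.stability == {"dfe": "stable", "cie": "stable",
                                 "ee_0": "unstable"}
        assert all(v < 1e-8 for v in rep.residuals().values())
        assert rep.threshold_female_fraction == pytest.approx(
            female_infection_fraction(rep.ee_states[0]), rel=1e-12)
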