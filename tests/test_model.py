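"""Right-hand side, derived fractions and trajectory integration."""

import numpy as np
import pytest

from wolbsim import (
    IntegrationError,
    State,
    adult_infection_fraction,
    complete_infection_equilibrium,
    derived_fractions,
    disease_free_equilibrium,
    female_infection_fraction,
    rhs,
    simulate,
)

from conftest import random_params


class TestDerivedFractions:
    @pytest.mark.parametrize(
        "state, expected_mw, expected_K",
        [
            (State(M_u=100, M_w=100, L_u=5e4, L_w=5e4), 0.5, 0.5),
            (State(M_u=50, M_w=0), 0.0, 1.0),
            (State(M_u=10, M_w=30, L_u=2e5), 0.75, 0.0),
        ],
    )
    def test_fraction_and_capacity(self, baseline, state, expected_mw, expected_K):
        d = derived_fractions(state, baseline)
        assert d.male_infected_fraction == pytest.approx(expected_mw)
        assert d.K == pytest.approx(expected_K)
        assert d.male_uninfected_fraction + d.male_infected_fraction == pytest.approx(1.0)

    def test_no_males_convention(self, baseline):
        d = derived_fractions(State(F_u=10.0), baseline)
        assert d.male_infected_fraction == 0.0
        assert d.male_uninfected_fraction == 1.0


class TestRhs:
    def test_zero_at_disease_free_equilibrium(self, baseline):
        y = disease_free_equilibrium(baseline).to_array()
        residual = np.max(np.abs(rhs(0.0, y, baseline))) / np.max(y)
        assert residual < 1e-8

    def test_no_ci_means_full_uninfected_egg_laying(self, baseline):
        """With c_i = 0 uninfected females lay at phi_u regardless of the
        male infection composition."""
        p = baseline.replace(c_i=0.0)
        y = State(M_w=100.0, F_u=50.0).to_array()  # all males infected
        dEu = rhs(0.0, y, p)[4]
        assert dEu == pytest.approx(p.phi_u * 50.0)

    def test_complete_ci_sterilizes_with_only_infected_males(self, baseline):
        y = State(M_w=100.0, F_u=50.0).to_array()
        dEu = rhs(0.0, y, baseline)  # c_i = 1 at baseline
        assert dEu[4] == pytest.approx(0.0)

    def test_reduces_to_literal_complete_ci_form(self, baseline):
        """At c_i = 1 the generalized uninfected-egg birth term equals the
        literal complete-CI transcription phi_u * Mu/(Mu+Mw) * Fu."""
        rng = np.random.default_rng(7)
        p = baseline
        for _ in range(20):
            y = rng.uniform(1.0, 1e5, size=8)
            y[6:8] = rng.uniform(0, p.K_l / 2, size=2)
            Mu, Mw, Fu, Fw = y[0], y[1], y[2], y[3]
            literal_dEu = (p.phi_u * Mu / (Mu + Mw) * Fu
                           + p.v_u * p.phi_w * Fw
                           - (p.delta + p.mu_eu) * y[4])
            assert rhs(0.0, y, p)[4] == pytest.approx(literal_dEu, rel=1e-14)

    def test_nonfinite_state_raises(self, baseline):
        y = disease_free_equilibrium(baseline).to_array()
        y[0] = np.nan
        with pytest.raises(IntegrationError):
            rhs(0.0, y, baseline)


class TestInfectionFractions:
    def test_symmetric_females(self):
        assert female_infection_fraction(State(F_u=5.0, F_w=5.0)) == 0.5

    def test_complete_infection_state_is_one(self, baseline):
        cie = complete_infection_equilibrium(baseline)
        assert female_infection_fraction(cie) == 1.0
        assert adult_infection_fraction(cie) == 1.0

    def test_empty_population_is_zero(self):
        assert female_infection_fraction(State()) == 0.0
        assert adult_infection_fraction(State()) == 0.0


class TestSimulate:
    def test_dfe_is_fixed_point(self, baseline):
        dfe = disease_free_equilibrium(baseline)
        traj = simulate(baseline, dfe, 1000.0)
        np.testing.assert_allclose(traj.states[-1], dfe.to_array(), rtol=1e-6)

    def test_cie_is_fixed_point(self, baseline):
        cie = complete_infection_equilibrium(baseline)
        traj = simulate(baseline, cie, 1000.0)
        np.testing.assert_allclose(traj.states[-1], cie.to_array(), rtol=1e-6)

    def test_small_introduction_dies_out(self, baseline):
        """R0 < 1 at baseline: the wild population wipes out a one-female
        introduction of the infection."""
        y = disease_free_equilibrium(baseline).to_array()
        y[3] += 1.0
        traj = simulate(baseline, y, 2000.0)
        assert female_infection_fraction(traj.states[-1]) < 1e-6

    def test_nonnegativity_long_run(self, baseline):
        rng = np.random.default_rng(11)
        for _ in range(3):
            y = rng.uniform(0, 1, size=8) * np.array(
                [3e4, 3e4, 6e4, 6e4, 5e5, 5e5, 8e4, 8e4])
            traj = simulate(baseline, y, 1e4)
            assert traj.states.min() >= -1e-9 * np.max(np.abs(y))

    def test_piecewise_equals_single_span(self, baseline):
        """Autonomy: integrating 0->400 equals 0->150 then 150->400."""
        y0 = disease_free_equilibrium(baseline).to_array()
        y0[1] += 0.2 * y0[0]
        y0[3] += 0.2 * y0[2]
        full = simulate(baseline, y0, 400.0)
        first = simulate(baseline, y0, 150.0)
        second = simulate(baseline, first.states[-1], 400.0, t0=150.0)
        np.testing.assert_allclose(second.states[-1], full.states[-1], rtol=1e-6)

    def test_impulse_adds_counts_exactly(self, baseline):
        dfe = disease_free_equilibrium(baseline)
        delta = np.zeros(8)
        delta[1] = delta[3] = 1000.0
        traj = simulate(baseline, dfe, 10.0, impulses=[(5.0, delta)])
        before = traj.value(5.0 - 1e-9)
        # state just after the impulse, from the following segment
        after = traj.segments[-1][2](5.0)
        assert after[3] - before[3] == pytest.approx(1000.0, rel=1e-6)

    def test_larvae_above_capacity_rejected(self, baseline):
        bad = State(L_u=baseline.K_l, L_w=baseline.K_l)
        with pytest.raises(ValueError, match="carrying capacity"):
            simulate(baseline, bad, 10.0)

    def test_random_draws_stay_nonnegative(self, baseline):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = random_params(rng)
            y = rng.uniform(0, 1, 8) * 1e4
            traj = simulate(p, y, 500.0)
            assert traj.states.min() >= -1e-9 * 1e4


class TestTrajectory:
    def test_frame_columns_and_fractions(self, baseline):
        dfe = disease_free_equilibrium(baseline)
        traj = simulate(baseline, dfe, 30.0)
        frame = traj.to_frame()
        assert list(frame.columns) == [
            "t", "Mu", "Mw", "Fu", "Fw", "Eu", "Ew", "Lu", "Lw",
            "frac_female", "frac_adult"]
        assert np.all(frame["frac_female"] == 0.0)
        assert np.all(np.diff(frame["t"]) > 0)
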