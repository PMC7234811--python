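"""Kinetic core: derivatives, stiff integration, algebraic equilibrium."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinbind import (
    MixingCondition,
    RateConstants,
    SpeciesState,
    derivative,
    equilibrium,
    simulate,
)
from kinbind.exceptions import (
    AbsorbingStateWarning,
    DegenerateEquilibriumError,
    InvalidStateError,
)
from kinbind.kinetics import jacobian

ZERO = RateConstants(0, 0, 0, 0, 0, 0)


class TestDerivative:
    def test_null_dynamics(self):
        s = SpeciesState(1e-7, 2e-6, 3e-6, 4e-8, 5e-8)
        assert np.all(derivative(s, ZERO) == 0.0)

    def test_empty_system(self, published_rates):
        s = SpeciesState(1e-7, 0.0, 0.0, 0.0, 0.0)
        assert np.all(derivative(s, published_rates) == 0.0)

    def test_mass_action_encounter_term(self):
        # hand evaluation: with only P* and I* present and all rates but kb
        # zero, d[enc]/dt = kb * P* * I* = 1.5e7 * 1e-7 * 1e-5 = 1.5e-5 M/s
        r = RateConstants(0, 0, 1.5e7, 0, 0, 0)
        s = SpeciesState(1e-7, 0.0, 1e-5, 0.0, 0.0)
        d = derivative(s, r)
        assert d[3] == pytest.approx(1.5e-5, rel=1e-12)
        assert d[0] == pytest.approx(-1.5e-5, rel=1e-12)

    def test_conservation_of_derivatives(self, published_rates):
        s = SpeciesState(3e-8, 1e-6, 2e-6, 5e-8, 2e-8)
        d = derivative(s, published_rates)
        # d/dt of P-containing and I-containing totals both vanish
        # (to rounding in the cancellation of the mass-action terms)
        scale = np.max(np.abs(d))
        assert abs(d[0] + d[3] + d[4]) < 1e-12 * scale
        assert abs(d[1] + d[2] + d[3] + d[4]) < 1e-12 * scale

    def test_non_finite_state_rejected(self, published_rates):
        with pytest.raises(InvalidStateError):
            derivative(np.array([np.nan, 0, 0, 0, 0]), published_rates)

    def test_jacobian_matches_finite_differences(self, published_rates):
        y = np.array([5e-8, 1e-6, 2e-6, 3e-8, 1e-8])
        J = jacobian(y, published_rates)
        eps = 1e-12
        for j in range(5):
            dy = np.zeros(5)
            dy[j] = eps
            fd = (derivative(y + dy, published_rates)
                  - derivative(y - dy, published_rates)) / (2 * eps)
            assert np.allclose(J[:, j], fd, rtol=1e-5, atol=1e-3)


class TestSimulate:
    def test_zero_rates_constant_trajectory(self):
        mix = MixingCondition(1e-7, 1e-5, pre_equilibrated=False)
        t = np.linspace(0, 1, 50)
        traj = simulate(ZERO, mix, t)
        assert np.allclose(traj.states, traj.states[0], atol=1e-15)

    def test_two_state_limit_matches_binding_quadratic(self):
        # kr = k_minusr = 0 and fast pre-equilibrium: long-time encounter
        # complex obeys the single-site depletion quadratic with
        # Kd = k_minusb / kb applied to the competent inhibitor pool.
        r = RateConstants(k1=1e6, k_minus1=1e6, kb=1.5e7, k_minusb=5.0,
                          kr=0.0, k_minusr=0.0)
        P, I = 1e-7, 1e-5
        traj = simulate(r, MixingCondition(P, I), np.linspace(0, 20, 200))
        phi = 0.5
        # the competent fraction rescales the effective dissociation constant:
        # B^2 - (P + I + Kd/phi) B + P I = 0 with the full inhibitor total,
        # because I converts to I* as binding depletes the competent pool
        Kd_eff = r.k_minusb / (r.kb * phi)
        b = P + I + Kd_eff
        Bq = (b - np.sqrt(b * b - 4 * P * I)) / 2
        assert traj["enc"][-1] == pytest.approx(Bq, rel=1e-4)

    def test_long_time_state_reaches_algebraic_equilibrium(self, published_rates):
        P, I = 1e-7, 1e-5
        traj = simulate(published_rates, MixingCondition(P, I),
                        np.linspace(0, 50, 500))
        eq = equilibrium(published_rates, P, I)
        assert np.allclose(traj.states[-1], eq.as_array(), rtol=1e-6,
                           atol=1e-18)

    def test_conservation_along_trajectory(self, published_rates):
        P, I = 1e-7, 2.5e-5
        traj = simulate(published_rates, MixingCondition(P, I),
                        np.linspace(0, 2, 400))
        assert np.max(np.abs(traj.P_total - P)) / P < 1e-6
        assert np.max(np.abs(traj.I_total - I)) / I < 1e-6
        assert traj.states.min() >= -1e-12

    def test_fast_engine_matches_reference(self, published_rates):
        mix = MixingCondition(1e-7, 1e-5)
        t = np.linspace(0, 2, 300)
        ref = simulate(published_rates, mix, t, rtol=1e-10, atol=1e-16)
        fast = simulate(published_rates, mix, t, rtol=1e-9, atol=1e-16,
                        engine="fast")
        assert np.allclose(fast.states, ref.states, rtol=1e-5, atol=1e-14)

    def test_bad_grid_rejected(self, published_rates):
        mix = MixingCondition(1e-7, 1e-5)
        with pytest.raises(InvalidStateError):
            simulate(published_rates, mix, [0.1, 0.2])
        with pytest.raises(InvalidStateError):
            simulate(published_rates, mix, [0.0, 0.2, 0.1])

    def test_pre_equilibrium_relaxation_rate(self):
        # with I <-> I* 100x faster than binding and kr = 0, the encounter
        # complex relaxes at ~ kb * phi * I_total + k_minusb
        r = RateConstants(k1=1.9e5, k_minus1=1.5e5, kb=1.5e7, k_minusb=50.0,
                          kr=0.0, k_minusr=0.0)
        P, I = 1e-9, 1e-5  # P << I: pseudo-first-order
        phi = r.competent_fraction
        k_pred = r.kb * phi * I + r.k_minusb
        t = np.linspace(0, 8.0 / k_pred, 800)
        traj = simulate(r, MixingCondition(P, I), t, rtol=1e-10, atol=1e-18)
        enc = traj["enc"]
        # log-linear fit of the mid-window approach to equilibrium (early
        # points carry the fast exchange mode, late points solver round-off)
        resid = enc[-1] - enc
        mask = (resid > 1e-2 * enc[-1]) & (resid < 0.8 * enc[-1])
        slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
        assert -slope == pytest.approx(k_pred, rel=0.02)


class TestEquilibrium:
    def test_no_kinase_partitions_free_inhibitor(self, published_rates):
        eq = equilibrium(published_rates, 0.0, 1e-5)
        phi = published_rates.competent_fraction
        assert eq.enc == eq.final == 0.0
        assert eq.I_star == pytest.approx(phi * 1e-5, rel=1e-12)
        assert eq.I == pytest.approx((1 - phi) * 1e-5, rel=1e-12)

    def test_two_state_limit_no_final(self):
        r = RateConstants(1e4, 1e4, 1.5e7, 0.5, 0.0, 0.0)
        eq = equilibrium(r, 1e-7, 1e-5)
        assert eq.final == 0.0
        assert eq.enc > 0

    def test_derivative_vanishes_at_equilibrium(self, published_rates):
        eq = equilibrium(published_rates, 1e-7, 1e-5)
        d = derivative(eq, published_rates)
        scale = max(published_rates.as_array()) * 1e-5
        assert np.max(np.abs(d)) < 1e-9 * scale

    def test_detailed_balance(self, published_rates):
        r = published_rates
        eq = equilibrium(r, 1e-7, 1e-5)
        assert r.kb * eq.P_star * eq.I_star == pytest.approx(
            r.k_minusb * eq.enc, rel=1e-6)
        assert r.kr * eq.enc == pytest.approx(r.k_minusr * eq.final, rel=1e-6)

    def test_degenerate_binding_raises(self):
        r = RateConstants(1e4, 1e4, 0.0, 0.5, 0.0, 0.0)
        with pytest.raises(DegenerateEquilibriumError):
            equilibrium(r, 1e-7, 1e-5)

    def test_absorbing_rearrangement_warns(self):
        r = RateConstants(1e4, 1e4, 1.5e7, 0.5, 100.0, 0.0)
        with pytest.warns(AbsorbingStateWarning):
            eq = equilibrium(r, 1e-7, 1e-5)
        assert eq.final == pytest.approx(1e-7)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        k1=st.floats(1e2, 1e6), km1=st.floats(1e2, 1e6),
        kb=st.floats(1e5, 1e9), kmb=st.floats(1e-2, 1e3),
        kr=st.floats(0.0, 1e4), kmr=st.floats(1e-1, 1e4),
        P=st.floats(1e-9, 1e-5), I=st.floats(1e-9, 1e-4),
    )
    def test_equilibrium_properties_hold_generically(
            self, k1, km1, kb, kmb, kr, kmr, P, I):
        r = RateConstants(k1, km1, kb, kmb, kr, kmr)
        eq = equilibrium(r, P, I)
        a = eq.as_array()
        assert np.all(a >= -1e-20)
        assert eq.P_total == pytest.approx(P, rel=1e-9)
        assert eq.I_total == pytest.approx(I, rel=1e-9)
        assert r.kb * eq.P_star * eq.I_star == pytest.approx(
            r.k_minusb * eq.enc, rel=1e-6)
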