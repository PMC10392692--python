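"""Aggregation kinetics: derived rates, ODE/closed-form equivalence, t1/2."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asynsalt.kinetics import (
    KineticParams,
    closed_form_mass,
    derived_rates,
    half_time,
    logistic_mass,
    moment_odes,
)

T_GRID = np.linspace(0.0, 64.0, 257)


def seeded_params(k2kplus, seed_uM=0.05, seed_length=500.0, m0_uM=5.0, n_2=2.0):
    M0 = seed_uM * 1e-6
    return KineticParams(k_n=0.0, k_2=k2kplus, k_plus=1.0, n_2=n_2, n_c=2.0,
                         m0=m0_uM * 1e-6, M0=M0, P0=M0 / seed_length)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(k_2=-1.0)
        with pytest.raises(ValueError):
            KineticParams(n_2=0.5)
        with pytest.raises(ValueError):
            KineticParams(M0=1e-9, P0=0.0)  # seeds carry mass AND number


class TestDerivedRates:
    def test_seeded_limit_of_printed_definitions(self):
        d = derived_rates(seeded_params(1e16))
        assert d.lam == 0.0
        assert d.C_plus == 0.0 and d.C_minus == 0.0
        assert d.k_inf_bar == d.k_inf
        assert d.B_minus == 0.0

    def test_kappa_by_direct_arithmetic(self):
        p = KineticParams(k_n=0.0, k_2=1e4, k_plus=1e4, m0=5e-6, n_2=2.0)
        d = derived_rates(p)
        assert d.kappa == pytest.approx(math.sqrt(2 * 1e8 * (5e-6) ** 3))

    @pytest.mark.parametrize("kn,k2", [(1e-2, 1e15), (1.0, 1e16), (10.0, 3e14)])
    def test_k_inf_bar_at_least_k_inf(self, kn, k2):
        # C+C- = -lam^4/(4 kappa^4) <= 0, so the radicand grows
        d = derived_rates(KineticParams(k_n=kn, k_2=k2, k_plus=1.0, m0=5e-6))
        assert d.k_inf_bar >= d.k_inf


class TestMomentOdes:
    def test_pure_elongation_initial_slope(self):
        p = KineticParams(k_2=0.0, k_plus=1e4, m0=5e-6, M0=1e-8, P0=1e-11)
        t = np.linspace(0, 0.01, 50)
        curve = moment_odes(p, t)
        slope = (curve.M_frac[1] - curve.M_frac[0]) / (t[1] - t[0])
        expected = 2 * p.k_plus * p.m0 * p.P0 / p.m_tot
        assert slope == pytest.approx(expected, rel=1e-3)

    def test_all_rates_zero_is_constant(self):
        p = KineticParams(M0=1e-8, P0=1e-11)
        curve = moment_odes(p, T_GRID)
        assert np.allclose(curve.M_frac, p.M0 / p.m_tot, atol=1e-12)

    def test_mass_fraction_monotone_and_bounded(self):
        curve = moment_odes(seeded_params(1e16), T_GRID)
        assert np.all(np.diff(curve.M_frac) >= -1e-12)
        assert np.all((curve.M_frac >= 0) & (curve.M_frac <= 1))

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            moment_odes(seeded_params(1e16), np.array([0.0, 0.0, 1.0]))


class TestClosedForm:
    def test_initial_condition(self):
        p = seeded_params(1e16)
        curve = closed_form_mass(p, T_GRID)
        assert curve.M_frac[0] == pytest.approx(p.M0 / p.m_tot, abs=1e-9)

    def test_plateau(self):
        curve = closed_form_mass(seeded_params(1e17), np.linspace(0, 640, 100))
        assert curve.M_frac[-1] == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        log_k2kp=st.floats(14.5, 17.5),
        log_seed=st.floats(-3.0, -1.0),
        log_len=st.floats(2.0, 3.0),
    )
    def test_matches_moment_odes_on_seeded_family(self, log_k2kp, log_seed,
                                                  log_len):
        """The exact seeded reduction is the central equivalence oracle."""
        p = seeded_params(10**log_k2kp, seed_uM=10**log_seed,
                          seed_length=10**log_len)
        ode = moment_odes(p, T_GRID)
        cf = closed_form_mass(p, T_GRID)
        assert np.max(np.abs(ode.M_frac - cf.M_frac)) < 1e-4

    def test_pure_elongation_branch(self):
        p = KineticParams(k_2=0.0, k_plus=1e4, m0=5e-6, M0=1e-8, P0=1e-11)
        ode = moment_odes(p, T_GRID)
        cf = closed_form_mass(p, T_GRID)
        assert np.max(np.abs(ode.M_frac - cf.M_frac)) < 1e-6

    def test_unseeded_without_primary_stays_flat(self):
        p = KineticParams(k_2=1e16, k_plus=1.0, m0=5e-6)
        assert np.all(closed_form_mass(p, T_GRID).M_frac == 0.0)


class TestLogisticLaw:
    """The generalized-logistic protocol equation, kept for reference."""

    def test_reduces_to_exact_at_low_seed(self):
        p = seeded_params(1e16, seed_uM=0.001)
        diff = np.max(np.abs(logistic_mass(p, T_GRID).M_frac
                             - moment_odes(p, T_GRID).M_frac))
        assert diff < 0.02  # documented few-percent shape accuracy

    def test_unseeded_primary_secondary_close_to_ode(self):
        p = KineticParams(k_n=1e-2, k_2=1e16, k_plus=1.0, m0=5e-6)
        diff = np.max(np.abs(logistic_mass(p, T_GRID).M_frac
                             - moment_odes(p, T_GRID).M_frac))
        assert diff < 0.02


class TestHalfTime:
    def test_symmetric_logistic_midpoint(self):
        t = np.linspace(0, 10, 401)
        y = 1.0 / (1.0 + np.exp(-(t - 5.0) / 0.4))
        assert half_time(t, y, 0.0, 1.0) == pytest.approx(5.0, abs=1e-3)

    def test_linear_ramp(self):
        t = np.linspace(0, 10, 11)
        assert half_time(t, t / 10.0, 0.0, 1.0) == pytest.approx(5.0)

    def test_noisy_sigmoid_within_one_sample(self, rng):
        t = np.arange(0, 64.25, 0.25)
        y = 1.0 / (1.0 + np.exp(-(t - 8.0) / 0.8))
        y_noisy = y * (1 + 0.01 * rng.standard_normal(len(t)))
        assert abs(half_time(t, y_noisy, 0.0, 1.0) - 8.0) <= 0.25

    def test_flat_trace_returns_none(self):
        t = np.linspace(0, 10, 20)
        assert half_time(t, np.full(20, 0.3)) is None

    def test_monotone_in_rate_product(self):
        """Faster k2*k_plus means earlier half-time, as in the salt series."""
        t_halves = [
            half_time(T_GRID, closed_form_mass(seeded_params(k), T_GRID).M_frac,
                      0.0, 1.0)
            for k in (1e15, 1e16, 1e17)
        ]
        assert t_halves[0] > t_halves[1] > t_halves[2]
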