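"""Structural model: closed form vs ODE oracle, conservation, limits."""

import numpy as np
import pytest
from scipy.integrate import quad

from oracles import ode_conc
from rivapk.pkmodel import (IndivParams, Regimen, conc_profile,
                            conc_single_dose, exposure_ss,
                            steady_state_profile)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        IndivParams(ka=-0.1, cl_f=7.48, v_f=4.75, d1=0.8, alag1=1.2)
    with pytest.raises(ValueError):
        IndivParams(ka=0.1, cl_f=0.0, v_f=4.75, d1=0.8, alag1=1.2)
    with pytest.raises(ValueError):
        Regimen(dose=-5.0)
    with pytest.raises(ValueError):
        Regimen(dose=5.0, interval=0.0)


def test_zero_before_lag(typical_params):
    """No drug reaches the circulation before the absorption lag (1.23 h)."""
    t = np.array([0.0, 0.5, 1.0, 1.2299])
    assert np.all(conc_single_dose(t, 5.0, typical_params) == 0.0)
    assert conc_single_dose(1.0, 5.0, typical_params) == 0.0


def test_matches_ode_oracle_at_random_draws(typical_params):
    """Closed form agrees with stiff ODE integration of the depot/central
    system to 1e-6 relative, over 20 parameter draws x 20 times."""
    rng = np.random.default_rng(42)
    base = np.array([typical_params.ka, typical_params.cl_f, typical_params.v_f,
                     typical_params.d1, typical_params.alag1])
    for _ in range(20):
        p = IndivParams(*(base * np.exp(rng.normal(0.0, 0.5, size=5))))
        times = rng.uniform(0.05, 48.0, size=20)
        for t in times:
            ref = ode_conc(float(t), 5.0, p)
            got = conc_single_dose(float(t), 5.0, p)
            assert got == pytest.approx(ref, rel=1e-6, abs=1e-9)


def test_mass_balance(typical_params):
    """Integral of CL * C(t) over all time returns the full dose to 0.1%."""
    dose = 5.0
    total, _ = quad(lambda t: conc_single_dose(t, dose, typical_params),
                    0.0, 2000.0, limit=500)
    absorbed = total * typical_params.cl_f / 1000.0
    assert absorbed == pytest.approx(dose, rel=1e-3)


def test_linearity_in_dose(typical_params):
    t = np.linspace(0.0, 48.0, 97)
    c1 = conc_single_dose(t, 5.0, typical_params)
    for alpha in (0.0, 0.5, 2.0, 3.7):
        np.testing.assert_allclose(conc_single_dose(t, 5.0 * alpha, typical_params),
                                   alpha * c1, rtol=1e-12, atol=1e-12)


def test_continuity_at_phase_boundaries(typical_params):
    """The profile is continuous across the lag and end-of-input boundaries."""
    p = typical_params
    eps = 1e-9
    for t0 in (p.alag1, p.alag1 + p.d1):
        lo = conc_single_dose(t0 - eps, 5.0, p)
        hi = conc_single_dose(t0 + eps, 5.0, p)
        assert hi == pytest.approx(lo, abs=1e-4)


def test_bolus_limit():
    """d1 -> 0 with large ka tends to the oral-bolus mono-exponential
    (dose/V)*1000*exp(-ke (t - alag))."""
    p = IndivParams(ka=5000.0, cl_f=7.48, v_f=4.75, d1=1e-9, alag1=1.0)
    ke = p.ke
    for t in (1.5, 2.0, 4.0):
        expected = 5.0 / p.v_f * 1000.0 * np.exp(-ke * (t - p.alag1))
        assert conc_single_dose(t, 5.0, p) == pytest.approx(expected, rel=1e-3)


def test_flip_flop_terminal_slope(typical_params):
    """ke = 7.48/4.75 ~ 1.57/h exceeds Ka = 0.140/h, so the terminal
    log-slope reflects absorption (flip-flop kinetics)."""
    p = typical_params
    assert p.ke > p.ka
    c1 = conc_single_dose(60.0, 5.0, p)
    c2 = conc_single_dose(80.0, 5.0, p)
    slope = (np.log(c2) - np.log(c1)) / 20.0
    assert slope == pytest.approx(-p.ka, rel=1e-3)


class TestMultipleDosing:
    def test_single_dose_degenerate(self, typical_params):
        t = np.linspace(0.0, 24.0, 49)
        np.testing.assert_allclose(
            conc_profile(t, Regimen(5.0, 24.0, 1), typical_params),
            conc_single_dose(t, 5.0, typical_params))

    def test_zero_dose(self, typical_params):
        t = np.linspace(0.0, 24.0, 10)
        assert np.all(conc_profile(t, Regimen(0.0, 24.0, 3), typical_params) == 0.0)

    def test_empty_times(self, typical_params):
        out = conc_profile(np.array([]), Regimen(5.0, 24.0, 2), typical_params)
        assert out.size == 0

    def test_superposition_two_doses(self, typical_params):
        """Two doses 24 h apart at t=30 h equal the sum of single-dose values
        at 30 and 6 h, and both match the ODE oracle with two dose events."""
        from oracles import ode_conc_events
        got = conc_profile(np.array([30.0]), Regimen(5.0, 24.0, 2), typical_params)[0]
        manual = (conc_single_dose(30.0, 5.0, typical_params)
                  + conc_single_dose(6.0, 5.0, typical_params))
        ode = ode_conc_events(30.0, [(0.0, 5.0), (24.0, 5.0)], typical_params)
        assert got == pytest.approx(manual, rel=1e-12)
        assert got == pytest.approx(ode, rel=1e-6)


class TestSteadyState:
    def test_matches_brute_force_superposition(self, typical_params):
        grid = np.linspace(0.0, 24.0, 241)
        reg = Regimen(5.0, 24.0, None)
        ss = steady_state_profile(grid, reg, typical_params)
        brute = sum(conc_single_dose(grid + k * 24.0, 5.0, typical_params)
                    for k in range(200))
        np.testing.assert_allclose(ss, brute, rtol=1e-6)

    def test_accumulation(self, typical_params):
        """Steady-state trough is at least the post-first-dose trough."""
        reg = Regimen(5.0, 24.0, None)
        ss_trough = steady_state_profile(np.array([24.0]), reg, typical_params)[0]
        first_trough = conc_single_dose(24.0, 5.0, typical_params)
        assert ss_trough >= first_trough

    def test_long_interval_limit(self, typical_params):
        """With a dosing interval of many half-lives, steady state equals a
        single dose."""
        grid = np.linspace(0.0, 48.0, 97)
        reg = Regimen(5.0, 1000.0, None)
        np.testing.assert_allclose(
            steady_state_profile(grid, reg, typical_params),
            conc_single_dose(grid, 5.0, typical_params), rtol=1e-9, atol=1e-30)

    def test_grid_outside_interval_rejected(self, typical_params):
        with pytest.raises(ValueError):
            steady_state_profile(np.array([25.0]), Regimen(5.0, 24.0, None),
                                 typical_params)


class TestExposure:
    def test_auc_equals_dose_over_clearance(self, typical_params):
        """AUC over one steady-state interval is dose/(CL/F) under linear
        kinetics; the trapezoid integral agrees within 0.5%."""
        em = exposure_ss(Regimen(5.0, 24.0, None), typical_params)
        assert em.auc_ss_24 == pytest.approx(5.0 / typical_params.cl_f, rel=5e-3)
        assert em.auc_ss_24 == pytest.approx(0.6684, rel=5e-3)

    def test_zero_dose(self, typical_params):
        em = exposure_ss(Regimen(0.0, 24.0, None), typical_params)
        assert (em.auc_ss_24, em.cmax_ss) == (0.0, 0.0)

    def test_cmax_grid_convergence(self, typical_params):
        """Cmax is stable to <0.5% under a 5x finer evaluation grid."""
        coarse = exposure_ss(Regimen(10.0, 24.0, None), typical_params)
        fine = exposure_ss(Regimen(10.0, 24.0, None), typical_params,
                           grid_step=0.004)
        assert coarse.cmax_ss == pytest.approx(fine.cmax_ss, rel=5e-3)

    def test_fast_kernel_matches_reference_kernel(self, typical_params):
        """The jitted scalar kernel and the vectorised numpy kernel are the
        same closed form."""
        from rivapk._fastkernel import pair_conc_eval
        from rivapk.pkmodel import _conc_kernel
        rng = np.random.default_rng(3)
        n = 500
        t = rng.uniform(0.0, 48.0, n)
        dose = rng.choice([5.0, 10.0], n)
        ka = rng.lognormal(np.log(0.14), 0.6, n)
        cl = rng.lognormal(np.log(7.48), 0.6, n)
        v = rng.lognormal(np.log(4.75), 0.6, n)
        d1 = rng.lognormal(np.log(0.83), 0.5, n)
        alag = rng.lognormal(np.log(1.23), 0.3, n)
        np.testing.assert_allclose(pair_conc_eval(t, dose, ka, cl, v, d1, alag),
                                   _conc_kernel(t, dose, ka, cl, v, d1, alag),
                                   rtol=1e-12, atol=1e-12)
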