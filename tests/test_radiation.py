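"""Step beams, kill maps, dose accounting, and plan execution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beamopt import (
    FractionPlan,
    GrowthParams,
    RadiationParams,
    StepProfile,
    apply_kill_exponential,
    apply_kill_logistic,
    gaussian_density,
    profile_flux,
    profile_strength,
    run_plan,
    tcp,
)
from beamopt.radiation import BudgetError
from beamopt.tables import reference_fermi, reference_gaussian


class TestStepProfile:
    def test_strength_lookup(self):
        p = StepProfile([(3.16, 2.5)])
        assert profile_strength(p, 1.0) == 2.5
        assert profile_strength(p, 5.0) == 0.0

    def test_two_step_lookup(self):
        # second ring of the reference two-step sigma=3 optimum
        p = StepProfile([(2.81, 2.10), (3.98, 1.06)])
        assert profile_strength(p, 3.5) == 1.06
        assert profile_strength(p, 1.0) == 2.10
        assert profile_strength(p, 4.5) == 0.0

    def test_half_open_boundary_convention(self):
        p = StepProfile([(2.0, 1.5), (4.0, 0.5)])
        assert profile_strength(p, 2.0) == 0.5  # piece [2, 4)
        assert profile_strength(p, 4.0) == 0.0

    def test_flux_budget_saturation(self):
        assert profile_flux(StepProfile([(np.sqrt(10), 2.5)])) == pytest.approx(25.0)
        p = StepProfile([(2.81, 2.10), (3.98, 1.06)])
        assert profile_flux(p) == pytest.approx(
            2.10 * 2.81**2 + 1.06 * (3.98**2 - 2.81**2)
        )
        assert profile_flux(p) == pytest.approx(25.0, rel=2e-2)

    def test_empty_profile(self):
        assert profile_flux(StepProfile([])) == 0.0

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            StepProfile([(3.0, 1.0), (2.0, 1.0)])
        with pytest.raises(ValueError):
            StepProfile([(2.0, -0.5)])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        radii=st.lists(st.floats(0.1, 10.0), min_size=1, max_size=3, unique=True),
        data=st.data(),
    )
    def test_flux_matches_numeric_integral(self, radii, data):
        radii = sorted(radii)
        strengths = [data.draw(st.floats(0, 2.5)) for _ in radii]
        p = StepProfile(list(zip(radii, strengths)))
        r = np.linspace(0, 12, 200001)
        numeric = np.trapezoid(2 * r * np.asarray(p.strength_at(r)), r)
        assert profile_flux(p) == pytest.approx(numeric, rel=1e-3, abs=1e-6)


class TestExponentialKill:
    def test_zero_profile_is_identity(self, gauss3, radiation):
        killed = apply_kill_exponential(gauss3, StepProfile([]), radiation)
        r = np.linspace(0, 10, 31)
        np.testing.assert_allclose(killed.density_at(r), gauss3.density_at(r), rtol=1e-14)

    def test_survival_factor(self, radiation):
        # gamma*dt*f = 60*0.007*2.5 = 1.05
        d = gaussian_density(1e5, 2.0)
        killed = apply_kill_exponential(d, StepProfile([(3.0, 2.5)]), radiation)
        assert killed.density_at(1.0) / d.density_at(1.0) == pytest.approx(
            np.exp(-1.05), rel=1e-12
        )
        assert killed.density_at(5.0) == d.density_at(5.0)

    def test_reference_onestep_outcome(self, gauss1, radiation):
        # cap-saturating beam on the sigma=1 tumour leaves ~3.54e6 cells
        killed = apply_kill_exponential(
            gauss1, StepProfile([(np.sqrt(10), 2.5)]), radiation
        )
        assert killed.total_cells() == pytest.approx(3.54e6, rel=2e-3)

    def test_never_increases_never_negative(self, gauss3, radiation):
        rng = np.random.default_rng(7)
        for _ in range(20):
            radii = np.sort(rng.uniform(0.5, 10, 2))
            strengths = rng.uniform(0, 2.5, 2)
            p = StepProfile(list(zip(radii, strengths)))
            killed = apply_kill_exponential(gauss3, p, radiation)
            r = np.linspace(0, 10, 101)
            post = np.asarray(killed.density_at(r))
            assert np.all(post <= np.asarray(gauss3.density_at(r)) * (1 + 1e-12))
            assert np.all(post >= 0)


class TestLogisticKill:
    def test_carrying_capacity_fixed_point(self, radiation):
        r = np.linspace(0, 10, 33)
        from beamopt import gridded_density

        d = gridded_density(r, np.full(33, 2e5))
        killed = apply_kill_logistic(d, StepProfile([(5.0, 2.5)]), radiation, n_max=2e5)
        np.testing.assert_allclose(killed.density_at(r), 2e5, rtol=1e-9)

    def test_exponential_limit(self, fermi1, radiation):
        p = StepProfile([(3.0, 2.0), (6.0, 1.0)])
        log_killed = apply_kill_logistic(fermi1, p, radiation, n_max=1e12 * 1.46e6)
        exp_killed = apply_kill_exponential(fermi1, p, radiation)
        r = np.linspace(0, 10, 101)
        np.testing.assert_allclose(
            log_killed.density_at(r), exp_killed.density_at(r), rtol=1e-6
        )

    def test_infinite_dose_kills_everything_below_capacity(self, fermi1):
        rad = RadiationParams(gamma=60.0, delta_t=10.0)  # enormous dose
        killed = apply_kill_logistic(fermi1, StepProfile([(10.0, 2.5)]), rad, n_max=1.5e6)
        assert killed.density_at(2.0) < 1e-3 * fermi1.density_at(2.0)

    def test_density_above_capacity_rejected(self, fermi1, radiation):
        with pytest.raises(ValueError):
            apply_kill_logistic(fermi1, StepProfile([(5.0, 1.0)]), radiation, n_max=1e6)

    def test_matches_piecewise_closed_form_on_fermi(self, fermi1, radiation):
        # survival of a Fermi density under piecewise-constant dose:
        # n = a1*nmax*e^{-x} / (a1*(e^{-x}-1) + nmax*(1 + b1*e^{c1 r^2}))
        n_max = 1.5e6
        a1, b1, c1 = fermi1.params.a1, fermi1.params.b1, fermi1.params.c1
        p = StepProfile([(3.0, 2.0), (6.0, 1.0)])
        killed = apply_kill_logistic(fermi1, p, radiation, n_max=n_max)
        r = np.linspace(0, 9.99, 301)
        x = radiation.gamma * radiation.delta_t * np.asarray(p.strength_at(r))
        expected = (
            a1 * n_max * np.exp(-x)
            / (a1 * (np.exp(-x) - 1.0) + n_max * (1.0 + b1 * np.exp(c1 * r**2)))
        )
        np.testing.assert_allclose(killed.density_at(r), expected, rtol=1e-10)

    def test_closed_form_ring_mass_matches_quadrature(self, fermi1, radiation):
        from scipy import integrate

        killed = apply_kill_logistic(
            fermi1, StepProfile([(3.0, 2.0), (5.0, 1.0)]), radiation, n_max=1.5e6
        )
        ref, _ = integrate.quad(
            lambda rr: 2 * np.pi * rr * killed.density_at(rr), 0, 10,
            points=[3, 5], limit=200,
        )
        assert killed.total_cells() == pytest.approx(ref, rel=1e-10)


class TestTCP:
    def test_values(self):
        assert tcp(0.0) == 1.0
        assert tcp(np.log(2)) == pytest.approx(0.5)
        assert tcp(1e7) == 0.0

    def test_monotone_decreasing(self):
        N = np.linspace(0, 50, 21)
        vals = [tcp(x) for x in N]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestRunPlan:
    def test_single_fraction_equals_kill(self, gauss3, radiation):
        p = StepProfile([(3.71, 25 / 3.71**2)])
        plan = FractionPlan([(p, radiation.delta_t, 0.0)])
        events = run_plan(gauss3, plan, radiation, GrowthParams())
        direct = apply_kill_exponential(gauss3, p, radiation).total_cells()
        assert events[-1][2] == pytest.approx(direct, rel=1e-14)

    def test_fraction_order_invariance(self, gauss3, radiation):
        # with no diffusion and tau=0 only the summed dose matters
        p1 = StepProfile([(2.81, 2.10), (3.98, 1.05)])
        p2 = StepProfile([(4.61, 1.07), (5.03, 0.55)])
        g = GrowthParams(D_n=0.0, rho=0.35)
        dt = radiation.delta_t
        N_a = run_plan(gauss3, FractionPlan([(p1, dt, 0.0), (p2, dt, 0.0)]), radiation, g)[-1][2]
        N_b = run_plan(gauss3, FractionPlan([(p2, dt, 0.0), (p1, dt, 0.0)]), radiation, g)[-1][2]
        assert N_a == pytest.approx(N_b, rel=1e-10)

    def test_two_identical_fractions_equal_double_dose(self, gauss3, radiation):
        p = StepProfile([(3.0, 1.0)])
        p2 = StepProfile([(3.0, 2.0)])
        dt = radiation.delta_t
        N_two = run_plan(
            gauss3, FractionPlan([(p, dt, 0.0), (p, dt, 0.0)]), radiation, GrowthParams(rho=0.0)
        )[-1][2]
        N_one = run_plan(gauss3, FractionPlan([(p2, dt, 0.0)]), radiation, GrowthParams(rho=0.0))[-1][2]
        assert N_two == pytest.approx(N_one, rel=1e-12)

    def test_zero_profiles_conserve_N(self, gauss3, radiation):
        plan = FractionPlan([(StepProfile([]), radiation.delta_t, 0.0)] * 2)
        N = run_plan(gauss3, plan, radiation, GrowthParams(rho=0.0))[-1][2]
        assert N == pytest.approx(gauss3.total_cells(), rel=1e-14)

    def test_budget_violation_names_fraction(self, gauss3, radiation):
        over = StepProfile([(5.0, 1.5)])  # flux 37.5 > 25
        plan = FractionPlan([(StepProfile([(3.0, 1.0)]), 0.007, 0.0), (over, 0.007, 0.0)])
        with pytest.raises(BudgetError, match="fraction 2"):
            run_plan(gauss3, plan, radiation, GrowthParams())

    def test_final_N_nonincreasing_in_budget(self, gauss3):
        from beamopt import DiscreteProblem, onestep_optimal

        Ns = []
        for Fp in [10.0, 15.0, 20.0, 25.0, 30.0]:
            rad = RadiationParams(budget_Fprime=Fp)
            res = onestep_optimal(DiscreteProblem(density=gauss3, radiation=rad, n_steps=1))
            Ns.append(res.N_final)
        assert all(a >= b - 1e-6 for a, b in zip(Ns, Ns[1:]))

    def test_growth_between_fractions_scales_outcome(self, gauss3, radiation):
        p = StepProfile([(3.0, 1.0)])
        dt = radiation.delta_t
        g = GrowthParams(D_n=0.0, rho=0.35)
        N_tau = run_plan(
            gauss3, FractionPlan([(p, dt, 1.0), (p, dt, 0.0)]), radiation, g
        )[-1][2]
        N_0 = run_plan(
            gauss3, FractionPlan([(p, dt, 0.0), (p, dt, 0.0)]), radiation, g
        )[-1][2]
        assert N_tau == pytest.approx(N_0 * np.exp(0.35), rel=1e-10)
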