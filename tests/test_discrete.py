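"""Discrete (step-profile) optimisation: stationarity, Monte-Carlo, fractions."""

import numpy as np
import pytest
from scipy import optimize

from beamopt import (
    DiscreteProblem,
    RadiationParams,
    apply_kill_exponential,
    mc_optimize,
    mc_optimize_logistic_death,
    onestep_objective,
    onestep_optimal,
    two_fraction_optimize,
)
from beamopt.tables import reference_fermi, reference_gaussian


def brute_force_onestep(problem, n_grid=2000):
    """Independent oracle: dense scan of the one-step objective + golden polish."""
    rad = problem.radiation
    r_min = np.sqrt(rad.budget_Fprime / rad.cap_C)
    R = problem.density.domain.R
    grid = np.linspace(r_min, R, n_grid)
    vals = np.array([onestep_objective(r, problem) for r in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda r: onestep_objective(r, problem), bounds=(lo, hi), method="bounded",
        options=dict(xatol=1e-10),
    )
    return float(res.x) if res.fun <= vals[i] else float(grid[i])


class TestOneStepObjective:
    def test_cap_boundary_value_sigma1(self, gauss1):
        prob = DiscreteProblem(density=gauss1, n_steps=1)
        N = onestep_objective(np.sqrt(10.0), prob)
        assert N == pytest.approx(3.54e6, rel=2e-3)

    def test_sigma5_reference_value(self):
        prob = DiscreteProblem(density=reference_gaussian(5.0), n_steps=1)
        assert onestep_objective(4.79, prob) == pytest.approx(8.43e6, rel=2e-3)

    def test_zero_budget_leaves_initial_N(self, gauss3):
        rad = RadiationParams(budget_Fprime=1e-12)
        prob = DiscreteProblem(density=gauss3, radiation=rad, n_steps=1)
        assert onestep_objective(5.0, prob) == pytest.approx(
            gauss3.total_cells(), rel=1e-6
        )

    def test_below_cap_feasible_radius_raises(self, gauss3):
        prob = DiscreteProblem(density=gauss3, n_steps=1)
        with pytest.raises(ValueError):
            onestep_objective(1.0, prob)  # f1 = 25 > C


class TestOneStepOptimal:
    @pytest.mark.parametrize(
        "sigma,r1_exp,f1_exp",
        [(3.0, 3.71, 1.82), (4.0, 4.28, 1.36), (5.0, 4.79, 1.09)],
    )
    def test_interior_optima(self, sigma, r1_exp, f1_exp):
        prob = DiscreteProblem(density=reference_gaussian(sigma), n_steps=1)
        res = onestep_optimal(prob)
        (r1, f1), = res.profiles[0].breaks
        assert r1 == pytest.approx(r1_exp, abs=5e-3)
        assert f1 == pytest.approx(f1_exp, abs=5e-3)
        assert res.method == "lagrange"

    def test_cap_bound_optimum_sigma1(self, gauss1):
        res = onestep_optimal(DiscreteProblem(density=gauss1, n_steps=1))
        (r1, f1), = res.profiles[0].breaks
        assert r1 == pytest.approx(np.sqrt(10.0), rel=1e-9)
        assert f1 == pytest.approx(2.5, rel=1e-9)

    @pytest.mark.parametrize("sigma", [1.0, 2.0, 3.0, 4.0, 5.0])
    def test_agrees_with_brute_force_scan(self, sigma):
        prob = DiscreteProblem(density=reference_gaussian(sigma), n_steps=1)
        res = onestep_optimal(prob)
        (r1, _), = res.profiles[0].breaks
        assert r1 == pytest.approx(brute_force_onestep(prob), abs=0.01)

    def test_sqrt_sigma_scaling_law(self):
        sigmas = np.array([3.0, 4.0, 5.0])
        r1s = []
        for s in sigmas:
            res = onestep_optimal(DiscreteProblem(density=reference_gaussian(s), n_steps=1))
            r1s.append(res.profiles[0].breaks[0][0])
        p = np.polyfit(np.log(sigmas), np.log(r1s), 1)[0]
        assert abs(p - 0.5) < 0.1

    def test_N_matches_plan_reevaluation(self, gauss3, radiation):
        res = onestep_optimal(DiscreteProblem(density=gauss3, n_steps=1))
        direct = apply_kill_exponential(gauss3, res.profiles[0], radiation).total_cells()
        assert res.N_final == pytest.approx(direct, rel=1e-10)


class TestMCOptimize:
    def test_two_step_beats_or_matches_one_step(self):
        for sigma in [1.0, 3.0, 5.0]:
            prob1 = DiscreteProblem(density=reference_gaussian(sigma), n_steps=1)
            prob2 = DiscreteProblem(density=reference_gaussian(sigma), n_steps=2)
            N1 = onestep_optimal(prob1).N_final
            N2 = mc_optimize(prob2, n_samples=200_000, seed=5).N_final
            assert N2 <= N1 * (1 + 1e-9)

    def test_seed_reproducibility(self, gauss3):
        prob = DiscreteProblem(density=gauss3, n_steps=2)
        a = mc_optimize(prob, n_samples=20_000, seed=42)
        b = mc_optimize(prob, n_samples=20_000, seed=42)
        assert a.profiles[0].breaks == b.profiles[0].breaks
        assert a.N_final == b.N_final

    def test_single_sample_runs(self, gauss3):
        res = mc_optimize(DiscreteProblem(density=gauss3, n_steps=2), n_samples=1, seed=9)
        assert res.N_final > 0
        assert res.profiles[0].flux() == pytest.approx(25.0, rel=1e-9)

    def test_budget_saturated_at_optimum(self, gauss3):
        res = mc_optimize(DiscreteProblem(density=gauss3, n_steps=2), n_samples=50_000, seed=2)
        assert res.profiles[0].flux() == pytest.approx(25.0, rel=1e-6)
        assert np.all(res.profiles[0].strengths <= 2.5 * (1 + 1e-9))

    def test_N_matches_plan_reevaluation(self, gauss3, radiation):
        res = mc_optimize(DiscreteProblem(density=gauss3, n_steps=2), n_samples=50_000, seed=2)
        direct = apply_kill_exponential(gauss3, res.profiles[0], radiation).total_cells()
        assert res.N_final == pytest.approx(direct, rel=1e-10)

    def test_cap_bound_sigma1_matches_onestep(self, gauss1):
        # when the strength cap binds, the second step adds nothing
        N1 = onestep_optimal(DiscreteProblem(density=gauss1, n_steps=1)).N_final
        N2 = mc_optimize(
            DiscreteProblem(density=gauss1, n_steps=2), n_samples=200_000, seed=3
        ).N_final
        assert N2 == pytest.approx(N1, rel=1e-3)


class TestTwoFractions:
    def test_order_invariance_without_diffusion(self, gauss3, radiation):
        from beamopt import FractionPlan, GrowthParams, run_plan

        prob = DiscreteProblem(
            density=gauss3, n_steps=2, n_fractions=2, constraint_mode="per_fraction"
        )
        res = two_fraction_optimize(prob, n_samples=50_000, seed=6)
        g = GrowthParams(D_n=0.0, rho=0.35)
        dt = radiation.delta_t
        p1, p2 = res.profiles
        N_ab = run_plan(gauss3, FractionPlan([(p1, dt, 0.0), (p2, dt, 0.0)]), radiation, g)[-1][2]
        N_ba = run_plan(gauss3, FractionPlan([(p2, dt, 0.0), (p1, dt, 0.0)]), radiation, g)[-1][2]
        assert N_ab == pytest.approx(N_ba, rel=1e-10)

    def test_first_fraction_matches_single_fraction_outcome(self, gauss1, radiation):
        # sigma=1: the cap binds, so fraction 1 achieves the one-fraction optimum
        prob = DiscreteProblem(
            density=gauss1, n_steps=2, n_fractions=2, constraint_mode="per_fraction"
        )
        res = two_fraction_optimize(prob, n_samples=200_000, seed=8)
        after1 = apply_kill_exponential(gauss1, res.profiles[0], radiation).total_cells()
        assert after1 == pytest.approx(3.54e6, rel=2e-3)

    @pytest.mark.parametrize("sigma", [1.0, 2.0, 3.0, 4.0, 5.0])
    def test_joint_budget_never_worse_than_per_fraction(self, sigma):
        d = reference_gaussian(sigma)
        per = two_fraction_optimize(
            DiscreteProblem(density=d, n_steps=2, n_fractions=2,
                            constraint_mode="per_fraction"),
            n_samples=100_000, seed=13,
        )
        joint = two_fraction_optimize(
            DiscreteProblem(density=d, n_steps=2, n_fractions=2,
                            constraint_mode="total"),
            n_samples=100_000, seed=13,
        )
        assert joint.N_final <= per.N_final * (1 + 1e-9)

    def test_reference_two_fraction_outcome(self, gauss3):
        # separately constrained two-fraction optimum for sigma=3 reaches
        # at least the tabulated quality (5.59e6 cells)
        prob = DiscreteProblem(
            density=gauss3, n_steps=2, n_fractions=2, constraint_mode="per_fraction"
        )
        res = two_fraction_optimize(prob, n_samples=200_000, seed=1)
        assert res.N_final <= 5.59e6 * (1 + 5e-3)


class TestLogisticDeathMC:
    def test_reduces_to_exponential_for_huge_nmax(self, fermi1):
        rad = RadiationParams(death_mode_b=1)
        prob = DiscreteProblem(density=fermi1, radiation=rad, n_max=1e9 * 1.46e6)
        res_log = mc_optimize_logistic_death(prob, n_samples=100_000, seed=3)
        prob_exp = DiscreteProblem(density=fermi1, n_steps=2)
        res_exp = mc_optimize(prob_exp, n_samples=100_000, seed=3)
        assert res_log.N_final == pytest.approx(res_exp.N_final, rel=1e-3)

    def test_ring_shaped_optimum_near_capacity(self, fermi1):
        # flat-topped density just below n_max: dose avoids the saturated
        # centre, inner-step strength collapses to ~0
        rad = RadiationParams(death_mode_b=1)
        prob = DiscreteProblem(density=fermi1, radiation=rad, n_max=1.5e6)
        res = mc_optimize_logistic_death(prob, n_samples=100_000, seed=3)
        (r1, f1), (r2, f2) = res.profiles[0].breaks
        assert f1 < 0.05
        assert f2 > 1.0
        assert r2 > r1 > 1.0
        assert res.profiles[0].flux() == pytest.approx(25.0, rel=1e-6)

    def test_missing_nmax_rejected(self, fermi1):
        rad = RadiationParams(death_mode_b=1)
        with pytest.raises(ValueError):
            mc_optimize_logistic_death(DiscreteProblem(density=fermi1, radiation=rad))

    def test_density_above_capacity_rejected(self, fermi1):
        rad = RadiationParams(death_mode_b=1)
        prob = DiscreteProblem(density=fermi1, radiation=rad, n_max=1e6)
        with pytest.raises(ValueError):
            mc_optimize_logistic_death(prob, n_samples=100, seed=0)
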