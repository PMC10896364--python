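"""Closed-form optimal-control tests: adjoint oracles, budgets, optimality."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from electrotaxis import (
    ExpSum,
    InvalidInputError,
    IsoperimetricSpec,
    ModelParameters,
    StimulusProtocol,
    adjoints_max_distance,
    adjoints_terminal_velocity,
    bang_bang_policy,
    constant_field_solution,
    optimal_field_max_distance,
    optimal_field_max_terminal_velocity,
    posterior_control_ensemble,
    simulate,
    switching_function,
)
from electrotaxis.calibration import PosteriorSamples

from conftest import random_parameter_sets

T = 3.0
BUDGET = 3.0  # normalised: 27 V^2 h / cm^2 at a 3 V/cm reference field


def backward_adjoints(p: ModelParameters, T: float, objective: str):
    """Independent oracle: integrate the costate ODEs backwards from the
    transversality condition with a tight-tolerance ODE solver."""
    ga, al, te, ta = p.gamma, p.alpha, p.tau_e, p.tau_a

    def ode(t, y):
        lv, ls, li = y
        if objective == "distance":
            dlv = -1.0 + ga * lv
            dls = -al * lv + ls / te
        else:  # terminal velocity: objective weight (1 + lv) on the dynamics
            dlv = ga + ga * lv
            dls = -al * (1.0 + lv) + ls / te
        return [dlv, dls, ls / te + li / ta]

    grid = np.linspace(T, 0.0, 201)
    sol = solve_ivp(ode, (T, 0.0), [0.0, 0.0, 0.0], t_eval=grid,
                    rtol=1e-11, atol=1e-13)
    return sol.t[::-1], sol.y[:, ::-1]


class TestExpSum:
    def test_evaluation_and_algebra(self):
        f = ExpSum([2.0, -1.0], [0.0, 1.5], T=2.0)
        t = np.linspace(0.0, 2.0, 7)
        expected = 2.0 - np.exp(1.5 * (t - 2.0))
        assert np.allclose(f(t), expected)
        assert np.allclose((3.0 * f)(t), 3.0 * expected)

    def test_integral_sq_against_quadrature(self):
        from scipy.integrate import quad

        f = ExpSum([1.3, -0.7, 0.2], [0.0, 0.8, 2.5], T=3.0)
        num, _ = quad(lambda t: f(t) ** 2, 0.0, 3.0, epsabs=1e-12)
        assert f.integral_sq() == pytest.approx(num, rel=1e-10)

    def test_solve_linear_terminal_condition(self):
        src = ExpSum([1.0], [2.0], T=1.5)
        lam = src.solve_linear(0.5)
        assert lam(1.5) == pytest.approx(0.0, abs=1e-14)


class TestAdjoints:
    @pytest.mark.parametrize("builder,objective", [
        (adjoints_max_distance, "distance"),
        (adjoints_terminal_velocity, "terminal_velocity"),
    ])
    def test_closed_forms_match_backward_integration(self, builder, objective):
        for p in random_parameter_sets(12, seed=21):
            adj = builder(p, T)
            tt, num = backward_adjoints(p, T, objective)
            for cf, ref in zip((adj.lambda_v, adj.lambda_seff, adj.lambda_I), num):
                scale = np.max(np.abs(ref)) + 1e-12
                assert np.allclose(cf(tt), ref, atol=1e-6 * scale)

    def test_terminal_conditions_vanish(self, params):
        for adj in (adjoints_max_distance(params, T),
                    adjoints_terminal_velocity(params, T)):
            assert adj.lambda_v(T) == pytest.approx(0.0, abs=1e-12)
            assert adj.lambda_seff(T) == pytest.approx(0.0, abs=1e-10)
            assert adj.lambda_I(T) == pytest.approx(0.0, abs=1e-10)

    def test_distance_velocity_costate_value_at_zero(self, params):
        """lambda_v(0) = (1 - e^{-gamma T})/gamma: positive, because velocity
        remaining at the horizon still contributes distance."""
        adj = adjoints_max_distance(params, T)
        ga = params.gamma
        assert adj.lambda_v(0.0) == pytest.approx((1 - np.exp(-ga * T)) / ga,
                                                  rel=1e-12)
        assert adj.lambda_v(0.0) > 0

    def test_terminal_velocity_costate_sign(self, params):
        adj = adjoints_terminal_velocity(params, T)
        assert adj.lambda_v(0.0) == pytest.approx(np.exp(-params.gamma * T) - 1,
                                                  rel=1e-12)
        assert adj.lambda_v(0.0) < 0


@pytest.fixture(scope="module")
def dist_solution(params):
    return optimal_field_max_distance(
        params, IsoperimetricSpec(T=T, s_budget=BUDGET, objective="distance"))


@pytest.fixture(scope="module")
def term_solution(params):
    return optimal_field_max_terminal_velocity(
        params, IsoperimetricSpec(T=T, s_budget=BUDGET,
                                  objective="terminal_velocity"))


class TestIsoperimetricSolutions:
    def test_budget_conservation(self, dist_solution, term_solution):
        for sol in (dist_solution, term_solution):
            assert sol.budget_used == pytest.approx(BUDGET, rel=1e-6)

    def test_mu_star_positive(self, dist_solution, term_solution):
        assert dist_solution.mu_star > 0
        assert term_solution.mu_star > 0

    def test_objective_consistent_with_resimulation(self, params, dist_solution):
        t = dist_solution.t
        s_fun = lambda tt: np.interp(tt, t, dist_solution.S_star)
        traj = simulate(params, s_fun, t, clamp=False)
        assert traj.distance == pytest.approx(dist_solution.objective_value,
                                              rel=1e-3)

    def test_budget_doubling_scales_control_and_distance(self, params,
                                                         dist_solution):
        sol2 = optimal_field_max_distance(
            params, IsoperimetricSpec(T=T, s_budget=2 * BUDGET,
                                      objective="distance"))
        assert np.allclose(sol2.S_star, np.sqrt(2.0) * dist_solution.S_star,
                           rtol=1e-9)
        assert sol2.objective_value == pytest.approx(
            np.sqrt(2.0) * dist_solution.objective_value, rel=1e-6)

    def test_dominates_constant_field(self, dist_solution, term_solution,
                                      params):
        spec_d = IsoperimetricSpec(T=T, s_budget=BUDGET, objective="distance")
        spec_t = IsoperimetricSpec(T=T, s_budget=BUDGET,
                                   objective="terminal_velocity")
        assert dist_solution.objective_value > constant_field_solution(
            params, spec_d).objective_value
        assert term_solution.objective_value > constant_field_solution(
            params, spec_t).objective_value

    @pytest.mark.parametrize("objective", ["distance", "terminal_velocity"])
    def test_first_order_optimality(self, params, objective):
        """Any budget-respecting perturbation of S* lowers the objective."""
        spec = IsoperimetricSpec(T=T, s_budget=BUDGET, objective=objective)
        build = (optimal_field_max_distance if objective == "distance"
                 else optimal_field_max_terminal_velocity)
        sol = build(params, spec, n_grid=241)
        t = sol.t
        rng = np.random.default_rng(42)
        value = lambda tr: tr.distance if objective == "distance" else tr.v[-1]
        for _ in range(20):
            # smooth random variation, renormalised to the exact budget
            freqs = rng.integers(1, 6, size=3)
            coefs = rng.standard_normal(3)
            delta = sum(c * np.sin(np.pi * f * t / T)
                        for c, f in zip(coefs, freqs))
            pert = sol.S_star + 0.05 * delta
            pert *= np.sqrt(BUDGET / np.trapezoid(pert**2, t))
            s_fun = lambda tt: np.interp(tt, t, pert)
            obj = value(simulate(params, s_fun, t, clamp=False, rtol=1e-8))
            assert obj <= sol.objective_value * (1 + 1e-6)

    def test_wrong_objective_rejected(self, params):
        with pytest.raises(InvalidInputError):
            optimal_field_max_distance(
                params, IsoperimetricSpec(objective="terminal_velocity"))


class TestSwitchingAndBangBang:
    def test_switching_vanishes_at_horizon(self, params):
        adj = adjoints_max_distance(params, T)
        assert switching_function(params, adj, T) == pytest.approx(0.0,
                                                                   abs=1e-9)

    def test_switching_positive_before_horizon(self, params):
        adj = adjoints_max_distance(params, T)
        tt = np.linspace(0.0, T - 1e-6, 400)
        assert np.all(adj.switching(tt) > 0)

    def test_switching_matches_finite_difference_hamiltonian(self, params):
        """The relaxed Hamiltonian is linear in s, so a centred difference in
        s recovers tau_e^-1 lambda_seff + tau_a^-1 lambda_I exactly."""
        adj = adjoints_max_distance(params, T)
        te, ta, ga, al = (params.tau_e, params.tau_a, params.gamma,
                          params.alpha)
        state = (12.0, 0.4, 0.6)  # arbitrary (v, s_eff, I)

        def hamiltonian(s, t):
            v, se, inh = state
            return (v + adj.lambda_v(t) * (-ga * v + al * se)
                    + adj.lambda_seff(t) * (s - se - inh) / te
                    + adj.lambda_I(t) * (s - inh) / ta)

        h = 0.25
        for t in (0.0, 1.0, 2.5):
            fd = (hamiltonian(1.0 + h, t) - hamiltonian(1.0 - h, t)) / (2 * h)
            assert fd == pytest.approx(switching_function(params, adj, t),
                                       rel=1e-9)

    def test_policy_is_constant_pulse(self, params):
        proto = bang_bang_policy(params, T=T, s_max=1.0)
        assert len(proto.values) == 1
        assert proto.values[0] == pytest.approx(1.0)
        assert proto.duration == pytest.approx(T)

    def test_zero_bound_gives_zero_protocol(self, params):
        proto = bang_bang_policy(params, T=T, s_max=0.0)
        assert np.all(proto.values == 0.0)

    def test_dominates_random_bounded_protocols(self, params):
        """Random-search oracle: no bounded protocol beats the pulse."""
        s_max = 1.0
        t = np.linspace(0.0, T, 61)
        pulse = simulate(params, bang_bang_policy(params, T, s_max), t,
                         clamp=True)
        rng = np.random.default_rng(17)
        for _ in range(200):
            edges = np.sort(rng.uniform(0.0, T, size=5))
            bp = np.unique(np.concatenate([[0.0], edges, [T]]))
            vals = rng.uniform(0.0, s_max, size=len(bp) - 1)
            rand = simulate(params, StimulusProtocol(bp, vals), t, clamp=True,
                            rtol=1e-6, atol=1e-8)
            assert rand.distance <= pulse.distance * (1 + 1e-6)


class TestPosteriorEnsemble:
    def test_degenerate_posterior_collapses(self, params):
        theta = np.array([params.alpha, params.tau_e, params.tau_a, 3.0])
        samples = PosteriorSamples(draws=np.tile(theta, (2, 30, 1)),
                                   gamma=params.gamma)
        spec = IsoperimetricSpec(T=T, s_budget=BUDGET, objective="distance")
        band = posterior_control_ensemble(samples, spec, n=20, seed=0,
                                          n_grid=241)
        assert np.allclose(band["s_lower"], band["s_upper"], atol=1e-12)
        # the collapsed band is the point solution, satisfying the budget
        used = np.trapezoid(band["s_lower"] ** 2, band["t"])
        assert used == pytest.approx(BUDGET, rel=1e-3)
        sol = optimal_field_max_distance(params, spec, n_grid=241)
        assert np.allclose(band["s_lower"], sol.S_star, rtol=1e-9)

    def test_quantile_nesting(self, small_posterior):
        spec = IsoperimetricSpec(T=T, s_budget=BUDGET, objective="distance")
        inner = posterior_control_ensemble(small_posterior, spec, n=60, seed=4,
                                           quantiles=(0.05, 0.95), n_grid=101)
        outer = posterior_control_ensemble(small_posterior, spec, n=60, seed=4,
                                           quantiles=(0.025, 0.975), n_grid=101)
        assert np.all(outer["v_lower"] <= inner["v_lower"] + 1e-9)
        assert np.all(inner["v_upper"] <= outer["v_upper"] + 1e-9)

    def test_empty_posterior_rejected(self, params):
        samples = PosteriorSamples(draws=np.empty((2, 0, 4)),
                                   gamma=params.gamma)
        with pytest.raises(InvalidInputError):
            posterior_control_ensemble(
                samples, IsoperimetricSpec(objective="distance"), n=5)
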