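import numpy as np
import pytest

from imic import (IMICConfig, SolverError, growth_variability,
                  select_lambda_cv, select_lambda_sensitivity, solve_imic,
                  to_irreversible)
from imic.community import apply_medium
from imic.expression import CorrectionFactors, correction_factors
from imic.fixtures import (FixtureSpec, make_expression, make_kink_toy,
                           make_toy_community)
from imic.solver import default_lambda_grid


class TestConfig:
    def test_lambda_grid_default(self):
        grid = default_lambda_grid()
        assert grid[:4] == [0.1, 0.5, 1.0, 2.0]
        assert grid[-1] == 50.0 and len(grid) == 52

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            IMICConfig(lam=0.0)
        with pytest.raises(ValueError, match="increasing"):
            IMICConfig(lambda_grid=[1.0, 1.0, 2.0])


class TestGrowthLP:
    def test_strong_penalty_keeps_hard_bounds(self, kink_toy, config):
        """At lambda=50 relaxing costs more than the growth it buys."""
        model, factors = kink_toy
        sol = solve_imic(model, factors, config, lam=50.0)
        assert sol.mu["m1"] == pytest.approx(5.0, abs=1e-6)
        assert sol.objective == pytest.approx(5.0, abs=1e-6)
        assert sol.sum_beta == pytest.approx(0.0, abs=1e-8)

    def test_weak_penalty_lifts_bound_to_cap(self, kink_toy, config):
        """At lambda=0.01 the factor is relaxed to its cap of 1."""
        model, factors = kink_toy
        sol = solve_imic(model, factors, config, lam=0.01)
        assert sol.mu["m1"] == pytest.approx(10.0, abs=1e-6)
        assert sol.objective == pytest.approx(9.995, abs=1e-6)
        assert sol.beta_plus["m1::R1"] == pytest.approx(0.5, abs=1e-6)

    def test_uniform_factors_reduce_to_fba(self, chain4, config):
        """With every factor at 1 the LP is plain FBA and beta stays 0."""
        _, model, truth, _ = chain4
        sol = solve_imic(model, None, config, lam=1.0, uniform_factor=1.0)
        assert sol.sum_beta == pytest.approx(0.0, abs=1e-8)
        for member, mu in sol.mu.items():
            assert mu == pytest.approx(truth["max_growth"][member], abs=1e-6)

    def test_solution_satisfies_constraints(self, chain4, chain4_solution,
                                            config):
        _, model, _, factors = chain4
        sol = chain4_solution
        assert np.abs(model.S @ sol.v).max() < 1e-6
        ub = model.upper_bounds
        assert (sol.v >= -1e-8).all() and (sol.v <= ub + 1e-6).all()
        for j, rxn in enumerate(model.reactions):
            key = (rxn.member, rxn.original_id)
            if key not in factors.scaled:
                continue
            s = factors.scaled[key]
            bp = sol.beta_plus[rxn.id]
            bm = sol.beta_minus[rxn.id]
            effective = s + bp - bm
            assert -1e-8 <= effective <= 1 + 1e-8
            assert sol.v[j] <= ub[j] * effective + 1e-6
        assert sol.objective == pytest.approx(
            sol.sum_mu - sol.lam * sol.sum_beta, abs=1e-8)

    def test_infeasible_lambda_rejected(self, kink_toy, config):
        model, factors = kink_toy
        with pytest.raises(ValueError, match="positive"):
            solve_imic(model, factors, config, lam=-1.0)


class TestLambdaSensitivity:
    def test_kink_toy_selects_ten(self, kink_toy, config):
        model, factors = kink_toy
        scan = select_lambda_sensitivity(model, factors, config)
        assert scan.selected == 10.0
        assert scan.method == "sensitivity"
        z = scan.records["z"].to_numpy()
        assert (np.diff(z) <= 1e-9).all()

    def test_kink_follows_transport_capacity(self, config):
        """Shrinking the expression-bounded v_max moves the knee with it."""
        model, profile = make_kink_toy()
        j = model.rxn_index["m1::R1"]
        model.reactions[j].upper_bound = 7.0
        factors = correction_factors(model, profile)
        scan = select_lambda_sensitivity(model, factors, config)
        assert scan.selected == 7.0

    def test_flat_curve_warns_and_returns_smallest(self, kink_toy, config):
        model, _ = kink_toy
        flat = CorrectionFactors(
            "s", raw={("m1", "R1"): 2.0, ("m1", "BIOMASS"): 2.0}, scale=2.0)
        with pytest.warns(UserWarning, match="flat"):
            scan = select_lambda_sensitivity(model, flat, config)
        assert scan.selected == config.lambda_grid[0]

    def test_needs_three_grid_points(self, kink_toy):
        model, factors = kink_toy
        with pytest.raises(ValueError, match="3 grid"):
            select_lambda_sensitivity(model, factors,
                                      IMICConfig(lambda_grid=[1.0, 2.0]))


@pytest.fixture(scope="module")
def community():
    # activities deliberately not aligned with the members' transport
    # capacities, so the fully relaxed (low-lambda) regime mis-ranks them
    spec = FixtureSpec(seed=3, designed_activity=[27.0, 1.0, 9.0, 3.0],
                       expression_sparsity=0.1, noise_sd=0.05)
    model = to_irreversible(make_toy_community(spec)[0])
    acts = dict(zip(spec.member_ids, spec.designed_activity))
    total = sum(acts.values())
    abundances = {}
    factors = {}
    for t in range(4):
        sid = f"s{t + 1}"
        profile = make_expression(spec, sample_id=sid, sample_index=t)
        factors[sid] = correction_factors(model, profile)
        abundances[sid] = {m: a / total for m, a in acts.items()}
    return model, factors, abundances


class TestLambdaCV:
    def test_cv_prefers_expression_constrained_regime(self, community):
        model, factors, abundances = community
        config = IMICConfig(lambda_grid=[0.1, 10.0])
        scan = select_lambda_cv(model, factors, abundances, k=2,
                                config=config, seed=7)
        assert scan.selected == 10.0
        assert scan.method == "cross_validation"

    def test_single_grid_value_is_forced(self, community):
        model, factors, abundances = community
        config = IMICConfig(lambda_grid=[4.0])
        scan = select_lambda_cv(model, factors, abundances, k=2,
                                config=config, seed=1)
        assert scan.selected == 4.0

    def test_leave_one_out_runs_k_folds(self, community):
        model, factors, abundances = community
        config = IMICConfig(lambda_grid=[0.1, 10.0])
        scan = select_lambda_cv(model, factors, abundances, k=4,
                                config=config, seed=1)
        assert scan.selected == 10.0  # mean of 4 identical per-fold bests

    def test_too_many_folds_rejected(self, community):
        model, factors, abundances = community
        with pytest.raises(ValueError, match="folds"):
            select_lambda_cv(model, factors, abundances, k=99,
                             config=IMICConfig(lambda_grid=[1.0]), seed=1)

    def test_seed_is_mandatory(self, community):
        model, factors, abundances = community
        with pytest.raises(ValueError, match="seed"):
            select_lambda_cv(model, factors, abundances, k=2,
                             config=IMICConfig(lambda_grid=[1.0]))

    def test_constant_abundance_sample_excluded(self, community):
        model, factors, abundances = community
        flat = {s: {m: 0.25 for m in model.members} for s in abundances}
        with pytest.warns(UserWarning, match="constant abundance"):
            with pytest.raises(ValueError, match="folds"):
                select_lambda_cv(model, factors, flat, k=2,
                                 config=IMICConfig(lambda_grid=[1.0]), seed=1)


class TestVariability:
    def test_point_solution_contained(self, chain4, chain4_solution, config):
        _, model, _, factors = chain4
        var = growth_variability(model, factors, 10.0,
                                 chain4_solution.objective, config)
        for member, (lo, hi, rel) in var.records.items():
            mu_hat = chain4_solution.mu[member]
            assert lo - 1e-6 <= mu_hat <= hi + 1e-6
            assert 0.0 <= rel <= 1.0

    def test_single_route_has_zero_variability(self, kink_toy, config):
        model, factors = kink_toy
        sol = solve_imic(model, factors, config, lam=50.0)
        var = growth_variability(model, factors, 50.0, sol.objective, config)
        lo, hi, rel = var.records["m1"]
        assert hi - lo == pytest.approx(0.0, abs=1e-5)
        assert rel == pytest.approx(0.0, abs=1e-5)

    def test_zero_growth_member_reports_zero_variability(self, config):
        model, profile = make_kink_toy()
        apply_medium(model, {"EX_a": 0.0})
        factors = correction_factors(model, profile)
        sol = solve_imic(model, factors, config, lam=50.0)
        assert sol.mu["m1"] == pytest.approx(0.0, abs=1e-8)
        var = growth_variability(model, factors, 50.0, sol.objective, config)
        assert var.records["m1"][2] == 0.0

    def test_stale_objective_advises_resolve(self, kink_toy, config):
        model, factors = kink_toy
        with pytest.raises(SolverError, match="stale"):
            growth_variability(model, factors, 50.0, 1e6, config)
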