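import numpy as np
import pandas as pd
import pytest

from imic import (common_reactions, essential_imports,
                  flux_table_from_solutions, key_reactions, knockout_scan,
                  min_flux_sum, solve_imic, to_irreversible)
from imic.community import MemberModel, build_community
from imic.expression import CorrectionFactors, correction_factors
from imic.fixtures import FixtureSpec, make_expression, make_toy_community
from imic.gpr import GprTree


def two_reaction_member(member_id, rxn_ids, with_gpr=()):
    mets = [("s_e", "e"), ("x_c", "c")]
    rxns = [{
        "id": "EX_s", "stoichiometry": {"s_e": -1.0},
        "lower_bound": -10.0, "upper_bound": 1000.0, "gpr": None,
    }]
    for rid in rxn_ids:
        rxns.append({
            "id": rid, "stoichiometry": {"s_e": -1.0, "x_c": 1.0},
            "lower_bound": 0.0, "upper_bound": 10.0,
            "gpr": (GprTree.leaf(f"{member_id}_{rid}")
                    if rid in with_gpr else None),
        })
    rxns.append({
        "id": "BIOMASS", "stoichiometry": {"x_c": -1.0},
        "lower_bound": 0.0, "upper_bound": 1000.0, "gpr": None,
    })
    return MemberModel(member_id=member_id, metabolites=mets, reactions=rxns,
                       biomass_reaction_id="BIOMASS")


class TestFluxSum:
    def test_chain_import_rate(self, kink_toy, config):
        """At lambda=50 the optimum needs 5 units of substrate turnover."""
        model, factors = kink_toy
        sol = solve_imic(model, factors, config, lam=50.0)
        phi = min_flux_sum(model, factors, 50.0, sol.objective, "a_e", config)
        assert phi == pytest.approx(5.0, abs=1e-4)

    def test_no_incident_reactions_is_zero(self, config):
        member = MemberModel(
            "m1", [("a_e", "e"), ("b_c", "c"), ("orphan_c", "c")],
            [{"id": "EX_a", "stoichiometry": {"a_e": -1.0},
              "lower_bound": -10.0, "upper_bound": 1000.0, "gpr": None},
             {"id": "R1", "stoichiometry": {"a_e": -1.0, "b_c": 1.0},
              "lower_bound": 0.0, "upper_bound": 10.0,
              "gpr": GprTree.leaf("g1")},
             {"id": "BIOMASS", "stoichiometry": {"b_c": -1.0},
              "lower_bound": 0.0, "upper_bound": 1000.0, "gpr": None}],
            biomass_reaction_id="BIOMASS")
        model = to_irreversible(build_community([member]))
        factors = CorrectionFactors("s", raw={("m1", "R1"): 1.0}, scale=1.0)
        sol = solve_imic(model, factors, config, lam=1.0)
        with pytest.warns(UserWarning, match="no incident"):
            phi = min_flux_sum(model, factors, 1.0, sol.objective,
                               "m1::orphan_c", config)
        assert phi == 0.0

    def test_production_equals_consumption(self, chain4, chain4_solution):
        _, model, _, _ = chain4
        v = chain4_solution.v
        S = model.S.toarray()
        production = np.clip(S, 0, None) @ v
        consumption = np.clip(-S, 0, None) @ v
        assert np.abs(production - consumption).max() < 1e-6

    def test_raising_the_pinned_objective_never_lowers_phi(self, kink_toy,
                                                           config):
        model, factors = kink_toy
        sol = solve_imic(model, factors, config, lam=2.0)
        phis = [
            min_flux_sum(model, factors, 2.0, frac * sol.objective, "a_e",
                         config)
            for frac in (0.25, 0.5, 0.75, 1.0)
        ]
        assert all(b >= a - 1e-8 for a, b in zip(phis, phis[1:]))


class TestEssentialImports:
    def test_cross_fed_byproducts_are_essential(self, chain4, config):
        _, model, truth, factors = chain4
        result = essential_imports(model, factors, 10.0,
                                   candidates="all_extracellular",
                                   config=config)
        flags = dict(zip(result.table["metabolite"],
                         result.table["essential"]))
        for member in ("m1", "m2", "m3"):  # consumed by the next member
            assert flags[truth["byproducts"][member]]
        assert flags[truth["substrate"]]
        for decoy in truth["decoys"]:
            assert not flags[decoy]
            assert result.classes[decoy] == "never_essential"

    def test_common_import_candidates_are_shared_by_all(self, chain4, config):
        _, model, truth, factors = chain4
        result = essential_imports(model, factors, 10.0,
                                   candidates="common_imports", config=config)
        # only the primary substrate is imported by every member
        assert set(result.table["metabolite"]) == {truth["substrate"]}

    def test_time_classification(self, config):
        """Silencing the terminal member at one time point makes its
        byproduct's turnover time-dependent.

        The terminal member is the right probe: a silenced mid-chain member
        is rescued by the relaxation variables, because lifting its bounds
        also unlocks its downstream consumer's growth, so its byproduct
        keeps turning over. The last member has no consumer, and at
        lambda=12 (above its transport capacity of 10) rescuing it costs
        more than the growth it buys.
        """
        spec = FixtureSpec(seed=5, noise_sd=0.0, expression_sparsity=0.0)
        model = to_irreversible(make_toy_community(spec)[0])
        acts1 = dict(zip(spec.member_ids, spec.designed_activity))
        acts2 = dict(acts1)
        acts2["m4"] = 1e-9  # m4 transcriptionally silent at time point 2
        factors = {
            "s1": correction_factors(
                model, make_expression(spec, acts1, "s1", 0)),
            "s2": correction_factors(
                model, make_expression(spec, acts2, "s2", 1)),
        }
        result = essential_imports(model, factors, 12.0,
                                   candidates="all_extracellular",
                                   config=config)
        assert result.classes["byp_m4_e"] == "time_dependent"
        assert result.classes["sub_e"] == "time_independent"
        assert result.classes["decoy1_e"] == "never_essential"

    def test_relaxed_baseline_flags_subset_of_informative(self, chain4,
                                                          config):
        """Without expression constraints the analysis finds no more
        essential imports than with them (direction-of-effect check)."""
        _, model, _, factors = chain4
        uniform = CorrectionFactors(
            "u", raw={k: 1.0 for k in model.gpr_reactions()}, scale=1.0)
        informative = essential_imports(model, factors, 10.0,
                                        candidates="all_extracellular",
                                        config=config)
        baseline = essential_imports(model, uniform, 10.0,
                                     candidates="all_extracellular",
                                     config=config)

        def essentials(res):
            t = res.table
            return set(t.loc[t["essential"], "metabolite"])

        assert essentials(baseline) <= essentials(informative)


class TestCommonReactions:
    def test_intersection(self):
        a = two_reaction_member("mA", ["r1", "r2", "r3"])
        b = two_reaction_member("mB", ["r2", "r3", "r4"])
        model = build_community([a, b])
        assert set(common_reactions(model)) >= {"r2", "r3"}
        assert "r1" not in common_reactions(model)

    def test_gpr_filter(self):
        a = two_reaction_member("mA", ["r2", "r3"], with_gpr=("r2", "r3"))
        b = two_reaction_member("mB", ["r2", "r3"], with_gpr=("r3",))
        model = build_community([a, b])
        assert "r3" in common_reactions(model, require_gpr=True)
        assert "r2" not in common_reactions(model, require_gpr=True)

    def test_single_member_identity(self):
        a = two_reaction_member("mA", ["r1", "r2"], with_gpr=("r1",))
        model = build_community([a])
        assert set(common_reactions(model)) == {"r1", "r2", "BIOMASS"}
        assert common_reactions(model, require_gpr=True) == ["r1"]


def _synthetic_tables(n_members=14, n_samples=3):
    rng = np.random.default_rng(0)
    members = [f"m{i}" for i in range(n_members)]
    weights = rng.dirichlet(np.ones(n_members))
    flux_rows, ab_rows = [], []
    for t in range(n_samples):
        for j, m in enumerate(members):
            flux_rows.append((f"s{t}", m, "prop", 5.0 * weights[j]))
            flux_rows.append((f"s{t}", m, "anti", 5.0 * (1 - weights[j])))
            flux_rows.append((f"s{t}", m, "flat", 1.0))
            ab_rows.append((f"s{t}", m, weights[j]))
    flux = pd.DataFrame(flux_rows,
                        columns=["sample", "member", "reaction", "net_flux"])
    abundance = pd.DataFrame(ab_rows,
                             columns=["sample", "member", "abundance"])
    return flux, abundance


class TestKeyReactions:
    def test_proportional_flux_is_key_anticorrelated_is_not(self):
        flux, abundance = _synthetic_tables()
        report = key_reactions(flux, abundance)
        assert report.key["prop"] and not report.key["anti"]
        prop = report.table[report.table["reaction"] == "prop"]
        anti = report.table[report.table["reaction"] == "anti"]
        assert prop["rho"].to_numpy() == pytest.approx(1.0)
        assert anti["rho"].to_numpy() == pytest.approx(-1.0)
        assert (prop["p_adj"] >= prop["p"] - 1e-15).all()

    def test_constant_flux_skipped_with_note(self):
        flux, abundance = _synthetic_tables()
        report = key_reactions(flux, abundance)
        assert not report.key["flat"]
        assert (report.skipped["reaction"] == "flat").sum() == 3
        assert "constant" in report.skipped["reason"].iloc[0]

    def test_fewer_than_four_members_rejected(self):
        flux, abundance = _synthetic_tables(n_members=3)
        with pytest.raises(ValueError, match=">= 4 members"):
            key_reactions(flux, abundance)

    def test_abundances_must_sum_to_one(self):
        flux, abundance = _synthetic_tables()
        abundance = abundance.assign(abundance=abundance["abundance"] * 2)
        with pytest.raises(ValueError, match="sum to 1"):
            key_reactions(flux, abundance)

    def test_flux_table_from_solutions(self, chain4, chain4_solution):
        _, model, _, _ = chain4
        table = flux_table_from_solutions(model, {"s1": chain4_solution})
        # every member shares TRANS and the CONV steps, all GPR-bearing
        assert set(table["reaction"]) == {"TRANS", "CONV1", "CONV2", "CONV3"}
        assert set(table["member"]) == set(model.members)


class TestKnockouts:
    def test_dead_reaction_knockout_is_neutral(self, chain4, config):
        _, model, truth, factors = chain4
        table = knockout_scan(model, [truth["dead_reaction"]], factors, 10.0,
                              config).set_index("reaction")
        assert table.loc[truth["dead_reaction"], "delta_sum_mu"] == (
            pytest.approx(0.0, abs=1e-6))

    def test_sole_precursor_knockout_kills_community(self, chain4, config):
        _, model, _, factors = chain4
        table = knockout_scan(model, ["TRANS"], factors, 10.0,
                              config).set_index("reaction")
        assert table.loc["TRANS", "sum_mu_ko"] == pytest.approx(0.0, abs=1e-8)

    def test_unknown_id_reported_and_scan_continues(self, chain4, config):
        _, model, truth, factors = chain4
        table = knockout_scan(model, ["ghost", truth["dead_reaction"]],
                              factors, 10.0, config)
        assert "unknown" in table.iloc[0]["error"]
        assert table.iloc[1]["error"] == ""

    def test_baseline_restored_between_knockouts(self, chain4, config):
        _, model, _, factors = chain4
        before = solve_imic(model, factors, config, lam=10.0)
        knockout_scan(model, ["TRANS", "CONV1"], factors, 10.0, config)
        after = solve_imic(model, factors, config, lam=10.0)
        assert after.objective == pytest.approx(before.objective, abs=1e-9)
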