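import numpy as np
import pytest
from cobra import Metabolite, Model, Reaction

from lp_oracle import network_to_cobra, random_flux_network, vertex_enumeration_max
from methanocom.fluxcalc import (
    FvaSpec,
    detect_infeasible_cycles,
    find_blocked_reactions,
    run_fva,
    solve_fba,
)
from methanocom.synthetic import DEFECT_REACTIONS, ToySpec, cap_bounds, make_toy_methanotroph

CHAIN_REACTIONS = ["EX_ch4_e", "TCH4", "MMO", "MDH", "ASSIM", "BIOMASS"]


class TestSolveFba:
    def test_chain_optimum_carbon_limited(self, chain_model):
        """CH4 uptake 10, yield 0.5: all carbon assimilated gives biomass 5."""
        state = solve_fba(chain_model, extra_bounds=cap_bounds(10, 100, 100))
        assert state.status == "optimal"
        assert state.objective_value == pytest.approx(5.0, abs=1e-6)

    def test_chain_optimum_oxygen_limited(self, chain_model):
        """O2 cap 10 at 2 O2/CH4 allows only 5 CH4: biomass 2.5."""
        state = solve_fba(chain_model, extra_bounds=cap_bounds(10, 10, 100))
        assert state.objective_value == pytest.approx(2.5, abs=1e-6)

    def test_closed_system_zero(self, chain_model):
        closed = {r.id: (0.0, 0.0) for r in chain_model.boundary}
        state = solve_fba(chain_model, extra_bounds=closed)
        assert state.status == "optimal"
        assert state.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_mass_balance_and_bounds_hold(self, chain_model):
        state = solve_fba(chain_model, extra_bounds=cap_bounds(10, 100, 100))
        residuals = state.residuals(chain_model)
        assert max(abs(v) for v in residuals.values()) < 1e-6
        for rxn in chain_model.reactions:
            v = state.fluxes[rxn.id]
            lb, ub = cap_bounds(10, 100, 100).get(rxn.id, rxn.bounds)
            assert lb - 1e-6 <= v <= ub + 1e-6

    def test_infeasible_maintenance_reported(self):
        model = make_toy_methanotroph(ToySpec(ngam=1.0))
        closed = {r.id: (0.0, 0.0) for r in model.boundary}
        state = solve_fba(model, extra_bounds=closed)
        assert state.status == "infeasible"
        assert state.fluxes == {}

    def test_unbounded_objective_reported(self):
        model = Model("loop")
        a = Metabolite("a_c", compartment="c")
        b = Metabolite("b_c", compartment="c")
        r1 = Reaction("R1", lower_bound=-float("inf"), upper_bound=float("inf"))
        r2 = Reaction("R2", lower_bound=-float("inf"), upper_bound=float("inf"))
        model.add_reactions([r1, r2])
        r1.add_metabolites({a: -1, b: 1})
        r2.add_metabolites({b: -1, a: 1})
        state = solve_fba(model, objective_id="R1")
        assert state.status == "unbounded"


class TestVertexOracle:
    def test_fba_matches_enumeration_on_small_networks(self):
        """LP optimum equals brute-force vertex enumeration (20 networks)."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            S, lb, ub, c = random_flux_network(rng)
            expected = vertex_enumeration_max(S, lb, ub, c)
            model = network_to_cobra(S, lb, ub)
            objective = f"R{int(np.argmax(c))}"
            state = solve_fba(model, objective_id=objective)
            assert state.status == "optimal"
            assert state.objective_value == pytest.approx(expected, abs=1e-6)


class TestRunFva:
    def test_ranges_collapse_at_optimum(self, chain_model):
        """A linear chain has a unique routing at the biomass optimum."""
        with chain_model:
            for rid, bounds in cap_bounds(10, 100, 100).items():
                chain_model.reactions.get_by_id(rid).bounds = bounds
            ranges = run_fva(
                chain_model,
                FvaSpec(5.0, "equality", CHAIN_REACTIONS),
            )
        for r in ranges:
            assert r.max_flux - r.min_flux < 1e-6, r

    def test_threshold_zero_allows_zero_flux(self, chain_model):
        ranges = run_fva(chain_model, FvaSpec(0.0, "equality", CHAIN_REACTIONS))
        for r in ranges:
            if chain_model.reactions.get_by_id(r.reaction_id).lower_bound >= 0:
                assert r.min_flux == pytest.approx(0.0, abs=1e-6)

    def test_fva_brackets_fba_solution(self, chain_model):
        """Every optimal FBA flux lies inside its FVA range."""
        with chain_model:
            for rid, bounds in cap_bounds(10, 100, 100).items():
                chain_model.reactions.get_by_id(rid).bounds = bounds
            state = solve_fba(chain_model)
            ranges = run_fva(chain_model, FvaSpec(state.objective_value, "equality"))
        for r in ranges:
            v = state.fluxes[r.reaction_id]
            assert r.min_flux - 1e-6 <= v <= r.max_flux + 1e-6

    def test_planted_reversible_loop_spans_default_bounds(self):
        """With all uptakes closed a reversible duplicate pair circulates freely."""
        model = make_toy_methanotroph(
            ToySpec(planted_defects=frozenset({"duplicate-reaction"}))
        )
        with model:
            for rxn in model.boundary:
                rxn.bounds = (0.0, 0.0)
            model.objective = model.problem.Objective(0)
            ranges = {
                r.reaction_id: r
                for r in run_fva(model, FvaSpec(0.0, "equality", ["DUP1", "DUP2"]))
            }
        for rid in ("DUP1", "DUP2"):
            assert ranges[rid].min_flux == pytest.approx(-1000, rel=1e-6)
            assert ranges[rid].max_flux == pytest.approx(1000, rel=1e-6)

    def test_infeasible_threshold_raises(self, chain_model):
        with chain_model:
            for rxn in chain_model.boundary:
                rxn.bounds = (0.0, 0.0)
            with pytest.raises(ValueError, match="5.0"):
                run_fva(chain_model, FvaSpec(5.0, "equality"))


class TestBlockedReactions:
    def test_orphan_reaction_is_blocked(self):
        model = make_toy_methanotroph(
            ToySpec(planted_defects=frozenset({"orphan-metabolite"}))
        )
        assert find_blocked_reactions(model) == {"ORPH"}

    def test_defect_free_toy_has_none(self, chain_model):
        assert find_blocked_reactions(chain_model) == set()

    def test_stable_under_bound_scaling(self):
        model = make_toy_methanotroph(
            ToySpec(planted_defects=frozenset({"orphan-metabolite"}))
        )
        before = find_blocked_reactions(model)
        for rxn in model.reactions:
            rxn.bounds = (rxn.lower_bound * 2.5, rxn.upper_bound * 2.5)
        assert find_blocked_reactions(model) == before


class TestInfeasibleCycles:
    def test_duplicate_pair_forms_one_group(self):
        model = make_toy_methanotroph(
            ToySpec(planted_defects=frozenset({"duplicate-reaction"}))
        )
        groups = detect_infeasible_cycles(model)
        assert [sorted(g.reaction_ids) for g in groups] == [["DUP1", "DUP2"]]

    def test_opposed_irreversible_pair_detected(self):
        """The ATPase/ATP-synthase shape: two irreversible opposed reactions."""
        model = make_toy_methanotroph(
            ToySpec(planted_defects=frozenset({"futile-loop"}))
        )
        groups = detect_infeasible_cycles(model)
        assert [sorted(g.reaction_ids) for g in groups] == [["FUT1", "FUT2"]]

    def test_loop_free_chain_is_clean(self, chain_model):
        assert detect_infeasible_cycles(chain_model) == []

    def test_groups_are_disjoint_and_signed(self, defect_model):
        groups = detect_infeasible_cycles(defect_model)
        all_ids = [rid for g in groups for rid in g.reaction_ids]
        assert len(all_ids) == len(set(all_ids))
        expected = set(DEFECT_REACTIONS["futile-loop"]) | set(
            DEFECT_REACTIONS["duplicate-reaction"]
        )
        assert set(all_ids) == expected
        for group in groups:
            assert group.signature
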