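import itertools

import pytest

from methanocom.community import (
    InhibitionParams,
    NutrientCondition,
    apply_formaldehyde_inhibition,
    biomass_split_envelope,
    build_community,
    compute_inhibition_R,
    pool_balance_residuals,
    solve_fixed_ratio,
    solve_optcom,
    verify_inner_optimality,
)
from methanocom.fluxcalc import solve_fba
from methanocom.synthetic import (
    SHARED_METABOLITES,
    ToySpec,
    cap_bounds,
    make_toy_community,
    make_toy_methanotroph,
)

RICH = NutrientCondition("rich", 10, 100, 100)


class TestBuildCommunity:
    def test_link_variable_pairs(self, asymmetric_pair):
        """Two members x five shared metabolites -> ten link pairs."""
        for mid in ("A", "B"):
            for sid in SHARED_METABOLITES:
                up = asymmetric_pair.model.reactions.get_by_id(
                    asymmetric_pair.uptake_link(mid, sid)
                )
                ex = asymmetric_pair.model.reactions.get_by_id(
                    asymmetric_pair.export_link(mid, sid)
                )
                assert up.lower_bound == 0 and ex.lower_bound == 0

    def test_directionality_inherited_from_member(self, asymmetric_pair):
        """CO2 was export-only in the member, so its uptake link is shut."""
        up = asymmetric_pair.model.reactions.get_by_id(
            asymmetric_pair.uptake_link("A", "co2_e")
        )
        assert up.upper_bound == 0

    def test_unknown_shared_id_raises(self):
        members = [make_toy_methanotroph(ToySpec(), "A")]
        with pytest.raises(ValueError, match="unobtanium_e"):
            build_community(members, {"ch4_e", "unobtanium_e"})

    def test_single_member_community_equals_fba(self):
        """A one-member community with pool pass-through is plain FBA."""
        spec = ToySpec(biomass_yield_per_ch4=0.5, o2_per_ch4=2.0)
        member = make_toy_methanotroph(spec, "solo")
        community = build_community([member], set(SHARED_METABOLITES))
        solution = solve_optcom(community, RICH)
        standalone = solve_fba(member, extra_bounds=cap_bounds(10, 100, 100))
        assert solution.total_biomass == pytest.approx(
            standalone.objective_value, abs=1e-6
        )
        assert solution.inner_optimality_certified == {"solo": True}


class TestInhibitionR:
    def test_zero_offset(self):
        assert compute_inhibition_R(1, 7) == pytest.approx(1 / 7)

    def test_onset_offset(self):
        assert compute_inhibition_R(1, 7, "onset-offset") == pytest.approx(1 / 6)

    def test_no_inhibition_limit(self):
        assert compute_inhibition_R(1, 1e9) == pytest.approx(0.0, abs=1e-8)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            compute_inhibition_R(7, 1)
        with pytest.raises(ValueError):
            InhibitionParams(c_min=7, c_max=7)


class TestInhibitionConstraint:
    def _community(self):
        community = make_toy_community(
            ToySpec(biomass_yield_per_ch4=1.0, formaldehyde_uptake_enabled=True),
            ToySpec(),
        )
        apply_formaldehyde_inhibition(community, "A", InhibitionParams())
        return community

    def test_member_without_uptake_rejected(self):
        community = make_toy_community(ToySpec(), ToySpec())
        with pytest.raises(ValueError, match="formaldehyde uptake"):
            apply_formaldehyde_inhibition(community, "A", InhibitionParams())

    def test_unset_vmax_instructs_to_solve_first(self):
        community = make_toy_community(
            ToySpec(formaldehyde_uptake_enabled=True), ToySpec()
        )
        params = InhibitionParams(v_maxbiomass=None)
        with pytest.raises(ValueError, match="uninhibited"):
            apply_formaldehyde_inhibition(community, "A", params)

    def test_zero_uptake_not_binding(self):
        community = self._community()
        solution = solve_optcom(community, RICH)
        assert solution.link_values["uptake"][("A", "hcho_e")] == pytest.approx(
            0.0, abs=1e-9
        )
        assert solution.member_biomass["A"] == pytest.approx(
            solution.inhibition_vmax["A"], abs=1e-6
        )

    def test_total_inhibition_at_uptake_seven(self):
        """R = 1/7 and uptake 7 close the growth window entirely."""
        community = self._community()
        forced = {
            "U__hcho_e": (7.0, 7.0),
            community.uptake_link("A", "hcho_e"): (7.0, 7.0),
        }
        solution = solve_optcom(community, RICH, extra_bounds=forced)
        assert solution.status == "optimal"
        assert solution.member_biomass["A"] == pytest.approx(0.0, abs=1e-6)

    def test_intermediate_uptake_halves_the_bound(self):
        """uptake 3.5 with v_max 10: biomass capped at 5.0 exactly."""
        community = self._community()
        forced = {
            "U__hcho_e": (3.5, 3.5),
            community.uptake_link("A", "hcho_e"): (3.5, 3.5),
            # methane sized so the uninhibited optimum is v_max = 10
        }
        condition = NutrientCondition("sized", 10, 100, 100)
        solution = solve_optcom(community, condition, extra_bounds=forced)
        assert solution.inhibition_vmax["A"] == pytest.approx(10.0, abs=1e-6)
        assert solution.member_biomass["A"] == pytest.approx(5.0, abs=1e-6)


class TestSolveOptcom:
    def test_identical_members_split_degenerate(self):
        community = make_toy_community(
            ToySpec(biomass_yield_per_ch4=0.5, o2_per_ch4=2.0),
            ToySpec(biomass_yield_per_ch4=0.5, o2_per_ch4=2.0),
        )
        solution = solve_optcom(community, RICH)
        assert solution.total_biomass == pytest.approx(5.0, abs=1e-6)
        envelope = biomass_split_envelope(community, RICH, solution.total_biomass)
        for mid in ("A", "B"):
            lo, hi = envelope[mid]
            assert lo == pytest.approx(0.0, abs=1e-6)
            assert hi == pytest.approx(5.0, abs=1e-6)

    def test_better_member_takes_all(self, asymmetric_pair):
        solution = solve_optcom(asymmetric_pair, RICH)
        assert solution.total_biomass == pytest.approx(6.0, abs=1e-6)
        assert solution.member_biomass["A"] == pytest.approx(6.0, abs=1e-6)
        assert solution.link_values["uptake"][("B", "ch4_e")] == pytest.approx(
            0.0, abs=1e-6
        )

    def test_zero_caps_zero_biomass(self, asymmetric_pair):
        solution = solve_optcom(
            asymmetric_pair, NutrientCondition("nothing", 0, 0, 0)
        )
        assert solution.status != "optimal" or solution.total_biomass == pytest.approx(
            0.0, abs=1e-9
        )

    def test_zero_caps_infeasible_with_maintenance(self):
        community = make_toy_community(ToySpec(ngam=1.0), ToySpec(ngam=1.0))
        solution = solve_optcom(community, NutrientCondition("nothing", 0, 0, 0))
        assert solution.status == "infeasible"

    def test_cross_feeding_strictly_helps(self):
        """Recovering the secreter's formaldehyde beats exporting it."""
        secretor = ToySpec(
            biomass_yield_per_ch4=0.6, formaldehyde_secretion_fraction=0.2
        )
        with_uptake = make_toy_community(
            ToySpec(biomass_yield_per_ch4=0.4, formaldehyde_uptake_enabled=True),
            secretor,
        )
        without_uptake = make_toy_community(
            ToySpec(biomass_yield_per_ch4=0.4), secretor
        )
        best = solve_optcom(with_uptake, RICH).total_biomass
        base = solve_optcom(without_uptake, RICH).total_biomass
        assert base == pytest.approx(4.8, abs=1e-6)
        assert best == pytest.approx(5.6, abs=1e-6)

    def test_pool_conservation(self, asymmetric_pair):
        solution = solve_optcom(asymmetric_pair, RICH)
        residuals = pool_balance_residuals(asymmetric_pair, solution)
        assert set(residuals) == set(SHARED_METABOLITES)
        assert max(abs(v) for v in residuals.values()) < 1e-6

    def test_monotone_in_every_cap(self, asymmetric_pair):
        """Total biomass is non-decreasing in each supply cap."""
        grid = [5.0, 10.0, 20.0]
        totals = {}
        for ch4, o2, n2 in itertools.product(grid, repeat=3):
            sol = solve_optcom(
                asymmetric_pair,
                NutrientCondition("g", ch4, o2, n2),
                certify=False,
            )
            totals[(ch4, o2, n2)] = sol.total_biomass
        for axis in range(3):
            for point in itertools.product(range(len(grid)), repeat=3):
                if point[axis] == 0:
                    continue
                lower = list(point)
                lower[axis] -= 1
                a = totals[tuple(grid[i] for i in lower)]
                b = totals[tuple(grid[i] for i in point)]
                assert b >= a - 1e-6

    def test_bounded_by_sum_of_standalone_optima(self, asymmetric_pair):
        solution = solve_optcom(asymmetric_pair, RICH)
        standalone = sum(
            solve_fba(member, extra_bounds=cap_bounds(10, 100, 100)).objective_value
            for member in asymmetric_pair.members.values()
        )
        assert solution.total_biomass <= standalone + 1e-6


class TestInnerOptimality:
    def test_solutions_certify(self, asymmetric_pair):
        solution = solve_optcom(asymmetric_pair, RICH)
        assert all(solution.inner_optimality_certified.values())

    def test_wasteful_solution_fails(self, asymmetric_pair):
        """A member reporting less biomass than its links allow is flagged."""
        solution = solve_optcom(asymmetric_pair, RICH)
        solution.member_biomass["A"] -= 1.0
        verdict = verify_inner_optimality(asymmetric_pair, solution)
        assert verdict["A"] is False or verdict["A"] == False  # noqa: E712
        assert verdict["B"]

    def test_single_member_certificate_is_fba_optimality(self):
        member = make_toy_methanotroph(ToySpec(), "solo")
        community = build_community([member], set(SHARED_METABOLITES))
        solution = solve_optcom(community, RICH)
        assert solution.inner_optimality_certified == {"solo": True}


class TestFixedRatio:
    @pytest.mark.parametrize("ratio", [9.3, 0.05])
    def test_ratio_honored(self, asymmetric_pair, ratio):
        solution = solve_fixed_ratio(asymmetric_pair, RICH, ratio)
        assert solution.status == "optimal"
        assert solution.member_biomass["A"] == pytest.approx(
            ratio * solution.member_biomass["B"], abs=1e-6
        )

    def test_equal_ratio_on_identical_members(self):
        community = make_toy_community(ToySpec(), ToySpec())
        solution = solve_fixed_ratio(community, RICH, 1.0)
        assert solution.member_biomass["A"] == pytest.approx(
            solution.member_biomass["B"], abs=1e-6
        )

    def test_never_exceeds_unconstrained_optimum(self, asymmetric_pair):
        free = solve_optcom(asymmetric_pair, RICH).total_biomass
        for ratio in (9.3, 1.0, 0.05):
            constrained = solve_fixed_ratio(asymmetric_pair, RICH, ratio)
            assert constrained.total_biomass <= free + 1e-6

    def test_invalid_ratio(self, asymmetric_pair):
        with pytest.raises(ValueError):
            solve_fixed_ratio(asymmetric_pair, RICH, -1.0)
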