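"""Monoculture FBA and the community growth/FVA solver."""

import pytest

from camp import (
    InfeasibleError,
    NutrientCondition,
    apply_community_condition,
    apply_condition,
    build_pair_community,
    fba,
    self_pair,
    solve_steadycom,
    steadycom_fva,
)
from camp.steadycom import CommunityLP
from camp.synthetic import FIXTURE_MEDIUM, crossfeed_auxotroph, crossfeed_donor, homofermenter

from oracles import brute_force_flux_extreme, grid_search_mu

# Hand-solved optimum of the homofermenter LP under glucose -1 (closed
# xylose): 2 ATP per glucose, maintenance 0.36, growth costs 10 ATP
# -> mu = (2 - 0.36) / 10, with lactate carrying the remaining redox.
HOMO_MU_GLC = (2.0 - 0.36) / 10.0


class TestFba:
    def test_homofermenter_matches_hand_solution(self, minimal):
        model = homofermenter()
        apply_condition(model, minimal.restricted_to({"EX_glc_D(e)"}),
                        FIXTURE_MEDIUM)
        mu, fluxes = fba(model)
        assert mu == pytest.approx(HOMO_MU_GLC, abs=1e-9)
        assert fluxes["EX_lac_D(e)"] == pytest.approx(2.0 - HOMO_MU_GLC,
                                                      abs=1e-9)

    def test_all_uptakes_closed_is_zero_growth(self):
        model = homofermenter()
        condition = NutrientCondition(
            "closed", {"EX_glc_D(e)": 0.0, "EX_xyl_D(e)": 0.0},
            atpm_flux=0.0)
        apply_condition(model, condition)
        mu, _ = fba(model)
        assert mu == pytest.approx(0.0, abs=1e-9)

    def test_unmeetable_maintenance_is_infeasible(self):
        model = homofermenter()
        condition = NutrientCondition(
            "starved", {"EX_glc_D(e)": 0.0, "EX_xyl_D(e)": 0.0})
        apply_condition(model, condition)  # ATPM clamped at 0.36, no carbon
        with pytest.raises(InfeasibleError):
            fba(model)


class TestSolveSteadycom:
    def test_identical_pair_recovers_monoculture_growth(
            self, homo_self_community, minimal):
        model = homofermenter()
        apply_condition(model, minimal, FIXTURE_MEDIUM)
        mono_mu, _ = fba(model)
        solution = solve_steadycom(homo_self_community)
        assert solution.mu == pytest.approx(mono_mu, abs=1e-4)

    def test_abundances_normalised(self, hetero_homo_solution):
        total = sum(hetero_homo_solution.abundances.values())
        assert total == pytest.approx(1.0, abs=1e-6)
        assert all(x >= -1e-9
                   for x in hetero_homo_solution.abundances.values())

    def test_member_growth_is_mu_times_abundance(self, hetero_homo_solution):
        s = hetero_homo_solution
        for member, x in s.abundances.items():
            assert s.member_growth[member] == pytest.approx(s.mu * x,
                                                            abs=1e-9)

    def test_biomass_coupling_holds(self, hetero_homo_community,
                                    hetero_homo_solution):
        cm, s = hetero_homo_community, hetero_homo_solution
        for member, bio in cm.biomass_ids.items():
            assert s.fluxes[bio] == pytest.approx(
                s.mu * s.abundances[member], abs=1e-6)

    def test_no_carbon_means_zero_growth(self):
        donor = crossfeed_donor()
        aux = crossfeed_auxotroph()
        cm = build_pair_community(donor, aux)
        condition = NutrientCondition(
            "closed", {"EX_glc_D(e)": 0.0, "EX_xyl_D(e)": 0.0},
            atpm_flux=0.0)
        apply_community_condition(cm, condition, FIXTURE_MEDIUM)
        assert solve_steadycom(cm).mu == pytest.approx(0.0, abs=1e-5)

    def test_bisection_matches_grid_oracle(self, hetero_homo_community):
        mu = solve_steadycom(hetero_homo_community).mu
        oracle = grid_search_mu(hetero_homo_community, step=1e-3)
        assert abs(mu - oracle) <= 2e-3

    def test_feasibility_monotone_at_optimum(self, hetero_homo_community):
        cm = hetero_homo_community
        mu = solve_steadycom(cm).mu
        lp = CommunityLP(cm)
        eps = 1e-5
        assert lp.max_total_abundance(mu - eps) >= 1.0 - 1e-9
        assert lp.max_total_abundance(mu + eps) < 1.0 - 1e-9

    def test_dead_member_carries_no_flux(self, minimal):
        # donor and homofermenter compete for glucose only; the donor's
        # lower ATP yield excludes it at the optimum
        cm = build_pair_community(
            crossfeed_donor(atp_per_glucose=1.0), homofermenter())
        apply_community_condition(
            cm, minimal.restricted_to({"EX_glc_D(e)"}), FIXTURE_MEDIUM)
        solution = solve_steadycom(cm)
        dead = min(solution.abundances, key=solution.abundances.get)
        assert solution.abundances[dead] == pytest.approx(0.0, abs=1e-6)
        for rid in cm.member_reactions[dead]:
            assert solution.fluxes[rid] == pytest.approx(0.0, abs=1e-5)

    def test_scaling_member_capacity_leaves_growth_unchanged(self, minimal):
        mus = []
        for scale in (1.0, 2.0):
            model = homofermenter()
            for rid in ("glc_Dt", "lac_Dt"):
                rxn = model.reactions.get_by_id(rid)
                rxn.bounds = (rxn.lower_bound * scale,
                              rxn.upper_bound * scale)
            cm = self_pair(model)
            apply_community_condition(cm, minimal, FIXTURE_MEDIUM)
            mus.append(solve_steadycom(cm).mu)
        assert mus[0] == pytest.approx(mus[1], abs=1e-5)


class TestFva:
    def test_range_is_ordered_and_contains_solution_flux(
            self, hetero_homo_community, hetero_homo_solution):
        cm, s = hetero_homo_community, hetero_homo_solution
        rng = steadycom_fva(cm, cm.product_exchange_id, s.mu)
        assert rng.minimum <= rng.maximum
        assert rng.minimum - 1e-6 <= s.fluxes[cm.product_exchange_id] \
            <= rng.maximum + 1e-6

    def test_obligate_pair_biomass_range_degenerate(
            self, donor_auxotroph_community):
        """With obligate cross-feeding the abundance split is unique, so
        each member's biomass flux range collapses to mu * X_k."""
        cm = donor_auxotroph_community
        solution = solve_steadycom(cm)
        for member, bio in cm.biomass_ids.items():
            rng = steadycom_fva(cm, bio, solution.mu)
            expected = solution.mu * solution.abundances[member]
            assert rng.minimum == pytest.approx(expected, abs=1e-5)
            assert rng.maximum == pytest.approx(expected, abs=1e-5)

    def test_product_max_matches_abundance_brute_force(
            self, hetero_homo_community, hetero_homo_solution):
        cm, s = hetero_homo_community, hetero_homo_solution
        rng = steadycom_fva(cm, cm.product_exchange_id, s.mu)
        oracle = brute_force_flux_extreme(
            cm, cm.product_exchange_id, s.mu, "max")
        assert rng.maximum == pytest.approx(oracle, abs=1e-4)
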