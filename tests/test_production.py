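"""Yield bookkeeping, robustness scenarios, metabolic distance, ranking."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from camp import (
    NutrientCondition,
    apply_community_condition,
    build_pair_community,
    efficiency_scenarios,
    expected_yield,
    jaccard_distance,
    monoculture_yield,
    observed_yield,
    rank_communities,
    solve_steadycom,
    ten_fold_candidate,
)
from camp.synthetic import (
    FIXTURE_MEDIUM,
    Route,
    atp_chassis,
    crossfeed_auxotroph,
    homofermenter,
)

HOMO_MU_GLC = (2.0 - 0.36) / 10.0  # hand-solved (see test_steadycom)


class TestMonocultureYield:
    def test_homofermenter_hand_value(self, homo, minimal):
        my = monoculture_yield(homo, minimal, "EX_lac_D(e)", FIXTURE_MEDIUM)
        # all glucose carbon not in biomass leaves as lactate
        assert my.product_max == pytest.approx(2.0 - HOMO_MU_GLC, abs=1e-6)
        assert my.substrate_uptake == pytest.approx(1.0, abs=1e-6)
        assert my.yield_value == pytest.approx(2.0 - HOMO_MU_GLC, abs=1e-6)

    def test_non_viable_model_excluded(self, minimal):
        assert monoculture_yield(crossfeed_auxotroph(), minimal,
                                 "EX_lac_D(e)", FIXTURE_MEDIUM) is None

    def test_missing_product_yields_zero_with_warning(self, minimal):
        model = atp_chassis("nolac", [Route("glc_D", 2.0)])
        with pytest.warns(UserWarning, match="absent"):
            my = monoculture_yield(model, minimal, "EX_lac_D(e)",
                                   FIXTURE_MEDIUM)
        assert my.yield_value == 0.0


class TestExpectedYield:
    def test_printed_formula(self):
        assert expected_yield(10, 5, 1.8, 0.9) == pytest.approx(22.5)
        assert expected_yield(0, 0, 1.8, 0.9) == 0.0
        assert expected_yield(10, 5, 0, 0) == 0.0

    def test_normalised_mode(self):
        assert expected_yield(10, 5, 1.8, 0.9, normalize=True) == \
            pytest.approx(22.5 / 15)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            expected_yield(-1, 0, 0, 0)

    def test_candidacy_inclusive_and_monotone(self):
        assert ten_fold_candidate(10.0, 1.0) is True  # exactly 10-fold
        assert ten_fold_candidate(9.999, 1.0) is False
        assert ten_fold_candidate(11.0, 1.0) is True


class TestObservedYield:
    def test_identity_pair_matches_monoculture(self, homo_self_community,
                                               minimal):
        mono = monoculture_yield(homofermenter(), minimal, "EX_lac_D(e)",
                                 FIXTURE_MEDIUM)
        solution = solve_steadycom(homo_self_community)
        obs = observed_yield(homo_self_community, solution.mu)
        assert obs.moi == pytest.approx(mono.yield_value, abs=1e-6)

    def test_member_uptakes_sum_to_total(self, hetero_homo_community,
                                         hetero_homo_solution):
        obs = observed_yield(hetero_homo_community, hetero_homo_solution.mu)
        assert sum(obs.member_uptake.values()) == \
            pytest.approx(obs.total_uptake, abs=1e-5)


class TestEfficiencyScenarios:
    def test_obligate_lactate_secretor_fails_crossfeed_block(
            self, hetero_homo_community):
        # the homofermenter cannot re-oxidise NADH without lactate export
        result = efficiency_scenarios(hetero_homo_community)
        assert result.scenario_pass["no_crossfeed_homo"] is False
        assert result.overall is False

    def test_amino_acid_fallbacks_pass_all_scenarios(self, minimal):
        a = atp_chassis("gena", [
            Route("glc_D", 4.0, {"lac_D": 1.0}),
            Route("arg_L", 3.0, {"orn": 1.0}),
        ])
        b = atp_chassis("genb", [
            Route("glc_D", 2.0, {"lac_D": 1.0}),
            Route("glu_L", 3.0),
        ])
        cm = build_pair_community(a, b, product_exchange="EX_lac_D(e)")
        apply_community_condition(cm, minimal, FIXTURE_MEDIUM)
        result = efficiency_scenarios(cm)
        assert result.overall is True
        assert all(result.scenario_pass.values())


class TestJaccard:
    @pytest.mark.parametrize("a,b,expected", [
        ({"x", "y"}, {"x", "y"}, 0.0),
        ({"x"}, {"y"}, 1.0),
        ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
    ])
    def test_closed_forms(self, a, b, expected):
        assert jaccard_distance(a, b) == pytest.approx(expected)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            jaccard_distance(set(), set())

    @given(st.sets(st.integers(0, 12), max_size=8),
           st.sets(st.integers(0, 12), max_size=8),
           st.sets(st.integers(0, 12), max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_metric_properties(self, a, b, c):
        sets = [s or {99} for s in (a, b, c)]  # avoid the empty-set domain
        a, b, c = sets
        dab = jaccard_distance(a, b)
        assert 0.0 <= dab <= 1.0
        assert dab == jaccard_distance(b, a)
        assert (dab == 0.0) == (a == b)
        assert dab <= jaccard_distance(a, c) + jaccard_distance(c, b) + 1e-12


class TestRanking:
    def test_both_maxima_rank_first_with_unit_score(self):
        ranked = rank_communities([
            (("a", "b"), 0.1, 1.0),
            (("c", "d"), 0.2, 3.0),
        ])
        assert ranked[0].pair == ("c", "d")
        assert ranked[0].score == pytest.approx(1.0)

    def test_all_equal_cohort_breaks_ties_lexicographically(self):
        ranked = rank_communities([
            (("c", "d"), 0.1, 1.0),
            (("a", "b"), 0.1, 1.0),
        ])
        assert [r.pair for r in ranked] == [("a", "b"), ("c", "d")]
        assert all(r.score == pytest.approx(1.0) for r in ranked)

    def test_dominated_record_ranks_last(self):
        ranked = rank_communities([
            (("a", "b"), 0.3, 2.0),
            (("c", "d"), 0.2, 3.0),
            (("e", "f"), 0.1, 1.0),  # dominated on both axes
        ])
        assert ranked[-1].pair == ("e", "f")

    def test_order_invariant_to_affine_rescaling(self):
        records = [(("a", "b"), 0.1, 2.0), (("c", "d"), 0.25, 1.0),
                   (("e", "f"), 0.18, 3.0)]
        scaled = [(p, 100 * mu + 7, 0.5 * moi - 2 + 2)
                  for p, mu, moi in records]
        scaled = [(p, mu, moi + 2) for p, mu, moi in scaled]  # keep moi >= 0
        base = [r.pair for r in rank_communities(records)]
        assert [r.pair for r in rank_communities(scaled)] == base

    def test_empty_and_singleton(self):
        assert rank_communities([]) == []
        only = rank_communities([(("a", "b"), 0.1, 1.0)])
        assert only[0].score == pytest.approx(1.0)
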