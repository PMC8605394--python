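"""Enforced-flux scanning and deletion testing on community models."""

import pytest

from camp import (
    apply_community_condition,
    deletion_sets,
    evaluate_deletions,
    fseof_scan,
    select_strategies,
    self_pair,
    solve_steadycom,
    steadycom_fva,
)
from camp.knockout import KnockoutResult
from camp.synthetic import FIXTURE_MEDIUM, homofermenter


class TestFseofScan:
    def test_acetate_branch_in_candidates(self, hetero_homo_community):
        scan = fseof_scan(hetero_homo_community)
        assert "hetero__ACKr" in scan.candidates
        assert "hetero__PTAr" in scan.candidates
        assert "hetero__PFL" in scan.candidates

    def test_lactate_branch_is_amplification_target(
            self, hetero_homo_community):
        scan = fseof_scan(hetero_homo_community)
        assert "hetero__LDH_D" in scan.amplification_targets
        assert not scan.candidates & scan.amplification_targets

    def test_candidates_exclude_protected_reactions(
            self, hetero_homo_community):
        cm = hetero_homo_community
        scan = fseof_scan(cm)
        protected = set(cm.biomass_ids.values()) | set(cm.atpm_ids.values())
        for transfers in cm.transfer_ids.values():
            protected |= set(transfers.values())
        protected |= set(cm.community_exchange_ids.values())
        assert not scan.candidates & protected

    def test_levels_strictly_increasing(self, hetero_homo_community):
        scan = fseof_scan(hetero_homo_community)
        levels = scan.enforced_levels
        assert all(b > a for a, b in zip(levels, levels[1:]))
        assert all(
            p[0] > p[-1] for rid, p in scan.flux_profiles.items()
            if rid in scan.candidates
        )

    def test_sole_sink_community_gives_empty_scan(self, minimal):
        # the homofermenter's only fermentation product is lactate, so
        # there is no competing flux to attenuate
        cm = self_pair(homofermenter(), product_exchange="EX_lac_D(e)")
        apply_community_condition(cm, minimal, FIXTURE_MEDIUM)
        scan = fseof_scan(cm)
        assert scan.empty
        assert scan.candidates == frozenset()


class TestDeletionSets:
    def test_threshold_rule(self):
        ids = [f"r{i:02d}" for i in range(30)]
        sets = deletion_sets(ids)
        assert len([s for s in sets if len(s) == 1]) == 30
        assert len([s for s in sets if len(s) == 2]) == 435
        ids31 = ids + ["r30"]
        assert all(len(s) == 1 for s in deletion_sets(ids31))
        assert len(deletion_sets(ids31)) == 31


class TestEvaluateDeletions:
    def test_acetate_branch_deletion_improves_lactate(
            self, hetero_homo_community):
        results = evaluate_deletions(
            hetero_homo_community, ["hetero__ACKr", "hetero__PTAr"])
        assert len(results) == 3  # two singles + one double
        for result in results:
            assert result.viable
            assert result.improved
            assert result.mutant_product_flux > \
                result.wildtype_product_flux + 1e-6

    def test_deletion_restricts_feasible_set(self, hetero_homo_community):
        cm = hetero_homo_community
        results = evaluate_deletions(cm, ["hetero__ACKr"])
        mutant = results[0]
        wt_at_mutant_mu = steadycom_fva(
            cm, cm.product_exchange_id, mutant.mutant_mu).maximum
        assert mutant.mutant_product_flux <= wt_at_mutant_mu + 1e-6

    def test_order_independent(self, hetero_homo_community):
        forward = evaluate_deletions(
            hetero_homo_community, ["hetero__ACKr", "hetero__PTAr"])
        reverse = evaluate_deletions(
            hetero_homo_community, ["hetero__PTAr", "hetero__ACKr"])
        assert [r.deleted_reactions for r in forward] == \
            [r.deleted_reactions for r in reverse]
        assert [r.mutant_product_flux for r in forward] == \
            pytest.approx([r.mutant_product_flux for r in reverse], abs=1e-6)

    def test_lethal_deletion_recorded_not_raised(self, hetero_homo_community):
        # deleting lower glycolysis in both members leaves no ATP source
        # for the maintenance demand
        results = evaluate_deletions(
            hetero_homo_community, ["hetero__GAPD", "homo__EMP"])
        double = [r for r in results if len(r.deleted_reactions) == 2]
        assert double and not double[0].viable
        assert not double[0].improved


class TestSelectStrategies:
    def _result(self, ids, flux, viable=True, improved=True):
        return KnockoutResult(frozenset(ids), 0.1, flux, viable, improved,
                              1.0)

    def test_filters_and_sorts(self):
        results = [
            self._result({"a"}, 2.0),
            self._result({"b", "c"}, 3.0),
            self._result({"d"}, 3.0),
            self._result({"e"}, 5.0, viable=False, improved=False),
        ]
        chosen = select_strategies(results)
        assert [sorted(r.deleted_reactions) for r in chosen] == [
            ["d"], ["b", "c"], ["a"]]  # equal flux: single beats double

    def test_no_improvement_gives_empty_list(self):
        results = [self._result({"a"}, 0.5, improved=False)]
        assert select_strategies(results) == []

    def test_best_strategy_dominates(self, hetero_homo_community):
        results = evaluate_deletions(hetero_homo_community, ["hetero__ACKr"])
        chosen = select_strategies(results)
        if chosen:
            top = chosen[0].mutant_product_flux
            assert all(top >= r.mutant_product_flux for r in chosen)
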