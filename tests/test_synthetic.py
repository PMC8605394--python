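"""Generated toy models: archetypes, interaction pairs, seeded panels."""

import pytest

from camp import (
    NutrientCondition,
    monoculture_growth,
    save_model,
)
from camp.exceptions import FixtureSpecError
from camp.synthetic import (
    CARBON,
    FIXTURE_MEDIUM,
    FixtureSpec,
    INTERACTION_LABELS,
    Route,
    atp_chassis,
    crossfeed_auxotroph,
    heterofermenter,
    homofermenter,
    make_fixture,
    make_interaction_pair,
    make_panel,
)

XYLOSE_ONLY = NutrientCondition(
    "xylose_only", {"EX_glc_D(e)": 0.0, "EX_xyl_D(e)": -1.0})
CLOSED = NutrientCondition(
    "closed", {"EX_glc_D(e)": 0.0, "EX_xyl_D(e)": 0.0}, atpm_flux=0.0)


class TestArchetypes:
    @pytest.mark.parametrize("archetype", [
        "homofermenter_glc", "heterofermenter_glc_xyl",
        "crossfeed_donor", "crossfeed_auxotroph",
    ])
    def test_build_and_carbon_closure(self, archetype, minimal):
        model = make_fixture(FixtureSpec(archetype))
        # closed medium: no carbon in, so no growth and no product
        assert monoculture_growth(model, CLOSED) == pytest.approx(0.0,
                                                                  abs=1e-9)
        with model as m:
            for rxn in m.exchanges:
                rxn.lower_bound = 0.0
            m.objective = "EX_lac_D(e)" if "EX_lac_D(e)" in m.reactions \
                else list(m.exchanges)[0].id
            assert m.slim_optimize(error_value=0.0) == pytest.approx(
                0.0, abs=1e-9)

    def test_homofermenter_max_lactate_stoichiometry(self, homo):
        # at glucose uptake 1 with growth off, both pyruvate and both
        # NADH go to D-lactate: maximal lactate flux 2
        with homo as m:
            m.reactions.get_by_id("EX_glc_D(e)").lower_bound = -1.0
            m.reactions.get_by_id("EX_xyl_D(e)").lower_bound = 0.0
            m.objective = "EX_lac_D(e)"
            assert m.slim_optimize() == pytest.approx(2.0, abs=1e-6)

    def test_xylose_use_mirrors_pentose_capability(self, homo, hetero):
        assert monoculture_growth(hetero, XYLOSE_ONLY, FIXTURE_MEDIUM) > 0.01
        assert monoculture_growth(homo, XYLOSE_ONLY,
                                  FIXTURE_MEDIUM) == pytest.approx(0.0)

    def test_auxotroph_needs_acetate(self, minimal):
        aux = crossfeed_auxotroph()
        assert monoculture_growth(aux, minimal, FIXTURE_MEDIUM) == 0.0
        with_acetate = NutrientCondition(
            "acetate_fed",
            {"EX_glc_D(e)": 0.0, "EX_xyl_D(e)": 0.0, "EX_ac(e)": -1.0})
        assert monoculture_growth(aux, with_acetate, FIXTURE_MEDIUM) > 0.1

    def test_unknown_archetype_rejected(self):
        with pytest.raises(FixtureSpecError):
            make_fixture(FixtureSpec("chemolithotroph"))

    def test_route_carbon_overflow_rejected(self):
        with pytest.raises(FixtureSpecError):
            atp_chassis("bad", [Route("for", 1.0, {"ac": 1.0})])


class TestInteractionPairs:
    @pytest.mark.parametrize("label", INTERACTION_LABELS)
    def test_pair_round_trips_requested_label(self, label):
        model_a, model_b, condition = make_interaction_pair(label)
        # make_interaction_pair validates end-to-end and raises otherwise
        assert model_a.id.startswith(label)
        assert condition.substrate_bounds["EX_glc_D(e)"] == -1.0

    def test_unknown_label_rejected(self):
        with pytest.raises(FixtureSpecError):
            make_interaction_pair("symbiosis")


class TestPanel:
    def test_panel_size_and_pair_count(self):
        models = make_panel(10, seed=3)
        assert len(models) == 10
        assert len({m.id for m in models}) == 10
        from camp import iter_pairs
        assert len(list(iter_pairs(models))) == 45

    def test_same_seed_byte_identical_sbml(self, tmp_path):
        for run in ("a", "b"):
            for model in make_panel(4, seed=11):
                save_model(model, tmp_path / f"{run}_{model.id}.xml")
        for model_id in [m.id for m in make_panel(4, seed=11)]:
            assert (tmp_path / f"a_{model_id}.xml").read_bytes() == \
                (tmp_path / f"b_{model_id}.xml").read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        a = make_panel(4, seed=1)
        b = make_panel(4, seed=2)
        assert any(
            {r.id: r.bounds for r in m1.reactions} !=
            {r.id: r.bounds for r in m2.reactions} or
            m1.reactions.query(lambda r: True) and
            _stoich(m1) != _stoich(m2)
            for m1, m2 in zip(a, b)
        )

    def test_panel_members_grow_under_minimal(self, minimal):
        for model in make_panel(8, seed=5):
            assert monoculture_growth(model, minimal, FIXTURE_MEDIUM) > 0.01

    def test_too_small_panel_rejected(self):
        with pytest.raises(FixtureSpecError):
            make_panel(1)


def _stoich(model):
    return {r.id: {m.id: c for m, c in r.metabolites.items()}
            for r in model.reactions}


class TestCarbonTable:
    def test_core_reactions_carbon_balanced(self, hetero):
        """Every non-drain reaction conserves carbon per the fixture
        carbon table (currency metabolites are carbon-free)."""
        drains = {"BIOMASS", "ATPM"}
        carbon_free = {"atp", "adp", "nad", "nadh", "coa"}
        for rxn in hetero.reactions:
            if rxn.id in drains or rxn in hetero.exchanges:
                continue
            balance = 0.0
            for met, coef in rxn.metabolites.items():
                base = met.id.rsplit("(", 1)[0]
                if base in carbon_free:
                    continue
                balance += coef * CARBON[base]
            assert balance == pytest.approx(0.0, abs=1e-9), rxn.id
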