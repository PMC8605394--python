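"""Programmatic toy metabolic models for desk-scale pipeline testing.

Two families of fixtures:

* **Fermenter chassis** — small redox-coupled networks emulating lactic
  acid bacteria.  The homofermenter runs a lumped Embden-Meyerhof-Parnas
  (EMP) route where every NADH produced in glycolysis must be reoxidised
  by D-lactate dehydrogenase, so lactate secretion is stoichiometrically
  tied to sugar uptake.  The heterofermenter runs the phosphoketolase
  route (glucose -> ribulose-5-P -> xylulose-5-P -> acetyl-P +
  glyceraldehyde-3-P) with the classic mixed-acid branches: acetate via
  phosphotransacetylase/acetate kinase (substrate-level ATP), ethanol and
  acetaldehyde as NADH sinks, formate via pyruvate formate-lyase.  The
  acetate kinase carries a finite capacity, which keeps the optimum
  non-degenerate: lactate has a genuine flux range at maximal growth and
  knocking out the acetate branch re-routes carbon towards lactate.

* **ATP-accounting chassis** — linear "catabolic route" models in which
  each substrate is converted to ATP (plus carbon-balanced byproducts) and
  biomass is built from ATP alone.  Community optima of these models are
  solvable by hand, which makes it possible to author species pairs whose
  co-culture outcome realises any requested interaction type.

All fixtures use VMH-style identifiers (``EX_glc_D(e)``, ``ATPM``, Table-1
reaction names such as ``ACKr``, ``PTAr``, ``PFL``, ``RPE``,
``XU5PG3PL``), carry exchanges for both glucose and xylose even when they
cannot catabolise one of them, and are carbon-balanced in their core
reactions (ATP/ADP, NAD/NADH and CoA are carbon-free carriers; biomass
and ATPM are drains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from cobra import Model, Metabolite, Reaction

from .community import apply_community_condition, build_pair_community
from .exceptions import FixtureSpecError
from .io import NutrientCondition, monoculture_growth

__all__ = [
    "FixtureSpec",
    "CARBON",
    "make_fixture",
    "make_interaction_pair",
    "make_panel",
    "homofermenter",
    "heterofermenter",
    "crossfeed_donor",
    "crossfeed_auxotroph",
    "atp_chassis",
    "fixture_condition",
    "FIXTURE_MEDIUM",
    "INTERACTION_LABELS",
]

#: Carbon atoms per metabolite base id (currency carriers are carbon-free
#: by convention; orn stands in for the ornithine released by the
#: arginine-deiminase-like route).
CARBON: Dict[str, int] = {
    "glc_D": 6, "xyl_D": 5, "lac_D": 3, "ac": 2, "etoh": 2, "acald": 2,
    "for": 1, "co2": 1, "arg_L": 6, "glu_L": 5, "orn": 5, "pyr": 3,
    "ru5p": 5, "xu5p": 5, "g3p": 3, "accoa": 2, "actp": 2,
}

#: Medium (beyond the sugar substrates) used with fixture models: two
#: amino-acid exchanges serve as the non-sugar nutrient components.
FIXTURE_MEDIUM = frozenset({"EX_arg_L(e)", "EX_glu_L(e)"})

INTERACTION_LABELS = (
    "mutualism", "competition", "parasitism",
    "commensalism", "amensalism", "neutralism",
)

_GAM = 10.0  # growth-associated ATP demand (mmol ATP per unit biomass flux)


def fixture_condition(name: str = "minimal", **kw) -> NutrientCondition:
    """The standard nutrient conditions as used with fixture models."""
    if name == "minimal":
        return NutrientCondition.minimal(**kw)
    if name == "excess":
        return NutrientCondition.excess(**kw)
    raise ValueError(f"unknown fixture condition {name!r}")


# ---------------------------------------------------------------------------
# low-level builder


class _Builder:
    """Incremental construction of a toy model with VMH-style ids."""

    def __init__(self, model_id: str):
        self.model = Model(model_id)
        self._mets: Dict[str, Metabolite] = {}

    def met(self, met_id: str, compartment: str) -> Metabolite:
        key = f"{met_id}({compartment})"
        if key not in self._mets:
            m = Metabolite(key, compartment=compartment)
            self._mets[key] = m
            self.model.add_metabolites([m])
        return self._mets[key]

    def rxn(self, rxn_id: str, stoich: Mapping[Metabolite, float],
            lb: float = 0.0, ub: float = 1000.0) -> Reaction:
        r = Reaction(rxn_id, lower_bound=lb, upper_bound=ub)
        r.add_metabolites(dict(stoich))
        self.model.add_reactions([r])
        return r

    def exchange(self, base: str, lb: float = -1000.0,
                 ub: float = 1000.0) -> None:
        """Exchange + reversible transport for a species (e <-> c)."""
        e, c = self.met(base, "e"), self.met(base, "c")
        self.rxn(f"EX_{base}(e)", {e: -1.0}, lb, ub)
        self.rxn(f"{base}t", {e: -1.0, c: 1.0}, -1000.0, 1000.0)

    def currency(self) -> Tuple[Metabolite, Metabolite]:
        return self.met("atp", "c"), self.met("adp", "c")

    def redox(self) -> Tuple[Metabolite, Metabolite]:
        return self.met("nad", "c"), self.met("nadh", "c")

    def atpm(self) -> None:
        atp, adp = self.currency()
        self.rxn("ATPM", {atp: -1.0, adp: 1.0}, 0.0, 1000.0)

    def biomass(self, extra: Optional[Mapping[Metabolite, float]] = None,
                gam: float = _GAM) -> None:
        atp, adp = self.currency()
        stoich: Dict[Metabolite, float] = {atp: -gam, adp: gam}
        if extra:
            for met, coef in extra.items():
                stoich[met] = stoich.get(met, 0.0) + coef
        r = self.rxn("BIOMASS", stoich, 0.0, 1000.0)
        self.model.objective = r

    def build(self) -> Model:
        return self.model


def _carbon_filler(consumed: Mapping[str, float],
                   produced: Mapping[str, float]) -> float:
    """CO2 count balancing the carbon of a lumped route."""
    c_in = sum(CARBON[m] * n for m, n in consumed.items())
    c_out = sum(CARBON[m] * n for m, n in produced.items())
    filler = c_in - c_out
    if filler < 0:
        raise FixtureSpecError(
            f"route produces more carbon than it consumes: {produced}"
        )
    return float(filler)


# ---------------------------------------------------------------------------
# fermenter chassis


def homofermenter(model_id: str = "homo", gam: float = _GAM,
                  glucose_capacity: float = 1000.0) -> Model:
    """Homofermentative glucose fermenter (lumped EMP + D-LDH).

    Glucose yields 2 pyruvate, 2 ATP and 2 NADH; lactate dehydrogenase is
    the only NADH sink besides biomass, so carbon not used for growth is
    secreted as D-lactate (yield 2 per glucose when growth is off).
    A xylose exchange/transport pair is present but disconnected from
    catabolism, mirroring sugar-restricted strains.  ``glucose_capacity``
    caps the uptake capacity of the glucose exchange (a transporter
    V\\ :sub:`max`); the default is effectively uncapped.
    """
    b = _Builder(model_id)
    atp, adp = b.currency()
    nad, nadh = b.redox()
    for base in ("glc_D", "xyl_D", "lac_D", "co2"):
        b.exchange(base, lb=(-abs(glucose_capacity) if base == "glc_D"
                             else -1000.0))
    glc, pyr, lac = b.met("glc_D", "c"), b.met("pyr", "c"), b.met("lac_D", "c")
    b.rxn("EMP", {glc: -1, adp: -2, nad: -2, pyr: 2, atp: 2, nadh: 2})
    b.rxn("LDH_D", {pyr: -1, nadh: -1, lac: 1, nad: 1})
    b.atpm()
    b.biomass({pyr: -1.0, nadh: -1.0, nad: 1.0}, gam=gam)
    return b.build()


def heterofermenter(model_id: str = "hetero", ackr_capacity: float = 2.0,
                    gam: float = _GAM) -> Model:
    """Heterofermentative glucose/xylose fermenter (phosphoketolase route).

    Glucose is oxidatively decarboxylated into the pentose pool (1 NADH),
    xylose enters by kinase; xylulose-5-phosphate phosphoketolase
    (``XU5PG3PL``) splits the pentose into a C2 unit and
    glyceraldehyde-3-phosphate (the acetyl-phosphate intermediate is
    lumped into the acetyl-CoA node, so the acetate branch runs strictly
    through phosphotransacetylase ``PTAr`` and acetate kinase ``ACKr``).
    ``ACKr`` carries substrate-level ATP with a finite capacity; the
    acetaldehyde/ethanol chain is the alternative NADH sink; pyruvate
    splits between D-lactate and the formate branch (``PFL``).  This
    topology makes acetate formation compete with lactate for both carbon
    and ATP-coupled growth, so attenuating or deleting the acetate branch
    redirects flux towards lactate as in real heterofermentative LAB.
    """
    b = _Builder(model_id)
    atp, adp = b.currency()
    nad, nadh = b.redox()
    for base in ("glc_D", "xyl_D", "lac_D", "ac", "etoh", "acald", "for",
                 "co2"):
        b.exchange(base)
    coa = b.met("coa", "c")
    glc, xyl = b.met("glc_D", "c"), b.met("xyl_D", "c")
    ru5p, xu5p = b.met("ru5p", "c"), b.met("xu5p", "c")
    g3p, pyr = b.met("g3p", "c"), b.met("pyr", "c")
    accoa, actp = b.met("accoa", "c"), b.met("actp", "c")
    lac, ac = b.met("lac_D", "c"), b.met("ac", "c")
    etoh, acald = b.met("etoh", "c"), b.met("acald", "c")
    formate, co2 = b.met("for", "c"), b.met("co2", "c")

    b.rxn("G6PDH2r", {glc: -1, atp: -1, nad: -1, ru5p: 1, co2: 1,
                      adp: 1, nadh: 1})
    b.rxn("RPE", {ru5p: -1, xu5p: 1}, -1000.0, 1000.0)
    b.rxn("XYLK", {xyl: -1, atp: -1, xu5p: 1, adp: 1})
    b.rxn("XU5PG3PL", {xu5p: -1, coa: -1, accoa: 1, g3p: 1})
    b.rxn("GAPD", {g3p: -1, adp: -2, nad: -2, pyr: 1, atp: 2, nadh: 2})
    b.rxn("LDH_D", {pyr: -1, nadh: -1, lac: 1, nad: 1})
    b.rxn("PFL", {pyr: -1, coa: -1, accoa: 1, formate: 1})
    b.rxn("PTAr", {accoa: -1, actp: 1, coa: 1}, -1000.0, 1000.0)
    b.rxn("ACKr", {actp: -1, adp: -1, ac: 1, atp: 1},
          -1000.0, ackr_capacity)
    b.rxn("ACALD", {accoa: -1, nadh: -1, acald: 1, coa: 1, nad: 1})
    b.rxn("ALCD2x", {acald: -1, nadh: -1, etoh: 1, nad: 1})
    # arginine deiminase pathway: substrate-level ATP from arginine,
    # the classic LAB fallback energy source
    b.exchange("arg_L")
    b.exchange("orn")
    arg, orn = b.met("arg_L", "c"), b.met("orn", "c")
    b.rxn("ARGDI", {arg: -1, adp: -1, orn: 1, co2: 1, atp: 1})
    b.atpm()
    b.biomass({pyr: -1.0, nadh: -1.0, nad: 1.0}, gam=gam)
    return b.build()


# ---------------------------------------------------------------------------
# ATP-accounting chassis


@dataclass(frozen=True)
class Route:
    """One lumped catabolic route of an ATP-accounting chassis.

    ``substrate`` is consumed (1 mmol), producing ``atp`` mmol ATP and the
    ``products`` (coupled byproducts, secreted obligately whenever the
    route runs); CO2 fills the carbon balance.
    """

    substrate: str
    atp: float
    products: Mapping[str, float] = field(default_factory=dict)


def atp_chassis(model_id: str, routes: Sequence[Route],
                gam: float = _GAM) -> Model:
    """Toy species whose growth is a linear function of route ATP yields."""
    if not routes:
        raise FixtureSpecError("a chassis needs at least one route")
    b = _Builder(model_id)
    atp, adp = b.currency()
    bases = {"glc_D", "xyl_D", "co2"}
    for route in routes:
        bases.add(route.substrate)
        bases.update(route.products)
    for base in sorted(bases):
        b.exchange(base)
    for i, route in enumerate(routes):
        sub = b.met(route.substrate, "c")
        stoich: Dict[Metabolite, float] = {sub: -1.0}
        if route.atp:
            stoich[atp] = route.atp
            stoich[adp] = -route.atp
        for met_id, n in route.products.items():
            met = b.met(met_id, "c")
            stoich[met] = stoich.get(met, 0.0) + n
        filler = _carbon_filler({route.substrate: 1.0}, route.products)
        if filler:
            co2 = b.met("co2", "c")
            stoich[co2] = stoich.get(co2, 0.0) + filler
        b.rxn(f"CAT_{route.substrate}_{i}", stoich)
    b.atpm()
    b.biomass(gam=gam)
    return b.build()


def crossfeed_donor(model_id: str = "donor", atp_per_glucose: float = 2.0,
                    acetate_per_glucose: float = 2.0) -> Model:
    """Grows on glucose, obligately secreting acetate (2 per glucose)."""
    if acetate_per_glucose * CARBON["ac"] > CARBON["glc_D"]:
        raise FixtureSpecError("acetate yield exceeds glucose carbon")
    return atp_chassis(model_id, [
        Route("glc_D", atp_per_glucose, {"ac": acetate_per_glucose}),
    ])


def crossfeed_auxotroph(model_id: str = "auxotroph",
                        atp_per_acetate: float = 2.0) -> Model:
    """Grows only when acetate is supplied (no sugar catabolism at all)."""
    return atp_chassis(model_id, [Route("ac", atp_per_acetate)])


# ---------------------------------------------------------------------------
# named fixtures


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of a toy model fixture.

    ``yield_params`` are archetype-specific stoichiometric knobs (e.g.
    ``ackr_capacity`` for the heterofermenter, ``acetate_per_glucose`` for
    the donor); ``secretion_set`` restricts which byproduct exchanges the
    fermenter chassis keep open.
    """

    archetype: str
    yield_params: Mapping[str, float] = field(default_factory=dict)
    secretion_set: Tuple[str, ...] = ("ac", "etoh", "for", "acald")
    seed: int = 0


_ARCHETYPES = {
    "homofermenter_glc": homofermenter,
    "heterofermenter_glc_xyl": heterofermenter,
    "crossfeed_donor": crossfeed_donor,
    "crossfeed_auxotroph": crossfeed_auxotroph,
}


def make_fixture(spec: FixtureSpec, model_id: Optional[str] = None) -> Model:
    """Build the toy model described by a :class:`FixtureSpec`.

    Every archetype except the (by construction substrate-less) auxotroph
    grows under at least the minimal nutrient condition; generation fails
    loudly otherwise.
    """
    if spec.archetype not in _ARCHETYPES:
        raise FixtureSpecError(
            f"unknown archetype {spec.archetype!r}; "
            f"choose from {sorted(_ARCHETYPES)}"
        )
    factory = _ARCHETYPES[spec.archetype]
    kwargs = dict(spec.yield_params)
    if model_id is not None:
        kwargs["model_id"] = model_id
    try:
        model = factory(**kwargs)
    except TypeError as exc:
        raise FixtureSpecError(
            f"invalid yield_params for {spec.archetype!r}: {exc}"
        ) from exc
    if spec.archetype != "crossfeed_auxotroph":
        mu = monoculture_growth(model, NutrientCondition.minimal(),
                                FIXTURE_MEDIUM)
        if mu <= 1e-9:
            raise FixtureSpecError(
                f"{spec.archetype} fixture does not grow under the minimal "
                "condition"
            )
    return model


# ---------------------------------------------------------------------------
# interaction pairs

# Route tables realising each interaction type through the shared-pool
# community optimum.  With biomass built from ATP alone, the community
# optimum allocates each shared substrate to its most ATP-efficient
# consumer, the abundance of member k is atp_k / total_atp, and the
# per-member growth rate is mu * X_k; the tables below are chosen so the
# resulting per-member changes versus monoculture fall squarely inside the
# sign pattern of the requested label (hand-derived, verified end-to-end
# at generation time).
_PAIR_TABLE: Dict[str, Tuple[List[Route], List[Route]]] = {
    "neutralism": (
        [Route("glc_D", 10.0)],
        [Route("arg_L", 10.0, {"orn": 1.0})],
    ),
    "competition": (
        [Route("glc_D", 3.0), Route("arg_L", 1.0, {"orn": 1.0})],
        [Route("glc_D", 1.0), Route("arg_L", 3.0, {"orn": 1.0})],
    ),
    "parasitism": (
        [Route("arg_L", 8.0, {"orn": 1.0}), Route("ac", 4.0)],
        [Route("glc_D", 2.0, {"ac": 1.0}), Route("arg_L", 2.0, {"orn": 1.0})],
    ),
    "amensalism": (
        [Route("glc_D", 6.0)],
        [Route("glc_D", 2.0), Route("arg_L", 1.0, {"orn": 1.0})],
    ),
    "commensalism": (
        [Route("glc_D", 8.0, {"ac": 1.0})],
        [Route("arg_L", 1.0, {"orn": 1.0}), Route("ac", 2.0)],
    ),
    "mutualism": (
        [Route("glc_D", 2.0, {"ac": 1.0}), Route("for", 6.0)],
        [Route("arg_L", 2.0, {"orn": 1.0, "for": 1.0}), Route("ac", 6.0)],
    ),
}


def make_interaction_pair(
    target_label: str,
    validate: bool = True,
) -> Tuple[Model, Model, NutrientCondition]:
    """Author a species pair whose co-culture realises a given interaction.

    Returns ``(model_a, model_b, condition)``; with ``validate`` (default)
    the full pipeline (monoculture FBA, community solve, classification) is
    run and generation fails loudly if the label does not round-trip.
    """
    if target_label not in _PAIR_TABLE:
        raise FixtureSpecError(
            f"unknown interaction label {target_label!r}; "
            f"choose from {sorted(_PAIR_TABLE)}"
        )
    routes_a, routes_b = _PAIR_TABLE[target_label]
    model_a = atp_chassis(f"{target_label}_A", routes_a)
    model_b = atp_chassis(f"{target_label}_B", routes_b)
    condition = NutrientCondition.minimal()
    if validate:
        label = _pipeline_label(model_a, model_b, condition)
        if label != target_label:
            raise FixtureSpecError(
                f"authored pair classifies as {label!r}, "
                f"not {target_label!r}"
            )
    return model_a, model_b, condition


def _pipeline_label(model_a: Model, model_b: Model,
                    condition: NutrientCondition) -> str:
    from .screening import classify_interaction, is_viable
    from .steadycom import solve_steadycom

    mono = {
        m.id: monoculture_growth(m, condition, FIXTURE_MEDIUM)
        for m in (model_a, model_b)
    }
    cm = build_pair_community(model_a, model_b)
    apply_community_condition(cm, condition, FIXTURE_MEDIUM)
    solution = solve_steadycom(cm)
    co = solution.member_growth
    if not is_viable(co.values()):
        return "non_viable"
    return classify_interaction(
        mono[model_a.id], mono[model_b.id], co[model_a.id], co[model_b.id]
    )


# ---------------------------------------------------------------------------
# panels


def make_panel(n: int, seed: int = 0) -> List[Model]:
    """A reproducible panel of n randomized fixtures for screen smoke tests.

    Archetypes rotate through homofermenters, heterofermenters, acetate
    donors and sugar/amino-acid generalists; quantitative knobs are drawn
    from a seeded generator, so the same (n, seed) yields identical models.
    """
    if n < 2:
        raise FixtureSpecError("a panel needs at least 2 models")
    rng = np.random.default_rng(seed)
    models: List[Model] = []
    kinds = ("homofermenter", "heterofermenter", "donor", "generalist")
    for i in range(n):
        kind = kinds[i % len(kinds)]
        mid = f"fx{i:03d}_{kind}"
        if kind == "homofermenter":
            models.append(homofermenter(mid, gam=float(rng.uniform(8, 12))))
        elif kind == "heterofermenter":
            models.append(heterofermenter(
                mid, ackr_capacity=float(rng.uniform(0.8, 2.5))))
        elif kind == "donor":
            models.append(crossfeed_donor(
                mid,
                atp_per_glucose=float(rng.uniform(1.5, 3.0)),
                acetate_per_glucose=float(rng.choice([1.0, 2.0])),
            ))
        else:
            fallback = "arg_L" if (i // len(kinds)) % 2 == 0 else "glu_L"
            fb_products = {"orn": 1.0} if fallback == "arg_L" else {}
            routes = [
                Route("glc_D", float(np.round(rng.uniform(1.0, 8.0), 2)),
                      {"lac_D": 1.0}),
                Route(fallback, float(np.round(rng.uniform(1.0, 8.0), 2)),
                      fb_products),
            ]
            if rng.random() < 0.5:
                routes.append(
                    Route("ac", float(np.round(rng.uniform(1.0, 4.0), 2)))
                )
            models.append(atp_chassis(mid, routes))
    return models
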