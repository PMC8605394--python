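"""Reading, patching and constraining genome-scale metabolic models.

Models are handled as :class:`cobra.Model` objects throughout the package.
Ids follow the VMH/AGORA convention: metabolites carry a compartment suffix
in parentheses (``glc_D(e)``), exchange reactions are ``EX_<met>(e)`` and the
non-growth ATP maintenance reaction is ``ATPM``.  The sign convention for
exchange fluxes is negative = uptake, positive = secretion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Set

import cobra
from cobra import Model, Metabolite, Reaction

from .exceptions import (
    ConditionError,
    FormatError,
    MissingReactionWarning,
    ModelError,
    NonViableWarning,
    PatchNoOpWarning,
)

__all__ = [
    "AMINO_ACID_EXCHANGES",
    "ESSENTIAL_EXCHANGES",
    "DEFAULT_MEDIUM",
    "NutrientCondition",
    "load_model",
    "save_model",
    "model_summary",
    "biomass_id",
    "atpm_id",
    "exchange_ids",
    "patch_substrate_capability",
    "apply_condition",
    "half_max_uptake",
    "monoculture_growth",
]

#: Exchange ids of the 20 proteinogenic amino acids (VMH naming).  Together
#: with :data:`ESSENTIAL_EXCHANGES` this forms a generic defined medium in
#: the style of the curated LAB media; it is a package-authored list, not a
#: database export.
AMINO_ACID_EXCHANGES: Set[str] = {
    "EX_ala_L(e)", "EX_arg_L(e)", "EX_asn_L(e)", "EX_asp_L(e)",
    "EX_cys_L(e)", "EX_gln_L(e)", "EX_glu_L(e)", "EX_gly(e)",
    "EX_his_L(e)", "EX_ile_L(e)", "EX_leu_L(e)", "EX_lys_L(e)",
    "EX_met_L(e)", "EX_phe_L(e)", "EX_pro_L(e)", "EX_ser_L(e)",
    "EX_thr_L(e)", "EX_trp_L(e)", "EX_tyr_L(e)", "EX_val_L(e)",
}

#: Inorganic / universal medium components allowed at the essential bound.
ESSENTIAL_EXCHANGES: Set[str] = {
    "EX_h2o(e)", "EX_h(e)", "EX_pi(e)", "EX_nh4(e)", "EX_k(e)",
    "EX_na1(e)", "EX_mg2(e)", "EX_ca2(e)", "EX_fe2(e)", "EX_cl(e)",
    "EX_so4(e)", "EX_cobalt2(e)", "EX_mn2(e)", "EX_zn2(e)",
}

DEFAULT_MEDIUM: Set[str] = AMINO_ACID_EXCHANGES | ESSENTIAL_EXCHANGES

_OXYGEN_EXCHANGES = ("EX_o2(e)", "EX_o2(u)")


@dataclass(frozen=True)
class NutrientCondition:
    """A nutrient condition: substrate bounds plus global constraints.

    Parameters
    ----------
    name
        Label for the condition (``minimal``, ``excess``,
        ``community_specific`` or any custom name).
    substrate_bounds
        Map of substrate exchange id -> lower bound (uptake, <= 0),
        in mmol/gDW/h.
    amino_acid_bound
        Lower bound applied to amino-acid exchanges present in the medium.
    essential_bound
        Lower bound applied to the remaining medium components.
    atpm_flux
        Non-growth ATP maintenance flux; clamped with equal lower and upper
        bounds on the ATPM reaction.
    anaerobic
        When true, oxygen uptake is closed.
    """

    name: str
    substrate_bounds: Mapping[str, float]
    amino_acid_bound: float = -1.0
    essential_bound: float = -1000.0
    atpm_flux: float = 0.36
    anaerobic: bool = True

    def __post_init__(self) -> None:
        for ex, lb in self.substrate_bounds.items():
            if lb > 0:
                raise ValueError(f"uptake bound for {ex} must be <= 0, got {lb}")
        if self.amino_acid_bound > 0 or self.essential_bound > 0:
            raise ValueError("medium uptake bounds must be <= 0")
        if self.atpm_flux < 0:
            raise ValueError("atpm_flux must be >= 0")

    # -- standard conditions -------------------------------------------------

    @classmethod
    def minimal(cls, glucose: str = "EX_glc_D(e)", xylose: str = "EX_xyl_D(e)",
                **kw) -> "NutrientCondition":
        """Minimal condition: glucose and xylose at -1 mmol/gDW/h each."""
        return cls("minimal", {glucose: -1.0, xylose: -1.0}, **kw)

    @classmethod
    def excess(cls, glucose: str = "EX_glc_D(e)", xylose: str = "EX_xyl_D(e)",
               **kw) -> "NutrientCondition":
        """Excess condition: glucose at -30, xylose at -10 mmol/gDW/h."""
        return cls("excess", {glucose: -30.0, xylose: -10.0}, **kw)

    @classmethod
    def community_specific(cls, substrate_bounds: Mapping[str, float],
                           **kw) -> "NutrientCondition":
        """Condition built from per-model half-maximal uptake fluxes."""
        return cls("community_specific", dict(substrate_bounds), **kw)

    # -- substrate regimes ---------------------------------------------------

    def restricted_to(self, substrates: Iterable[str]) -> "NutrientCondition":
        """Return a copy with all substrates outside ``substrates`` closed.

        Used for the single-substrate regimes (growth on glucose or xylose
        independently): the excluded substrate keeps its exchange but with a
        zero uptake bound.
        """
        keep = set(substrates)
        bounds = {ex: (lb if ex in keep else 0.0)
                  for ex, lb in self.substrate_bounds.items()}
        return replace(self, substrate_bounds=bounds)


# ---------------------------------------------------------------------------
# model I/O


def load_model(path: str) -> Model:
    """Read an SBML (L3/FBC) model and validate its basic structure.

    Raises
    ------
    FormatError
        If the file cannot be parsed as SBML.
    ModelError
        If no biomass reaction can be identified (objective annotation
        first, then an id containing ``biomass``).
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml raises a zoo of exception types
        raise FormatError(f"could not parse SBML file {path!r}: {exc}") from exc
    biomass_id(model)  # raises ModelError if undetectable
    return model


def save_model(model: Model, path: str) -> None:
    """Write a model as SBML L3 + FBC."""
    cobra.io.write_sbml_model(model, str(path))


def biomass_id(model: Model) -> str:
    """Identify the biomass reaction: objective first, id pattern second."""
    objective = [r.id for r in model.reactions
                 if getattr(r, "objective_coefficient", 0) != 0]
    if len(objective) == 1:
        return objective[0]
    named = [r.id for r in model.reactions if "biomass" in r.id.lower()]
    if len(named) == 1:
        return named[0]
    raise ModelError(
        f"model {model.id!r}: cannot identify a unique biomass reaction "
        f"(objective candidates {objective}, id candidates {named})"
    )


def atpm_id(model: Model) -> Optional[str]:
    """Return the id of the ATP maintenance reaction, or None."""
    for rxn in model.reactions:
        if rxn.id.upper() == "ATPM" or rxn.id.lower().endswith("__atpm"):
            return rxn.id
    return None


def exchange_ids(model: Model) -> Set[str]:
    """Ids of single-metabolite boundary (exchange) reactions."""
    return {r.id for r in model.exchanges}


def model_summary(model: Model) -> Dict:
    """JSON-serialisable structural summary of a model (for debugging)."""
    return {
        "model_id": model.id,
        "n_metabolites": len(model.metabolites),
        "n_reactions": len(model.reactions),
        "biomass_reaction_id": biomass_id(model),
        "atpm_reaction_id": atpm_id(model),
        "exchange_reaction_ids": sorted(exchange_ids(model)),
        "reactions": [
            {
                "id": r.id,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "stoichiometry": {m.id: c for m, c in r.metabolites.items()},
            }
            for r in model.reactions
        ],
    }


def dump_json(model: Model, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(model_summary(model), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# patching


def patch_substrate_capability(model: Model, metabolite_id: str) -> Model:
    """Add exchange + reversible transport for a substrate the model lacks.

    ``metabolite_id`` is the compartment-free base id (e.g. ``glc_D``).  The
    model gains ``EX_<met>(e)`` and a reversible transport
    ``<met>t: <met>(e) <-> <met>(c)``; metabolites are created as needed.
    If the exchange already exists the model is returned unchanged with a
    :class:`PatchNoOpWarning`.  The model is modified in place.
    """
    ex_id = f"EX_{metabolite_id}(e)"
    if ex_id in model.reactions:
        warnings.warn(
            f"model {model.id!r} already has {ex_id}; nothing patched",
            PatchNoOpWarning,
        )
        return model

    def _get_or_create(met_id: str, compartment: str) -> Metabolite:
        if met_id in model.metabolites:
            return model.metabolites.get_by_id(met_id)
        met = Metabolite(met_id, compartment=compartment)
        model.add_metabolites([met])
        return met

    met_e = _get_or_create(f"{metabolite_id}(e)", "e")
    met_c = _get_or_create(f"{metabolite_id}(c)", "c")

    exchange = Reaction(ex_id, lower_bound=-1000.0, upper_bound=1000.0)
    exchange.add_metabolites({met_e: -1.0})
    transport = Reaction(f"{metabolite_id}t", lower_bound=-1000.0,
                         upper_bound=1000.0)
    transport.add_metabolites({met_e: -1.0, met_c: 1.0})
    model.add_reactions([exchange, transport])
    return model


# ---------------------------------------------------------------------------
# conditions


def apply_condition(
    model: Model,
    condition: NutrientCondition,
    medium_exchange_ids: Iterable[str] = frozenset(),
    strict: bool = True,
) -> Model:
    """Apply a nutrient condition to a monoculture model (in place).

    Substrate exchanges receive the condition's bounds; amino-acid exchanges
    in the medium receive ``amino_acid_bound``; other medium exchanges
    receive ``essential_bound``; every remaining exchange is closed for
    uptake (lower bound 0).  The ATPM reaction is clamped to ``atpm_flux``
    with equal bounds, and oxygen uptake is closed when anaerobic.

    With ``strict`` (default) a substrate exchange id missing from the model
    raises :class:`ConditionError`; otherwise it is skipped with a warning.
    """
    medium = set(medium_exchange_ids)
    for ex, lb in condition.substrate_bounds.items():
        if ex not in model.reactions:
            if strict:
                raise ConditionError(
                    f"substrate exchange {ex!r} missing from model {model.id!r}"
                )
            warnings.warn(
                f"substrate exchange {ex!r} missing from model {model.id!r}",
                MissingReactionWarning,
            )
    for rxn in model.exchanges:
        if rxn.id in condition.substrate_bounds:
            rxn.lower_bound = condition.substrate_bounds[rxn.id]
        elif rxn.id in medium and rxn.id in AMINO_ACID_EXCHANGES:
            rxn.lower_bound = condition.amino_acid_bound
        elif rxn.id in medium:
            rxn.lower_bound = condition.essential_bound
        else:
            rxn.lower_bound = 0.0
    if condition.anaerobic:
        for o2 in _OXYGEN_EXCHANGES:
            if o2 in model.reactions:
                model.reactions.get_by_id(o2).lower_bound = 0.0
    maintenance = atpm_id(model)
    if maintenance is None:
        if condition.atpm_flux > 0:
            raise ConditionError(
                f"model {model.id!r} has no ATPM reaction to clamp"
            )
    else:
        model.reactions.get_by_id(maintenance).bounds = (
            condition.atpm_flux, condition.atpm_flux
        )
    return model


def monoculture_growth(
    model: Model,
    condition: Optional[NutrientCondition] = None,
    medium_exchange_ids: Iterable[str] = frozenset(),
) -> float:
    """Maximal FBA growth rate under a condition; 0 if infeasible.

    Infeasibility (e.g. the maintenance demand cannot be met on the given
    medium) is reported as zero growth so that screens can exclude the model
    rather than abort.
    """
    with model as m:
        if condition is not None:
            apply_condition(m, condition, medium_exchange_ids, strict=False)
        m.objective = biomass_id(m)
        mu = m.slim_optimize(error_value=float("nan"))
    if mu != mu:  # NaN: infeasible
        return 0.0
    return max(mu, 0.0)


def half_max_uptake(
    model: Model,
    substrate_exchange_id: str,
    condition: Optional[NutrientCondition] = None,
) -> float:
    """Substrate uptake flux (<= 0) at half-maximal growth.

    The maximal growth rate is computed with the substrate as sole carbon
    source under excess bounds (other substrates closed); biomass is then
    fixed at half that optimum and the uptake magnitude minimised by LP.
    Non-growers return 0 with a :class:`NonViableWarning`.
    """
    if condition is None:
        condition = NutrientCondition.excess()
    condition = condition.restricted_to({substrate_exchange_id})
    if substrate_exchange_id not in condition.substrate_bounds:
        bounds = dict(condition.substrate_bounds)
        bounds[substrate_exchange_id] = -30.0
        condition = replace(condition, substrate_bounds=bounds)
    with model as m:
        apply_condition(m, condition, strict=True)
        bio = biomass_id(m)
        m.objective = bio
        mu_max = m.slim_optimize(error_value=float("nan"))
        if not mu_max == mu_max or mu_max < 1e-9:
            warnings.warn(
                f"model {model.id!r} is non-viable on {substrate_exchange_id}",
                NonViableWarning,
            )
            return 0.0
        m.reactions.get_by_id(bio).bounds = (0.5 * mu_max, 0.5 * mu_max)
        # minimise uptake magnitude = maximise the (negative) exchange flux
        m.objective = m.reactions.get_by_id(substrate_exchange_id)
        m.objective_direction = "max"
        flux = m.slim_optimize(error_value=float("nan"))
    if flux != flux:
        warnings.warn(
            f"model {model.id!r}: half-max uptake LP infeasible for "
            f"{substrate_exchange_id}",
            NonViableWarning,
        )
        return 0.0
    return min(flux, 0.0)
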