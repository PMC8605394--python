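"""Two-species community models with a shared community compartment [u].

Each member keeps its own compartments and reactions under a member-id
prefix (``A__PFL``).  The member's original exchange reactions become
transfer reactions ``A__IEX_<met>(u)`` between the member's extracellular
compartment and the shared pool, carrying the member's own exchange bounds
(positive flux = secretion into [u]).  One community exchange
``EX_<met>(u)`` per pooled metabolite connects [u] to the environment;
nutrient conditions are applied to these community exchanges only, so a
condition bound caps *total* community uptake.
"""

from __future__ import annotations

import itertools
import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from cobra import Model, Metabolite, Reaction

from .exceptions import ConditionError, IdentityError, ModelError
from .io import (
    AMINO_ACID_EXCHANGES,
    NutrientCondition,
    atpm_id,
    biomass_id,
)

__all__ = [
    "CommunityModel",
    "build_pair_community",
    "apply_community_condition",
    "community_exchange_id",
    "self_pair",
    "iter_pairs",
]

_COMP_SUFFIX = re.compile(r"\((\w+)\)$")

_SECRETION_UB = 1000.0


def community_exchange_id(exchange_id: str) -> str:
    """Map a model-level exchange id to its community-level id.

    ``EX_lac_D(e)`` -> ``EX_lac_D(u)``.
    """
    return re.sub(r"\(e\)$", "(u)", exchange_id)


def _pool_met_id(met_id: str) -> str:
    if _COMP_SUFFIX.search(met_id):
        return _COMP_SUFFIX.sub("(u)", met_id)
    return met_id + "(u)"


@dataclass
class CommunityModel:
    """A two-member community as a tagged :class:`cobra.Model` plus an index.

    Attributes
    ----------
    model
        The merged stoichiometric model (member-tagged reactions, transfer
        reactions and community exchanges).
    member_ids
        Ordered pair of member identifiers.
    biomass_ids, atpm_ids
        Per-member tagged biomass / ATP-maintenance reaction ids.
    member_reactions
        Member -> all tagged reaction ids of that member (transfers
        included); used to scale bounds by abundance in the solver.
    transfer_ids
        Member -> {pool metabolite id -> transfer reaction id}.
    community_exchange_ids
        Pool metabolite id -> community exchange reaction id.
    product_exchange_id
        Community exchange of the target product, if set.
    """

    model: Model
    member_ids: Tuple[str, str]
    biomass_ids: Dict[str, str]
    atpm_ids: Dict[str, str]
    member_reactions: Dict[str, List[str]]
    transfer_ids: Dict[str, Dict[str, str]]
    community_exchange_ids: Dict[str, str]
    product_exchange_id: Optional[str] = None

    def member_of(self, reaction_id: str) -> Optional[str]:
        """Member owning a tagged reaction id, or None for community level."""
        for member in self.member_ids:
            if reaction_id.startswith(member + "__"):
                return member
        return None

    def untagged(self, reaction_id: str) -> str:
        member = self.member_of(reaction_id)
        if member is None:
            return reaction_id
        return reaction_id[len(member) + 2:]

    def transfer_flux(self, fluxes: Mapping[str, float], member: str,
                      pool_met: str) -> float:
        """Transfer flux of ``member`` for a pool metabolite (0 if absent)."""
        rid = self.transfer_ids[member].get(pool_met)
        return fluxes.get(rid, 0.0) if rid else 0.0

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            model=self.model.copy(),
            member_ids=self.member_ids,
            biomass_ids=dict(self.biomass_ids),
            atpm_ids=dict(self.atpm_ids),
            member_reactions={k: list(v) for k, v in self.member_reactions.items()},
            transfer_ids={k: dict(v) for k, v in self.transfer_ids.items()},
            community_exchange_ids=dict(self.community_exchange_ids),
            product_exchange_id=self.product_exchange_id,
        )

    def manifest(self) -> Dict:
        """JSON-serialisable listing of member / transfer / exchange ids."""
        return {
            "member_ids": list(self.member_ids),
            "biomass_ids": self.biomass_ids,
            "atpm_ids": self.atpm_ids,
            "member_reactions": self.member_reactions,
            "transfer_ids": self.transfer_ids,
            "community_exchange_ids": self.community_exchange_ids,
            "product_exchange_id": self.product_exchange_id,
        }

    def dump_manifest(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1, sort_keys=True)


def build_pair_community(model_a: Model, model_b: Model,
                         product_exchange: Optional[str] = None,
                         ) -> CommunityModel:
    """Merge two monoculture models into a community model.

    Members are tagged by their model ids (which must differ); their
    exchange reactions are converted into member<->[u] transfers with the
    original exchange bounds, and one community exchange per pooled
    metabolite is added, closed for uptake by default.

    ``product_exchange`` is a model-level exchange id (``EX_lac_D(e)``)
    whose community counterpart is recorded as the target product.
    """
    if model_a.id == model_b.id:
        raise IdentityError(
            f"duplicate member id {model_a.id!r}; rename one copy"
        )
    members = (model_a.id, model_b.id)
    merged = Model("__".join(members))
    pool_mets: Dict[str, Metabolite] = {}
    biomass_ids: Dict[str, str] = {}
    atpm_ids: Dict[str, str] = {}
    member_reactions: Dict[str, List[str]] = {m: [] for m in members}
    transfer_ids: Dict[str, Dict[str, str]] = {m: {} for m in members}

    def _pool(met: Metabolite) -> Metabolite:
        pid = _pool_met_id(met.id)
        if pid not in pool_mets:
            pooled = Metabolite(pid, name=met.name, compartment="u")
            pool_mets[pid] = pooled
            merged.add_metabolites([pooled])
        return pool_mets[pid]

    for source in (model_a, model_b):
        tag = source.id
        bio = biomass_id(source)
        maintenance = atpm_id(source)
        if maintenance is None:
            raise ModelError(f"member {tag!r} lacks an ATPM reaction")
        tagged_mets = {
            met.id: Metabolite(
                f"{tag}__{met.id}", name=met.name,
                compartment=f"{tag}_{met.compartment}",
            )
            for met in source.metabolites
        }
        merged.add_metabolites(list(tagged_mets.values()))
        exchanges = {r.id for r in source.exchanges}
        new_reactions = []
        for rxn in source.reactions:
            if rxn.id in exchanges:
                met = next(iter(rxn.metabolites))
                pooled = _pool(met)
                transfer = Reaction(
                    f"{tag}__IEX_{pooled.id}",
                    lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
                )
                # original exchange: met(e) -> (out); transfer: met(e) -> met(u)
                transfer.add_metabolites(
                    {tagged_mets[met.id]: -1.0, pooled: 1.0}
                )
                new_reactions.append(transfer)
                transfer_ids[tag][pooled.id] = transfer.id
            else:
                tagged = Reaction(
                    f"{tag}__{rxn.id}",
                    lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
                )
                tagged.add_metabolites(
                    {tagged_mets[m.id]: c for m, c in rxn.metabolites.items()}
                )
                new_reactions.append(tagged)
        merged.add_reactions(new_reactions)
        member_reactions[tag] = [r.id for r in new_reactions]
        biomass_ids[tag] = f"{tag}__{bio}"
        atpm_ids[tag] = f"{tag}__{maintenance}"

    community_exchange_ids: Dict[str, str] = {}
    pool_exchanges = []
    for pid, pooled in sorted(pool_mets.items()):
        ex = Reaction(f"EX_{pid}", lower_bound=0.0, upper_bound=_SECRETION_UB)
        ex.add_metabolites({pooled: -1.0})
        pool_exchanges.append(ex)
        community_exchange_ids[pid] = ex.id
    merged.add_reactions(pool_exchanges)

    product_id = None
    if product_exchange is not None:
        product_id = community_exchange_id(product_exchange)
        if product_id not in merged.reactions:
            warnings.warn(
                f"product exchange {product_id!r} absent from community "
                f"{merged.id!r}", UserWarning,
            )
            product_id = None

    return CommunityModel(
        model=merged,
        member_ids=members,
        biomass_ids=biomass_ids,
        atpm_ids=atpm_ids,
        member_reactions=member_reactions,
        transfer_ids=transfer_ids,
        community_exchange_ids=community_exchange_ids,
        product_exchange_id=product_id,
    )


def self_pair(model: Model, tags: Tuple[str, str] = ("copy1", "copy2"),
              product_exchange: Optional[str] = None) -> CommunityModel:
    """Community of two copies of the same model under distinct tags."""
    a, b = model.copy(), model.copy()
    a.id = f"{model.id}_{tags[0]}"
    b.id = f"{model.id}_{tags[1]}"
    return build_pair_community(a, b, product_exchange=product_exchange)


def iter_pairs(models: Iterable[Model]):
    """All unordered pairs of models (C(n, 2) communities)."""
    return itertools.combinations(list(models), 2)


def apply_community_condition(
    cm: CommunityModel,
    condition: NutrientCondition,
    medium_exchange_ids: Iterable[str] = frozenset(),
) -> CommunityModel:
    """Apply a nutrient condition at the community compartment (in place).

    Bounds are set on the ``EX_<met>(u)`` reactions only; member transfer
    bounds keep the members' own capabilities.  Substrates alien to both
    members get a (necessarily idle) community exchange so that the bound is
    always expressible.  Member ATPM reactions are clamped to the condition
    maintenance flux (scaled by abundance in the solver).
    """
    medium_u = {community_exchange_id(ex) for ex in medium_exchange_ids}
    aa_u = {community_exchange_id(ex) for ex in AMINO_ACID_EXCHANGES}
    substrate_u = {
        community_exchange_id(ex): lb
        for ex, lb in condition.substrate_bounds.items()
    }
    model = cm.model
    for ex_u in substrate_u:
        if ex_u not in model.reactions:
            pid = ex_u[3:]
            pooled = Metabolite(pid, compartment="u")
            model.add_metabolites([pooled])
            ex = Reaction(ex_u, lower_bound=0.0, upper_bound=_SECRETION_UB)
            ex.add_metabolites({pooled: -1.0})
            model.add_reactions([ex])
            cm.community_exchange_ids[pid] = ex_u
    for ex_u in cm.community_exchange_ids.values():
        rxn = model.reactions.get_by_id(ex_u)
        if ex_u in substrate_u:
            rxn.lower_bound = substrate_u[ex_u]
        elif ex_u in medium_u and ex_u in aa_u:
            rxn.lower_bound = condition.amino_acid_bound
        elif ex_u in medium_u:
            rxn.lower_bound = condition.essential_bound
        else:
            rxn.lower_bound = 0.0
    if condition.anaerobic and "EX_o2(u)" in model.reactions:
        model.reactions.get_by_id("EX_o2(u)").lower_bound = 0.0
    for member, maintenance in cm.atpm_ids.items():
        model.reactions.get_by_id(maintenance).bounds = (
            condition.atpm_flux, condition.atpm_flux
        )
    return cm
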