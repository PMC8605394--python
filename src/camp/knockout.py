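"""Reaction-knockout design on community models via enforced-flux scanning.

Flux Scanning based on Enforced Objective Flux (FSEOF): the product
exchange is forced stepwise from its wild-type level towards its maximum
while community growth is re-maximised at each step.  Internal member
reactions whose (parsimonious) flux magnitude shrinks monotonically as the
product is enforced carry flux that competes with product formation; they
are the knockout shortlist.  Reactions whose flux grows are amplification
targets and are reported separately but never deleted.  The shortlist is
then tested exhaustively: every single deletion, plus every unordered pair
when the shortlist is small enough, is re-solved and scored for product
gain and per-member viability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .community import CommunityModel
from .exceptions import ConfigurationError, InfeasibleError
from .screening import DEFAULT_MIN_GROWTH, is_viable
from .steadycom import CommunityLP, solve_steadycom, steadycom_fva

__all__ = [
    "FseofScan",
    "KnockoutResult",
    "fseof_scan",
    "deletion_sets",
    "evaluate_deletions",
    "select_strategies",
]

_TOL = 1e-6
DEFAULT_K_STEPS = 10
DEFAULT_SINGLE_ONLY_THRESHOLD = 30


@dataclass(frozen=True)
class FseofScan:
    enforced_levels: Tuple[float, ...]
    flux_profiles: Dict[str, Tuple[float, ...]]  # |flux| per level
    candidates: FrozenSet[str]  # attenuating reactions (knockout shortlist)
    amplification_targets: FrozenSet[str]
    wildtype_product_flux: float
    product_max: float

    @property
    def empty(self) -> bool:
        return not self.enforced_levels


@dataclass(frozen=True)
class KnockoutResult:
    deleted_reactions: FrozenSet[str]
    mutant_mu: float
    mutant_product_flux: float
    viable: bool
    improved: bool
    wildtype_product_flux: float
    member_growth: Dict[str, float] = field(default_factory=dict)


def _scannable(cm: CommunityModel) -> List[str]:
    """Internal member reactions eligible as candidates (no biomass, ATPM,
    transfer or exchange reactions)."""
    skip = set(cm.biomass_ids.values()) | set(cm.atpm_ids.values())
    for transfers in cm.transfer_ids.values():
        skip.update(transfers.values())
    eligible = []
    for member, rids in cm.member_reactions.items():
        for rid in rids:
            if rid not in skip:
                eligible.append(rid)
    return sorted(eligible)


def fseof_scan(
    cm: CommunityModel,
    product_exchange: Optional[str] = None,
    k_steps: int = DEFAULT_K_STEPS,
    tol: float = 1e-4,
    mu_floor: float = DEFAULT_MIN_GROWTH,
) -> FseofScan:
    """Scan internal fluxes while the product flux is enforced stepwise.

    The baseline is the least product the community must make while
    growing optimally (its flux minimum at mu*); the ceiling is the
    product maximum attainable while the community still grows at the
    viability floor ``mu_floor``.  At each enforced level community growth
    is re-maximised (it falls once the level exceeds what the wild-type
    optimum tolerates) and a parsimonious (minimum total member |flux|)
    profile with the product pinned at the level is recorded.  If the
    product cannot exceed its wild-type baseline the scan is empty.
    """
    product = product_exchange or cm.product_exchange_id
    if product is None:
        raise ValueError("no product exchange specified")
    lp = CommunityLP(cm)
    wildtype = solve_steadycom(cm, lp=lp)
    wt_flux = max(
        0.0, steadycom_fva(cm, product, wildtype.mu, lp=lp).minimum)
    floor = min(mu_floor, wildtype.mu)
    # ceiling: the best product level on the product-vs-growth frontier,
    # probed between the viability floor and the wild-type optimum (the
    # frontier may peak below mu* when product and growth compete)
    probe_mus = sorted(
        set(np.linspace(floor, 0.8 * wildtype.mu, 5))
        | set(np.linspace(0.8 * wildtype.mu, wildtype.mu, 11))
    )
    frontier: Dict[float, float] = {}
    for mu_probe in probe_mus:
        try:
            frontier[mu_probe] = steadycom_fva(
                cm, product, mu_probe, lp=lp).maximum
        except InfeasibleError:
            continue
    product_max = max(frontier.values())
    if product_max <= wt_flux + tol:
        return FseofScan((), {}, frozenset(), frozenset(), wt_flux,
                         product_max)
    levels = tuple(np.linspace(wt_flux, 0.99 * product_max, k_steps))
    eligible = _scannable(cm)
    profiles: Dict[str, List[float]] = {rid: [] for rid in eligible}
    product_var = lp.v[product]
    base_lb = product_var.lb
    try:
        for level in levels:
            product_var.lb = level
            # the highest probed growth whose frontier admits this level is
            # a feasible bisection seed
            lo = max(mu for mu, p in frontier.items() if p >= level - tol)
            step = solve_steadycom(cm, lp=lp, mu_bracket=(lo, 50.0),
                                   parsimonious=False)
            status, fluxes, _ = lp.parsimonious_fluxes(
                step.mu, extra_bounds={product: (level, level)}
            )
            if status != "optimal":
                fluxes = step.fluxes
            for rid in eligible:
                profiles[rid].append(abs(fluxes[rid]))
    finally:
        product_var.lb = base_lb

    candidates, amplified = set(), set()
    for rid, prof in profiles.items():
        drops = all(b <= a + tol for a, b in zip(prof, prof[1:]))
        rises = all(b >= a - tol for a, b in zip(prof, prof[1:]))
        if drops and prof[0] > tol and prof[-1] < prof[0] - tol:
            candidates.add(rid)
        elif rises and prof[-1] > prof[0] + tol:
            amplified.add(rid)
    return FseofScan(
        levels, {rid: tuple(p) for rid, p in profiles.items()},
        frozenset(candidates), frozenset(amplified), wt_flux, product_max,
    )


def deletion_sets(
    candidates: Iterable[str],
    single_only_threshold: int = DEFAULT_SINGLE_ONLY_THRESHOLD,
) -> List[FrozenSet[str]]:
    """Deletion combinations to test: all singles, plus all unordered
    pairs when the candidate list is at most ``single_only_threshold``."""
    ordered = sorted(set(candidates))
    sets: List[FrozenSet[str]] = [frozenset({rid}) for rid in ordered]
    if len(ordered) <= single_only_threshold:
        sets.extend(frozenset(p) for p in itertools.combinations(ordered, 2))
    return sets


def evaluate_deletions(
    cm: CommunityModel,
    candidates: Iterable[str],
    product_exchange: Optional[str] = None,
    single_only_threshold: int = DEFAULT_SINGLE_ONLY_THRESHOLD,
    min_growth: float = DEFAULT_MIN_GROWTH,
) -> List[KnockoutResult]:
    """Re-solve the community for every candidate deletion set.

    A deletion closes the reaction (both bounds 0) in the tagged member
    copy.  Mutants whose LP turns infeasible are recorded as non-viable
    rather than raising.  ``improved`` additionally requires viability.
    """
    product = product_exchange or cm.product_exchange_id
    if product is None:
        raise ValueError("no product exchange specified")
    wt_lp = CommunityLP(cm)
    wt = solve_steadycom(cm, lp=wt_lp)
    wt_pmax = steadycom_fva(cm, product, wt.mu, lp=wt_lp).maximum

    results: List[KnockoutResult] = []
    for dset in deletion_sets(candidates, single_only_threshold):
        mutant = cm.copy()
        for rid in dset:
            mutant.model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        try:
            sol = solve_steadycom(mutant)
            viable = is_viable(sol.member_growth.values(), min_growth)
            pmax = steadycom_fva(mutant, product, sol.mu).maximum
            result = KnockoutResult(
                deleted_reactions=dset,
                mutant_mu=sol.mu,
                mutant_product_flux=pmax,
                viable=viable,
                improved=viable and pmax > wt_pmax + _TOL,
                wildtype_product_flux=wt_pmax,
                member_growth=dict(sol.member_growth),
            )
        except (InfeasibleError, ConfigurationError):
            result = KnockoutResult(
                deleted_reactions=dset, mutant_mu=0.0,
                mutant_product_flux=0.0, viable=False, improved=False,
                wildtype_product_flux=wt_pmax,
            )
        results.append(result)
    results.sort(key=lambda r: sorted(r.deleted_reactions))
    return results


def select_strategies(results: Sequence[KnockoutResult],
                      ) -> List[KnockoutResult]:
    """Improving, viable mutants ordered by product flux (parsimony on
    ties: fewer deletions first, then lexicographic ids)."""
    chosen = [r for r in results if r.improved and r.viable]
    chosen.sort(key=lambda r: (
        -r.mutant_product_flux,
        len(r.deleted_reactions),
        sorted(r.deleted_reactions),
    ))
    return chosen
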