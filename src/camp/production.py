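"""Expected vs. observed product yield, robustness scenarios and ranking.

The yield bookkeeping follows the screen's convention: for a product *i*,
each member's monoculture yield ``y_ki`` is its maximal product flux at
maximal growth divided by its substrate uptake; the *expected* community
yield composes these with the co-culture substrate uptakes,

    ME_i = s1 * y1i + s2 * y2i,

while the *observed* yield is the community's maximal product flux at its
maximal growth rate divided by total community substrate uptake.  A
community whose observed yield reaches 10x the expected yield is a
candidate producer.  ``ME_i`` is computed literally as printed above (it
carries flux units, unlike the dimensionless ``MO_i``); pass
``normalize=True`` to :func:`expected_yield` to divide by ``s1 + s2``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from cobra import Model

from .community import CommunityModel, apply_community_condition, community_exchange_id
from .exceptions import InfeasibleError, MissingReactionWarning
from .io import NutrientCondition, apply_condition, biomass_id
from .screening import DEFAULT_MIN_GROWTH, is_viable
from .steadycom import CommunityLP, CommunitySolution, solve_steadycom, steadycom_fva

__all__ = [
    "MonocultureYield",
    "ObservedYield",
    "YieldRecord",
    "RankedCommunity",
    "EfficiencyResult",
    "monoculture_yield",
    "expected_yield",
    "observed_yield",
    "ten_fold_candidate",
    "efficiency_scenarios",
    "jaccard_distance",
    "rank_communities",
]

_EPS = 1e-9
DEFAULT_YIELD_FOLD = 10.0


@dataclass(frozen=True)
class MonocultureYield:
    model_id: str
    mu_max: float
    product_max: float  # maximal product flux at fixed maximal growth
    substrate_uptake: float  # total uptake magnitude, glucose + xylose
    yield_value: float  # product_max / substrate_uptake


@dataclass(frozen=True)
class ObservedYield:
    product_max: float
    total_uptake: float
    member_uptake: Dict[str, float]  # s_k per member, magnitudes
    moi: float


@dataclass(frozen=True)
class YieldRecord:
    pair: Tuple[str, str]
    s1: float
    s2: float
    y1i: float
    y2i: float
    mei: float
    moi: float
    candidate: bool


@dataclass(frozen=True)
class RankedCommunity:
    pair: Tuple[str, str]
    normalized_growth: float
    normalized_yield: float
    score: float
    jaccard_distance: Optional[float] = None


@dataclass(frozen=True)
class EfficiencyResult:
    scenario_pass: Dict[str, bool]
    overall: bool


def _ratio(numerator: float, denominator: float, what: str) -> float:
    if denominator < _EPS:
        if numerator > _EPS:
            warnings.warn(
                f"{what}: nonzero product flux with zero substrate uptake; "
                "yield reported as inf", UserWarning,
            )
            return math.inf
        return 0.0
    return numerator / denominator


def monoculture_yield(
    model: Model,
    condition: NutrientCondition,
    product_exchange: str,
    medium_exchange_ids: Iterable[str] = frozenset(),
) -> Optional[MonocultureYield]:
    """Maximal product yield of one model under a condition.

    Biomass is fixed at its FBA optimum, the product flux maximised, and
    (as a deterministic tie-break over alternate optima) the substrate
    uptake minimised at that product level.  Returns None for models that
    cannot grow under the condition (excluded from yield records).
    """
    substrates = list(condition.substrate_bounds)
    with model as m:
        apply_condition(m, condition, medium_exchange_ids, strict=False)
        bio = biomass_id(m)
        m.objective = bio
        mu_max = m.slim_optimize(error_value=float("nan"))
        if not mu_max == mu_max or mu_max < _EPS:
            return None
        m.reactions.get_by_id(bio).bounds = (mu_max, mu_max)
        if product_exchange not in m.reactions:
            warnings.warn(
                f"product exchange {product_exchange!r} absent from "
                f"{model.id!r}; yield 0", MissingReactionWarning,
            )
            return MonocultureYield(model.id, mu_max, 0.0, 0.0, 0.0)
        m.objective = product_exchange
        product_max = m.slim_optimize(error_value=float("nan"))
        if product_max != product_max:
            return None
        product_max = max(product_max, 0.0)
        m.reactions.get_by_id(product_exchange).bounds = (
            product_max, product_max
        )
        present = [s for s in substrates if s in m.reactions]
        if not present:
            return MonocultureYield(model.id, mu_max, product_max, 0.0,
                                    _ratio(product_max, 0.0, model.id))
        m.objective = sum(
            m.reactions.get_by_id(s).flux_expression for s in present
        )
        m.objective_direction = "max"  # least-negative total = least uptake
        m.slim_optimize(error_value=float("nan"))
        uptake = sum(
            max(0.0, -m.reactions.get_by_id(s).flux) for s in present
        )
    y = _ratio(product_max, uptake, f"monoculture yield of {model.id!r}")
    return MonocultureYield(model.id, mu_max, product_max, uptake, y)


def expected_yield(s1: float, s2: float, y1i: float, y2i: float,
                   normalize: bool = False) -> float:
    """Expected community product yield composed from monoculture yields."""
    if min(s1, s2, y1i, y2i) < 0:
        raise ValueError("uptakes and yields must be non-negative")
    mei = s1 * y1i + s2 * y2i
    if normalize:
        return _ratio(mei, s1 + s2, "normalised expected yield")
    return mei


def observed_yield(
    cm: CommunityModel,
    mu: float,
    product_exchange: Optional[str] = None,
    substrate_exchanges: Iterable[str] = ("EX_glc_D(u)", "EX_xyl_D(u)"),
    lp: Optional[CommunityLP] = None,
) -> ObservedYield:
    """Observed community yield at clamped growth rate ``mu``.

    The product flux is maximised over the community feasible set; with
    the product pinned at that maximum, total substrate uptake at [u] is
    minimised (deterministic representative of the optimal face), and the
    per-member uptakes s_k are read from the substrate transfer fluxes of
    that same solution.
    """
    product = product_exchange or cm.product_exchange_id
    if product is None:
        raise ValueError("no product exchange specified")
    lp = lp or CommunityLP(cm)
    subs = [s for s in substrate_exchanges if s in cm.model.reactions]
    rng = steadycom_fva(cm, product, mu, lp=lp)
    product_max = rng.maximum
    status, _, fluxes, _ = lp.optimize(
        mu, {s: 1.0 for s in subs}, "max",
        extra_bounds={product: (product_max, product_max)},
    )
    if status != "optimal":
        raise InfeasibleError(
            f"uptake minimisation infeasible for {cm.model.id!r}"
        )
    total = sum(max(0.0, -fluxes[s]) for s in subs)
    pool_mets = [s[3:] for s in subs]  # "EX_glc_D(u)" -> "glc_D(u)"
    member_uptake = {
        member: sum(
            max(0.0, -cm.transfer_flux(fluxes, member, pm))
            for pm in pool_mets
        )
        for member in cm.member_ids
    }
    moi = _ratio(product_max, total, f"observed yield of {cm.model.id!r}")
    return ObservedYield(product_max, total, member_uptake, moi)


def ten_fold_candidate(moi: float, mei: float,
                       fold: float = DEFAULT_YIELD_FOLD) -> bool:
    """Candidate producer iff observed >= fold * expected (inclusive)."""
    return moi >= fold * mei


def yield_record(
    pair: Tuple[str, str],
    observed: ObservedYield,
    mono_yields: Mapping[str, MonocultureYield],
    fold: float = DEFAULT_YIELD_FOLD,
) -> YieldRecord:
    """Assemble the per-community yield bookkeeping record."""
    a, b = pair
    s1 = observed.member_uptake[a]
    s2 = observed.member_uptake[b]
    y1 = mono_yields[a].yield_value
    y2 = mono_yields[b].yield_value
    mei = expected_yield(s1, s2, y1, y2)
    return YieldRecord(pair, s1, s2, y1, y2, mei, observed.moi,
                       ten_fold_candidate(observed.moi, mei, fold))


# ---------------------------------------------------------------------------
# robustness scenarios


def _blocked_copy(cm: CommunityModel,
                  bounds: Mapping[str, Tuple[float, float]]) -> CommunityModel:
    mutant = cm.copy()
    for rid, bnd in bounds.items():
        if rid in mutant.model.reactions:
            mutant.model.reactions.get_by_id(rid).bounds = bnd
    return mutant


def _viable(cm: CommunityModel, min_growth: float) -> bool:
    try:
        solution = solve_steadycom(cm)
    except InfeasibleError:
        return False
    return is_viable(solution.member_growth.values(), min_growth)


def efficiency_scenarios(
    cm: CommunityModel,
    product_exchange: Optional[str] = None,
    substrate_bases: Sequence[str] = ("glc_D", "xyl_D"),
    min_growth: float = DEFAULT_MIN_GROWTH,
) -> EfficiencyResult:
    """Perturbation scenarios for product- and growth-efficient pairs.

    Scenario ``no_crossfeed_<member>``: the member's product (lactate)
    transfer is fully blocked (both bounds 0), preventing product
    cross-feeding.  Scenario ``primary_<member>``: the member is the sole
    substrate consumer; the partner's sugar uptake through [u] is blocked
    (transfer lower bounds 0, secretion still allowed).  A scenario passes
    when the re-solved community keeps every member at or above
    ``min_growth``; the community is efficient when all scenarios pass.
    """
    product = product_exchange or cm.product_exchange_id
    product_pool = product[3:] if product else None  # "EX_lac_D(u)"->pool id
    scenario_pass: Dict[str, bool] = {}
    for member in cm.member_ids:
        blocks: Dict[str, Tuple[float, float]] = {}
        if product_pool is not None:
            rid = cm.transfer_ids[member].get(product_pool)
            if rid is not None:
                blocks[rid] = (0.0, 0.0)
        scenario_pass[f"no_crossfeed_{member}"] = _viable(
            _blocked_copy(cm, blocks), min_growth
        )
    for primary in cm.member_ids:
        other = next(m for m in cm.member_ids if m != primary)
        blocks = {}
        for base in substrate_bases:
            rid = cm.transfer_ids[other].get(f"{base}(u)")
            if rid is not None:
                ub = cm.model.reactions.get_by_id(rid).upper_bound
                blocks[rid] = (0.0, ub)
        scenario_pass[f"primary_{primary}"] = _viable(
            _blocked_copy(cm, blocks), min_growth
        )
    return EfficiencyResult(scenario_pass, all(scenario_pass.values()))


# ---------------------------------------------------------------------------
# metabolic distance and ranking


def jaccard_distance(reactions_a: Set[str], reactions_b: Set[str]) -> float:
    """1 - |intersection| / |union| of two reaction id sets."""
    if not reactions_a and not reactions_b:
        raise ValueError("Jaccard distance undefined for two empty sets")
    union = set(reactions_a) | set(reactions_b)
    inter = set(reactions_a) & set(reactions_b)
    return 1.0 - len(inter) / len(union)


def _minmax(values: Sequence[float]) -> List[float]:
    lo, hi = min(values), max(values)
    if hi - lo < _EPS:
        return [1.0] * len(values)  # degenerate cohort: all equal
    return [(v - lo) / (hi - lo) for v in values]


def rank_communities(
    records: Sequence[Tuple[Tuple[str, str], float, float]],
    jaccard: Optional[Mapping[Tuple[str, str], float]] = None,
) -> List[RankedCommunity]:
    """Min-max-normalised ranking of (pair, growth rate, observed yield).

    Growth and yield are each rescaled to [0, 1] over the cohort; the
    score is their unweighted mean.  Ties break by raw yield, then by
    lexicographic pair id.
    """
    if not records:
        return []
    growth = _minmax([mu for _, mu, _ in records])
    yields = _minmax([moi for _, _, moi in records])
    ranked = [
        RankedCommunity(
            pair=pair,
            normalized_growth=g,
            normalized_yield=y,
            score=0.5 * (g + y),
            jaccard_distance=(jaccard or {}).get(pair),
        )
        for (pair, mu, moi), g, y in zip(records, growth, yields)
    ]
    raw_moi = {pair: moi for pair, _, moi in records}
    ranked.sort(key=lambda r: (-r.score, -raw_moi[r.pair], r.pair))
    return ranked
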