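"""Interaction typing, viability, cross-feeding detection and summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .community import CommunityModel, community_exchange_id
from .steadycom import CommunitySolution

__all__ = [
    "SIGN_LABELS",
    "classify_interaction",
    "is_viable",
    "InteractionRecord",
    "make_interaction_record",
    "CrossFeedRecord",
    "detect_cross_feeding",
    "summarize_screen",
]

#: Total map from the per-member sign pair (growth change of each member
#: under the 10% rule) to the six ecological interaction types.  The map is
#: symmetric: unordered labels only.
SIGN_LABELS: Dict[Tuple[int, int], str] = {
    (1, 1): "mutualism",
    (-1, -1): "competition",
    (0, 0): "neutralism",
    (1, 0): "commensalism",
    (0, 1): "commensalism",
    (-1, 0): "amensalism",
    (0, -1): "amensalism",
    (1, -1): "parasitism",
    (-1, 1): "parasitism",
}

DEFAULT_INTERACTION_THRESHOLD = 0.10
DEFAULT_MIN_GROWTH = 0.01


def _sign(mono: float, co: float, threshold_frac: float) -> int:
    if co > mono * (1.0 + threshold_frac):
        return 1
    if co < mono * (1.0 - threshold_frac):
        return -1
    return 0


def classify_interaction(
    mono_a: float,
    mono_b: float,
    co_a: float,
    co_b: float,
    threshold_frac: float = DEFAULT_INTERACTION_THRESHOLD,
) -> str:
    """Interaction label from monoculture vs. co-culture growth rates.

    A member counts as increased (decreased) only when its co-culture
    growth differs from monoculture by strictly more than
    ``threshold_frac`` (default 10%) of the monoculture rate.
    """
    if min(mono_a, mono_b, co_a, co_b) < 0:
        raise ValueError("growth rates must be non-negative")
    if mono_a == 0 or mono_b == 0:
        raise ValueError(
            "members non-growing in monoculture cannot be classified"
        )
    return SIGN_LABELS[
        (_sign(mono_a, co_a, threshold_frac),
         _sign(mono_b, co_b, threshold_frac))
    ]


def is_viable(co_growth: Iterable[float],
              min_growth: float = DEFAULT_MIN_GROWTH) -> bool:
    """True iff every member grows at ``min_growth`` (inclusive) or faster."""
    return all(g >= min_growth for g in co_growth)


@dataclass(frozen=True)
class InteractionRecord:
    pair: Tuple[str, str]
    mono_growth: Tuple[float, float]
    co_growth: Tuple[float, float]
    relative_change: Tuple[float, float]
    label: str


def make_interaction_record(
    pair: Tuple[str, str],
    mono_growth: Tuple[float, float],
    co_growth: Tuple[float, float],
    threshold_frac: float = DEFAULT_INTERACTION_THRESHOLD,
    min_growth: float = DEFAULT_MIN_GROWTH,
) -> InteractionRecord:
    """Classify one pair, marking it ``non_viable`` when a member's
    co-culture growth falls below the viability threshold."""
    change = tuple(
        (co - mono) / mono if mono > 0 else float("nan")
        for mono, co in zip(mono_growth, co_growth)
    )
    if not is_viable(co_growth, min_growth):
        label = "non_viable"
    else:
        label = classify_interaction(
            mono_growth[0], mono_growth[1], co_growth[0], co_growth[1],
            threshold_frac,
        )
    return InteractionRecord(pair, tuple(mono_growth), tuple(co_growth),
                             change, label)


@dataclass(frozen=True)
class CrossFeedRecord:
    metabolite_id: str  # pool metabolite, e.g. "ac(u)"
    donor: str
    receiver: str
    donor_flux: float  # > 0, secretion into [u]
    receiver_flux: float  # < 0, uptake from [u]


def detect_cross_feeding(
    cm: CommunityModel,
    solution: CommunitySolution,
    threshold: float = 2.0,
    medium_exchange_ids: Iterable[str] = frozenset(),
) -> List[CrossFeedRecord]:
    """Metabolites secreted by one member and consumed by the other.

    A pool metabolite is cross-fed when one member's transfer flux is at
    least ``threshold`` (secretion) and the other's is at most
    ``-threshold`` (uptake), both inclusive, in community-scaled
    mmol/gDW/h.  Metabolites whose exchange belongs to the growth medium
    (including the sugar substrates) are never reported.
    """
    excluded = {
        community_exchange_id(ex)[3:]  # "EX_ac(u)" -> "ac(u)"
        for ex in medium_exchange_ids
    }
    a, b = cm.member_ids
    records: List[CrossFeedRecord] = []
    for pool_met in sorted(cm.community_exchange_ids):
        if pool_met in excluded:
            continue
        flux_a = cm.transfer_flux(solution.fluxes, a, pool_met)
        flux_b = cm.transfer_flux(solution.fluxes, b, pool_met)
        if flux_a >= threshold and flux_b <= -threshold:
            records.append(CrossFeedRecord(pool_met, a, b, flux_a, flux_b))
        elif flux_b >= threshold and flux_a <= -threshold:
            records.append(CrossFeedRecord(pool_met, b, a, flux_b, flux_a))
    return records


def summarize_screen(
    records: Sequence[InteractionRecord],
    solutions: Optional[Mapping[Tuple[str, str], CommunitySolution]] = None,
) -> Dict[str, pd.DataFrame]:
    """Per-species occurrence, abundance profiles and label fractions.

    ``occurrence``: how often each species appears in a viable pair.
    ``abundance``: distribution statistics of each species' relative
    abundance across its viable pairs (requires ``solutions``).
    ``label_fractions``: fraction of viable pairs per interaction type.
    """
    viable = [r for r in records if r.label != "non_viable"]
    occurrence: Dict[str, int] = {}
    for rec in viable:
        for member in rec.pair:
            occurrence[member] = occurrence.get(member, 0) + 1
    occurrence_df = pd.DataFrame(
        sorted(occurrence.items()), columns=["species", "occurrence"]
    )

    fractions = pd.Series(
        [r.label for r in viable], dtype="object"
    ).value_counts(normalize=True).rename_axis("label").to_frame("fraction")

    abundance_df = pd.DataFrame()
    if solutions:
        viable_pairs = {r.pair for r in viable}
        rows = []
        for pair, sol in solutions.items():
            if pair in viable_pairs or tuple(reversed(pair)) in viable_pairs:
                for member, x in sol.abundances.items():
                    rows.append({"species": member, "abundance": x})
        if rows:
            abundance_df = (
                pd.DataFrame(rows)
                .groupby("species")["abundance"]
                .describe()
                .reset_index()
            )
    return {
        "occurrence": occurrence_df,
        "abundance": abundance_df,
        "label_fractions": fractions.reset_index(),
    }
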