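"""Run configuration for the community screening workflow."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .exceptions import ConfigurationError

__all__ = ["Thresholds", "CampConfig"]

_CONDITION_NAMES = ("minimal", "excess", "community_specific")
_REGIMES = ("glc", "xyl", "glc_xyl")


@dataclass(frozen=True)
class Thresholds:
    """The workflow's decision constants (all strictly positive).

    interaction_frac
        Fractional growth change separating increase/decrease from
        "unaffected" (default 10%).
    viability_growth
        Minimum per-member growth rate for a viable community (1/h,
        inclusive).
    crossfeed_flux
        Minimum secretion/uptake flux for a cross-fed metabolite
        (mmol/gDW/h, inclusive).
    yield_fold
        Observed/expected yield fold marking candidate producers
        (inclusive).
    fseof_candidate_max
        Largest knockout shortlist for which double deletions are tested.
    atpm
        Non-growth ATP maintenance flux (mmol/gDW/h, clamped).
    """

    interaction_frac: float = 0.10
    viability_growth: float = 0.01
    crossfeed_flux: float = 2.0
    yield_fold: float = 10.0
    fseof_candidate_max: int = 30
    atpm: float = 0.36

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ConfigurationError(
                    f"threshold {name!r} must be positive, got {value}"
                )


@dataclass
class CampConfig:
    """Configuration of a full screen.

    ``substrates`` maps the logical substrate names to exchange ids;
    ``regimes`` selects single- or multi-substrate runs.  ``medium`` is
    either a list of exchange ids or one of the named presets
    (``default`` for the bundled amino-acid + essentials list, ``fixture``
    for the toy-model medium).
    """

    model_dir: Optional[str] = None
    conditions: List[str] = field(
        default_factory=lambda: ["minimal", "excess", "community_specific"]
    )
    substrates: Dict[str, str] = field(default_factory=lambda: {
        "glc": "EX_glc_D(e)", "xyl": "EX_xyl_D(e)",
    })
    regimes: List[str] = field(default_factory=lambda: ["glc_xyl"])
    product_exchange: str = "EX_lac_D(e)"
    medium: object = "fixture"
    thresholds: Thresholds = field(default_factory=Thresholds)
    mu_tolerance: float = 1e-6
    seed: int = 0
    panel_size: int = 6  # fixture panel size when model_dir is unset

    def __post_init__(self) -> None:
        if not self.substrates:
            raise ConfigurationError("substrates must be non-empty")
        for cond in self.conditions:
            if cond not in _CONDITION_NAMES:
                raise ConfigurationError(
                    f"unknown condition {cond!r}; allowed: {_CONDITION_NAMES}"
                )
        for regime in self.regimes:
            if regime not in _REGIMES:
                raise ConfigurationError(
                    f"unknown regime {regime!r}; allowed: {_REGIMES}"
                )
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        if self.mu_tolerance <= 0:
            raise ConfigurationError("mu_tolerance must be positive")

    def medium_exchange_ids(self) -> frozenset:
        from .io import DEFAULT_MEDIUM
        from .synthetic import FIXTURE_MEDIUM
        if self.medium == "default":
            return frozenset(DEFAULT_MEDIUM)
        if self.medium == "fixture":
            return frozenset(FIXTURE_MEDIUM)
        if isinstance(self.medium, (list, set, tuple, frozenset)):
            return frozenset(self.medium)
        raise ConfigurationError(f"unrecognised medium spec {self.medium!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "CampConfig":
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"invalid YAML config: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigurationError("config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
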