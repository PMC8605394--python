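"""Exception and warning hierarchy for the camp package."""


class CampError(Exception):
    """Base class for all camp errors."""


class FormatError(CampError):
    """A file could not be parsed as the expected format (e.g. SBML)."""


class ModelError(CampError):
    """A model violates a structural requirement (e.g. no biomass reaction)."""


class ConditionError(CampError):
    """A nutrient condition cannot be applied to a model."""


class IdentityError(CampError):
    """Conflicting or duplicate member identifiers in a community."""


class InfeasibleError(CampError):
    """An optimisation problem has no feasible solution."""


class ConfigurationError(CampError):
    """A run configuration is inconsistent (e.g. unbounded growth)."""


class FixtureSpecError(CampError):
    """A synthetic-model specification cannot be realised."""


class CampWarning(UserWarning):
    """Base class for camp warnings."""


class PatchNoOpWarning(CampWarning):
    """A substrate patch was requested for an already-present exchange."""


class NonViableWarning(CampWarning):
    """A model cannot grow under the queried condition."""


class MissingReactionWarning(CampWarning):
    """A referenced reaction id is absent from the model."""
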