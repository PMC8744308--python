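"""Exception hierarchy for fundshed."""


class FundshedError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FundshedError, ValueError):
    """A scalar parameter is out of its admissible range."""


class InvalidInputError(FundshedError, ValueError):
    """An input object violates a precondition (missing node, negative population, ...)."""


class InvalidContractError(FundshedError, ValueError):
    """A contract violates its invariants (bad shares, no delivery sites)."""


class InvalidScenarioError(FundshedError, ValueError):
    """A scenario configuration cannot be realised (e.g. bias 1.0 toward an empty stratum)."""


class ResourceGuardError(FundshedError, RuntimeError):
    """A requested problem size exceeds the configured guard cap."""


class SchemaError(FundshedError, ValueError):
    """A configuration file fails validation; carries the offending keys."""

    def __init__(self, message: str, keys: list[str] | None = None):
        super().__init__(message)
        self.keys = list(keys or [])


class MissingStageError(FundshedError, RuntimeError):
    """A report was requested from a manifest with incomplete stages."""
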