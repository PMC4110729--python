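"""Exception types shared across the package."""


class SwitchscapeError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(SwitchscapeError, ValueError):
    """A state or vector does not match the network's node count."""


class NetworkValidationError(SwitchscapeError, ValueError):
    """A Boolean network violates its structural invariants."""


class CapacityError(SwitchscapeError, ValueError):
    """An exhaustive operation was requested above its node-count cap."""


class DomainError(SwitchscapeError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class ConfigurationError(SwitchscapeError, ValueError):
    """A generation/ensemble configuration is unsatisfiable."""


class EmbeddingError(SwitchscapeError, ValueError):
    """A motif cannot be embedded into the given network."""


class ReachabilityError(SwitchscapeError, ValueError):
    """A hitting-time target is unreachable (singular linear system)."""


class RuleParseError(SwitchscapeError, ValueError):
    """Malformed Boolean rule text."""


class EnsembleBudgetError(SwitchscapeError, RuntimeError):
    """The attempt budget was exhausted before enough networks were accepted.

    Carries the partial result on the ``partial`` attribute.
    """

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


class PrecisionWarning(UserWarning):
    """A truncated numeric procedure reports unresolved tail mass."""
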