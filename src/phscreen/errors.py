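"""Exception hierarchy shared across the package."""


class PHScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(PHScreenError, ValueError):
    """A record or assessment violates its invariants."""


class DomainError(PHScreenError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class MissingDataError(PHScreenError, KeyError):
    """A required value is absent; callers decide the exclusion policy."""

    def __str__(self) -> str:  # KeyError quotes its message by default
        return str(self.args[0]) if self.args else ""


class ConfigurationError(PHScreenError, ValueError):
    """A spec, threshold, or config object is internally inconsistent."""


class SchemaError(PHScreenError, ValueError):
    """A tabular input does not match the documented column schema."""
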