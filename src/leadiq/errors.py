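"""Exception hierarchy for the lead-exposure cost pipeline."""


class LeadIQError(Exception):
    """Base class for all package errors."""


class SchemaError(LeadIQError):
    """Input table is missing a mandatory column or is otherwise malformed."""


class RowValidationError(LeadIQError):
    """A single input row violates a typed invariant.

    Carries the country identifier and the offending field so batch
    readers can report precisely which record failed.
    """

    def __init__(self, iso3: str, field: str, message: str):
        self.iso3 = iso3
        self.field = field
        super().__init__(f"country {iso3!r}, field {field!r}: {message}")


class ConfigError(LeadIQError):
    """Run configuration is malformed or contains out-of-range values."""


class FeasibilityError(LeadIQError):
    """No log-normal distribution satisfies the requested summary constraints."""


class QuadratureError(LeadIQError):
    """Numerical integration failed to reach the requested accuracy.

    ``achieved`` holds the best error estimate obtained before giving up.
    """

    def __init__(self, message: str, achieved: float):
        self.achieved = achieved
        super().__init__(f"{message} (achieved error estimate {achieved:.3e})")


class ScenarioError(LeadIQError):
    """A scenario could not be applied; aggregates per-country failures."""

    def __init__(self, message: str, failures: dict[str, Exception] | None = None):
        self.failures = failures or {}
        super().__init__(message)
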