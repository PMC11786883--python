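"""Exception hierarchy for nutrispan."""


class NutrispanError(Exception):
    """Base class for all package-specific errors."""


class FixtureError(NutrispanError):
    """A packaged or user-supplied data file is malformed."""


class ConfigError(NutrispanError):
    """A required configuration entry is missing or invalid."""


class CurveValidationError(NutrispanError):
    """A dose-response curve violates its structural invariants."""


class ScheduleValidationError(NutrispanError):
    """A mortality schedule violates its structural invariants."""
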