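"""Exception hierarchy for safeward.

Every error raised by the package derives from :class:`SafewardError`,
so callers can catch one base class at the CLI boundary.
"""


class SafewardError(Exception):
    """Base class for all safeward errors."""


class ConfigurationError(SafewardError, ValueError):
    """Invalid generator or simulation configuration."""


class FormatError(SafewardError, ValueError):
    """Malformed input file (missing column, empty file, ...)."""


class AnalysisError(SafewardError, ValueError):
    """A descriptive operation was asked to summarize nothing."""


class DomainError(SafewardError, ValueError):
    """An argument is outside its mathematical domain."""


class ModelError(SafewardError, ValueError):
    """Ill-formed stock-and-flow model specification."""


class CalibrationError(SafewardError, ValueError):
    """The anchor system does not determine the response parameters."""


class ScenarioError(SafewardError, ValueError):
    """A scenario override is outside the parameter's domain."""
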