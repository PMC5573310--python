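"""Exception hierarchy.

``ValidationError`` covers malformed inputs (bad matrices, infeasible
parameters); ``ConfigError`` covers inconsistent run configuration caught
before any computation starts.  The CLI maps ``ConfigError``/``ValidationError``
to exit code 2 and any other failure to exit code 1.
"""


class NeuroccaError(Exception):
    """Base class for package errors."""


class ValidationError(NeuroccaError, ValueError):
    """Invalid input data or infeasible parameters."""


class ConfigError(ValidationError):
    """Inconsistent run configuration, detected before compute."""
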