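"""Exception hierarchy.

Validation errors (bad inputs, malformed files, contract violations) are kept
distinct from computation errors (degenerate data, failed numerics) so the CLI
can map them to different exit codes.
"""


class AwfcError(Exception):
    """Base class for all package errors."""


class ValidationError(AwfcError, ValueError):
    """Input violates a documented contract (range, shape, labels, ...)."""


class FormatError(ValidationError):
    """A file could not be parsed in any supported dialect."""


class ManifestError(ValidationError):
    """Cohort manifest is malformed or inconsistent."""


class ComputationError(AwfcError, RuntimeError):
    """A numeric stage failed on admissible input."""


class DegenerateDataError(ComputationError):
    """Data admit no meaningful fit/statistic (all zero counts, zero variance)."""
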