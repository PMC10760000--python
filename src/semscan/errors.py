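"""Exception hierarchy for semscan.

Every malformed input or degenerate model state raises a typed error from
this module; callers never receive a partially constructed object.
"""


class SemScanError(Exception):
    """Base class for all semscan errors."""


class FormatError(SemScanError):
    """A file could not be parsed into the expected tabular layout."""


class ValidationError(SemScanError):
    """Parsed data violates a domain invariant (range, uniqueness, shape)."""


class PairingError(ValidationError):
    """Replicate pairing in a sample sheet is inconsistent or incomplete."""


class SchemaError(SemScanError):
    """A feature table does not match the schema a trained model expects."""


class DegenerateModelError(SemScanError):
    """A clustering or mixture fit has no meaningful solution (e.g. all
    inputs identical, or two mixture components collapsed onto each other)."""


class ConvergenceError(SemScanError):
    """An iterative fit failed to converge across all restarts."""
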