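"""Exception hierarchy for barcodeaudit.

Everything derives from :class:`BarcodeAuditError` so callers can catch the
package's failures in one clause; individual classes mark which validation
or numerical precondition was violated.
"""


class BarcodeAuditError(Exception):
    """Base class for all errors raised by barcodeaudit."""


class AlignmentError(BarcodeAuditError):
    """Sequences do not share a single alignment length."""


class JoinError(BarcodeAuditError):
    """FASTA identifiers and metadata rows do not match one-to-one."""


class ValidationError(BarcodeAuditError):
    """A record violates a dataset invariant (duplicate ID, empty taxon...)."""


class UndefinedDistanceError(BarcodeAuditError):
    """A sequence pair has zero comparable sites; K2P is undefined."""


class SaturationError(BarcodeAuditError):
    """K2P logarithm argument is non-positive (substitution saturation)."""


class RootingError(BarcodeAuditError):
    """The requested outgroup is not separable by a single edge."""


class DegenerateDesignError(BarcodeAuditError):
    """Regression design matrix is singular (e.g. constant predictor)."""


class ConfigError(BarcodeAuditError):
    """A simulation or pipeline configuration is infeasible."""
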