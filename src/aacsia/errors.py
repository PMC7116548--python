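"""Exception hierarchy.

Every error raised by this package derives from :class:`AacsiaError`, so
callers (and the CLI) can catch domain failures without masking genuine
programming errors.
"""


class AacsiaError(Exception):
    """Base class for all package errors."""


class SchemaError(AacsiaError):
    """A delimited table is missing required columns or rows."""


class IntegrityError(AacsiaError):
    """A table or run violates an internal consistency rule
    (duplicate injections, bracket spacing, mixed elements...)."""


class RegistryError(AacsiaError):
    """An amino-acid code is unknown to the registry."""


class ValidationError(AacsiaError):
    """A value is outside its admissible domain."""


class CalibrationError(AacsiaError):
    """Standard-bracket averaging or the nitrogen regression cannot proceed."""


class ConfigurationError(AacsiaError):
    """A configuration table (carbon counts, simulation config) is incomplete."""


class CorrectionError(AacsiaError):
    """The derivatization carbon correction cannot be applied."""


class TrophicError(AacsiaError):
    """Trophic-position computation is missing a required amino acid."""


class MixingError(AacsiaError):
    """The two-endmember mixing model is degenerate."""


class FingerprintError(AacsiaError):
    """The essential-amino-acid fingerprint matrix cannot be built or analysed."""
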