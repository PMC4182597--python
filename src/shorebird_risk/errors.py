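"""Exception hierarchy shared across the package.

Distinct classes exist so the command-line layer can map failures onto
distinct exit codes (validation vs. parameter vs. I/O vs. data-integrity).
"""


class ShorebirdRiskError(Exception):
    """Base class for all package errors."""


class ValidationError(ShorebirdRiskError):
    """Input data violates the risk-factor model (illegal level, bad category...)."""


class GlyphParseError(ValidationError):
    """An arrow cell could not be interpreted in any accepted dialect."""


class SchemaError(ValidationError):
    """A table file does not match the documented column schema."""


class ParameterError(ShorebirdRiskError):
    """A caller-supplied parameter is out of its legal domain."""


class IntegrityError(ShorebirdRiskError):
    """The packaged data bundle failed its integrity check."""


class GeometryError(ShorebirdRiskError):
    """A geometric input is degenerate or outside the supported domain."""
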