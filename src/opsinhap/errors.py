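"""Exception hierarchy shared across the package.

Two bases so the CLI can map failures onto exit codes: anything wrong with
the inputs (shape, units, schema, out-of-panel alleles) is a
:class:`ValidationError` (exit code 2); anything that goes wrong while a
statistically valid computation runs on valid inputs is an
:class:`AnalysisError` (exit code 3).
"""


class OpsinhapError(Exception):
    """Base class for all package errors."""


class ValidationError(OpsinhapError, ValueError):
    """Invalid input data or configuration."""


class AnalysisError(OpsinhapError, RuntimeError):
    """A computation could not be carried out on otherwise valid input."""
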