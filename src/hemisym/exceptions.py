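"""Exception hierarchy.

``ValidationError`` marks bad user input (configs, ratings, band edges,
montage mismatches); anything else raised by the package is a runtime
failure.  The CLI maps the two classes onto distinct exit codes.
"""


class HemisymError(Exception):
    """Base class for all package errors."""


class ValidationError(HemisymError, ValueError):
    """Invalid configuration or input data."""


class MontageError(ValidationError):
    """Channel names do not resolve against the expected montage."""


class BandError(ValidationError):
    """Invalid frequency-band specification."""
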