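"""Exception hierarchy.

``ValidationError`` covers bad inputs (files, parameters, inconsistent
metadata) and maps to CLI exit code 2; ``ComputationError`` covers failures
inside a computation stage and maps to exit code 3.
"""


class PathcomboError(Exception):
    """Base class for all package errors."""


class ValidationError(PathcomboError, ValueError):
    """Invalid input data, file contents, or configuration."""


class ParseError(ValidationError):
    """Malformed input file; message carries file/line context."""


class ComputationError(PathcomboError, RuntimeError):
    """A computation stage failed on otherwise valid input."""
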