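"""Exception hierarchy.

``UserInputError`` covers everything a caller can fix (malformed files,
bad parameters); the CLI maps it to exit code 1. Anything else escaping
the pipeline is treated as an internal error (exit code 2).
"""


class SirscanError(Exception):
    """Base class for package errors."""


class UserInputError(SirscanError):
    """Invalid input supplied by the caller (file contents, paths, config)."""


class FormatError(UserInputError):
    """A file does not conform to its expected format."""


class ValidationError(UserInputError):
    """Parsed data violates an invariant (e.g. feature beyond genome end)."""
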