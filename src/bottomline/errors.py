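"""Exception types shared across the package."""


class BottomlineError(Exception):
    """Base class for all package errors."""


class FormatError(BottomlineError):
    """A file does not conform to the expected format."""


class UsageError(BottomlineError):
    """An operation was called with invalid arguments or inputs."""
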