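"""Exception hierarchy.

Exit-code mapping used by the command line interface:
config problems -> 2, malformed/inconsistent data -> 3, degenerate pose
groups (empty target or byproduct group) -> 4.
"""


class MsperError(Exception):
    """Base class for all errors raised by msper."""


class ConfigError(MsperError):
    """Invalid or incomplete analysis configuration."""

    exit_code = 2


class DataError(MsperError):
    """Malformed or internally inconsistent input data."""

    exit_code = 3


class DegenerateGroupError(MsperError):
    """A pose-group partition left the target or byproduct group empty,
    so the contact-rate difference is undefined."""

    exit_code = 4
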