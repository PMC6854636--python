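"""Exception hierarchy.

Domain errors (bad data, degenerate inputs) are distinct from configuration
errors so the CLI can map them to different exit codes.
"""


class RFNetError(Exception):
    """Base class for all package errors."""


class DomainError(RFNetError):
    """Invalid data or a statistically degenerate input."""


class ConfigError(RFNetError):
    """Invalid configuration: bad paths, unknown options, bad schema."""


class DegenerateItemError(DomainError):
    """An ordinal item with fewer than two observed categories."""


class EstimationError(DomainError):
    """A model estimation routine failed to produce a usable result."""
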