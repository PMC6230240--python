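"""Exception types used across the package."""


class CansineError(Exception):
    """Base class for package errors."""


class FormatError(CansineError):
    """A file did not conform to its declared format."""


class ConsistencyError(CansineError):
    """Input data violated an internal-consistency invariant."""
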