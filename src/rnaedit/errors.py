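"""Exception hierarchy.

Format errors signal malformed input files; data errors signal inputs that
parse but violate a domain precondition (e.g. a single-sample comparison).
"""


class RnaEditError(Exception):
    """Base class for all package errors."""


class FormatError(RnaEditError):
    """A file could not be parsed as the expected format."""


class VcfFormatError(FormatError):
    pass


class GtfFormatError(FormatError):
    pass


class RepeatFormatError(FormatError):
    pass


class FastaFormatError(FormatError):
    pass


class ResourceFormatError(FormatError):
    pass


class DataError(RnaEditError):
    """Well-formed input that violates a domain precondition."""
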