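"""Exception types shared across the package."""


class TepControlError(Exception):
    """Base class for all package errors."""


class FormatError(TepControlError):
    """An input file does not match the expected tabular layout."""


class EmptyInputError(TepControlError):
    """An input that must be non-empty was empty."""


class UsageError(TepControlError):
    """An operation was called with arguments it cannot act on."""
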