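"""Exception types shared across the pipeline."""


class ImplearnError(Exception):
    """Base class for all package errors."""


class ParameterError(ImplearnError, ValueError):
    """A parameter violates an operation's precondition."""


class FormatError(ImplearnError, ValueError):
    """An input file does not parse in the expected dialect."""


class BoundsError(ImplearnError, ValueError):
    """An event or index falls outside the recording."""


class StratificationError(ImplearnError, ValueError):
    """A cross-validation fold cannot contain both classes."""
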