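"""Exception hierarchy shared across the package."""


class HeartlocError(Exception):
    """Base class for all package errors."""


class FormatError(HeartlocError):
    """An input file is not in the expected on-disk format."""


class ParameterError(HeartlocError, ValueError):
    """A parameter violates a precondition (e.g. cutoff >= Nyquist)."""


class DegenerateInputError(HeartlocError, ValueError):
    """Input data admits no meaningful result (e.g. all-zero signal)."""
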