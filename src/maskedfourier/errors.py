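"""Exception types raised by the package."""


class MaskedFourierError(Exception):
    """Base class for package errors."""


class InvalidGridError(MaskedFourierError, ValueError):
    """Grid construction parameters are unusable."""


class EmptyMaskError(MaskedFourierError, ValueError):
    """The mask contains no data points at all."""


class InconsistencyError(MaskedFourierError, ValueError):
    """An internal invariant (symmetry, layout, checksum) is violated."""


class CacheInvalidationError(MaskedFourierError, ValueError):
    """A cached factorization does not match the current mask/grid/modes."""
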