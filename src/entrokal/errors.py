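"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument or spec field violates its documented constraint."""


class WindowTooShortError(ParameterError):
    """A window has too few samples for the requested embedding dimension."""


class EmptySeriesError(ValueError):
    """A signal or entropy series has no usable (defined) values."""


class IntegrationError(RuntimeError):
    """A numerical trajectory left the finite domain."""


class ChannelNotFoundError(KeyError):
    """The requested channel label is not present in the EDF header."""


class EdfFormatError(ValueError):
    """The file is not readable as European Data Format."""


class UndefinedVrrError(ValueError):
    """VRR is undefined because the raw series has zero variance."""
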