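"""Exception hierarchy shared across the pipeline stages."""


class Tp53MirError(Exception):
    """Base class for all package errors."""


class ParameterError(Tp53MirError, ValueError):
    """A design / configuration field is invalid; message names the field."""


class FormatError(Tp53MirError, ValueError):
    """An input file or sequence violates its format contract."""


class DegenerateInputError(Tp53MirError, ValueError):
    """Statistically degenerate input (group too small, zero variance, ...)."""


class ConflictError(Tp53MirError, RuntimeError):
    """Signed-network propagation delivered contradictory directions to a node."""


class LookupError_(Tp53MirError, KeyError):
    """A node or gene referenced by the caller is absent."""
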