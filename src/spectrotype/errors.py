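"""Exception hierarchy shared by all spectrotype modules.

CLI exit codes: validation/format/parameter problems exit 2, degenerate or
out-of-domain inputs exit 3 (see :mod:`spectrotype.cli`).
"""


class SpectrotypeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SpectrotypeError):
    """A file could not be parsed; the message names the first bad element."""


class ValidationError(SpectrotypeError):
    """An object violates its documented invariants."""


class ParameterError(SpectrotypeError):
    """A parameter is outside its admissible range."""


class DegenerateInputError(SpectrotypeError):
    """Input is structurally valid but carries no usable signal."""


class DomainError(SpectrotypeError):
    """Two inputs are individually valid but mutually incompatible."""
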