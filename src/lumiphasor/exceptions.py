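"""Exception hierarchy.

All library errors derive from :class:`LumiphasorError` so callers can catch
one base class; most also derive from the matching builtin (``ValueError`` /
``KeyError``) so idiomatic ``except ValueError`` code keeps working.
"""


class LumiphasorError(Exception):
    """Base class for all lumiphasor errors."""


class ParameterError(LumiphasorError, ValueError):
    """An argument is outside its documented valid range."""


class DomainError(LumiphasorError, ValueError):
    """Input data lies outside the domain an operation is defined on
    (e.g. a spectrum with support outside the spectral window)."""


class UndefinedPhasorError(DomainError):
    """Phasor transform of a zero-total-intensity spectrum."""


class ShapeError(LumiphasorError, ValueError):
    """Arrays that must agree in shape do not."""


class FormatError(LumiphasorError, ValueError):
    """A file does not conform to the expected on-disk format."""


class IllPosedError(LumiphasorError, ValueError):
    """A fit or decomposition has no unique solution (e.g. collinear
    reference spectra, degenerate unmixing chord)."""
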