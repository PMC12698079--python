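"""Exception hierarchy shared across the package."""


class FingerPhantomError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FingerPhantomError, ValueError):
    """A physical parameter is outside its admissible range."""


class GeometryError(FingerPhantomError, ValueError):
    """A position/direction query is inconsistent with the geometry."""


class GridError(FingerPhantomError, ValueError):
    """A coefficient or wavelength grid is malformed or out of range."""


class OutOfRangeError(FingerPhantomError, ValueError):
    """A query lies outside the tabulated hull.

    Carries the name of the offending axis in ``axis``.
    """

    def __init__(self, message: str, axis: str | None = None):
        super().__init__(message)
        self.axis = axis


class NoSolutionError(FingerPhantomError, RuntimeError):
    """The inverse problem has no admissible solution for the given data."""


class UnattainableReflectanceError(NoSolutionError):
    """The requested reflectance cannot be produced anywhere in the bracket."""


class InvalidConcentrationError(FingerPhantomError, ValueError):
    """A pigment or scatterer concentration is non-positive or negative."""


class DivisionGuardError(FingerPhantomError, ZeroDivisionError):
    """A relative error was requested against a target containing zeros."""


class ConfigError(FingerPhantomError, ValueError):
    """Pipeline configuration failed validation before compute started."""
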