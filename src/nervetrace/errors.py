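"""Exception hierarchy shared across the package."""


class NerveTraceError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NerveTraceError):
    """A configuration value violates an invariant (bad range, size, depth...)."""


class GeometryError(NerveTraceError):
    """Shapes or crop boxes are incompatible."""


class PhantomSizingError(ConfigurationError):
    """The requested ellipse (including its rim) does not fit inside the frame."""


class EmptyMaskError(NerveTraceError):
    """A measurement was requested on a mask with no foreground pixels."""


class DegenerateMaskError(NerveTraceError):
    """The mask foreground is too small to trace (fewer than 4 pixels)."""


class DivergenceError(NerveTraceError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class ConstantInputError(NerveTraceError):
    """Rank correlation is undefined for a constant input vector."""
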