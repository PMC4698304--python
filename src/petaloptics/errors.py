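"""Exception hierarchy for petaloptics."""


class PetalOpticsError(Exception):
    """Base class for all petaloptics errors."""


class InvalidParameterError(PetalOpticsError, ValueError):
    """A model parameter violates its physical domain (negative, non-finite, ...)."""


class UnphysicalInputError(PetalOpticsError, ValueError):
    """Measured or derived optical quantities violate energy conservation."""


class SingularLayerError(PetalOpticsError, ZeroDivisionError):
    """An operation requires a layer with non-zero transmittance."""


class AlignmentError(PetalOpticsError, ValueError):
    """Spectra cannot be brought onto a common wavelength grid."""


class SpectrumFormatError(PetalOpticsError, ValueError):
    """A spectrum file could not be parsed."""


class FitDegenerateError(PetalOpticsError, RuntimeError):
    """Every wavelength of a fit failed; carries per-step failure counts."""

    def __init__(self, message: str, failure_counts: dict | None = None):
        super().__init__(message)
        self.failure_counts = failure_counts or {}
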