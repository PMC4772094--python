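"""Exception hierarchy shared across the package."""


class QdthermError(Exception):
    """Base class for all package-specific errors."""


class BandCoverageError(QdthermError, ValueError):
    """The wavelength grid does not cover the requested spectral band."""


class DegenerateSignalError(QdthermError, ValueError):
    """The denominator band carries no usable signal (I_low <= 0)."""


class FitError(QdthermError, RuntimeError):
    """A model fit failed to converge or the input is unfittable."""


class GatingError(QdthermError, ValueError):
    """A z-profile has no interior intensity peak to gate on."""


class InsufficientDataError(QdthermError, ValueError):
    """Too few observations for the requested estimate."""


class CorrectionError(QdthermError, ValueError):
    """Photobleach correction is undefined (model ratio <= 0)."""


class SegmentationError(QdthermError, ValueError):
    """Segmentation produced an empty foreground."""
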