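"""Exception hierarchy."""


class OnhColorError(Exception):
    """Base class for all package-specific errors."""


class FundusFormatError(OnhColorError):
    """Input raster is not an 8- or 16-bit RGB image."""


class SegmentationFailure(OnhColorError):
    """No plausible optic disc could be delimited; supply a manual seed."""


class ConsistencyError(OnhColorError):
    """Raster regions violate a structural invariant (e.g. vessels outside disc)."""


class VesselReferenceError(OnhColorError):
    """The vessel reference is unusable (too few pixels, or not red-dominant)."""


class InsufficientSampleError(OnhColorError):
    """Too few observations for the requested statistic."""


class ValidationError(OnhColorError):
    """Invalid user-supplied parameters."""
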